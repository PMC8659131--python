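# Methods

## Problem and scope

Biofilms on food-processing surfaces disperse into single microbial
cells (singlets, S), small aggregates (SA, 2–3 attached cells) and large
aggregates (LA, more than 3 cells). Imaging flow cytometry records a
four-channel image per event — brightfield (Ch01/BF), green fluorescence
(Ch02, RedoxSensor Green, a redox dye whose emission scales with
metabolic activity), red fluorescence (Ch05, propidium iodide, a
membrane-impermeant DNA dye marking dead cells) and darkfield
(Ch06/SSC). `aggrecyto` implements the interpretation side of that
measurement: feature extraction, quality gating, linear "super feature"
classification of the aggregation state, metabolic-activity gating, and
per-sample statistics. Instrument control, optics and wet-lab sampling
are out of scope; inputs are per-event TIFF stacks with a CSV manifest,
or precomputed feature CSVs.

## Synthetic event generator

Real environmental samples are not redistributable, so validation runs
on a generator (`synthetic_data`) that emulates the statistical
structure the analysis relies on. It is first-class, tested code, and
its defaults define the study conditions used throughout the tests and
the acceptance script.

**Geometry.** Events are rendered on 64×64 px canvases at 1.0 µm/px
(a FlowSight-class 20× pixel scale). Cells are ellipses with semi-major
axis U[3, 6] px and eccentricity U[0, 0.3]. Aggregates are built by
sequential attachment: each new cell is placed at a uniformly chosen
existing cell, at a uniform angle and a centre distance of
U[0.8, 1.2] × (sum of radii), rejection-sampled until the rasterized
union of cells is a single 8-connected component inside the image
bounds. Small aggregates draw 2–3 cells, large aggregates 4–7. Debris
events are 1–3 small specks (radius 0.7–1.5 px) with brightfield
contrast comparable to cells but no fluorophores: debris is optically
dense, and giving it realistic BF contrast keeps in-focus debris from
being confused with defocused events by the contrast-based focus filter
(its exclusion is the stain filter's job).

**Intensity model.** Per-cell fluorescence amplitudes are log-normal
per (channel, state) on a 0–1023 count scale: Ch02 medians 500 / 150 /
30 counts for active / mid-active / dead, Ch05 median 450 for dead and
15 otherwise; σ(log) 0.25–0.30. Backgrounds are 600 (BF), 8 (Ch02,
Ch05) and 15 (SSC) counts. Brightfield subtracts an absorbance of
250 × U[0.8, 1.2] inside cells; SSC adds multiplicative log-normal
speckle (σ 0.6). The camera model is Poisson shot noise on the expected
signal plus Gaussian read noise (σ 2 counts) and quantization to
uint16. No published intensity calibration exists for these dyes on
this scale; the values were chosen once for clear but overlapping state
clusters (the gates must be *calibrated*, not trivial) and are
configurable.

**Mixtures.** The default sample holds 1000–5000 events: 5% debris and
a 60/25/15 singlet/small/large split of the cellular events; per-cell
states 40/30/30 active/mid-active/dead; 10% of events are rendered out
of focus with Gaussian blur σ U[2, 4] px vs U[0, 0.5] px in focus.
Event classes are drawn by one seeded multinomial; per-event render
seeds are `master_seed + event_index`, so any event can be re-rendered
in isolation.

**What it does not emulate:** extracellular matrix, autofluorescence,
flow-rate drift, TDI readout artefacts, camera saturation behaviour
beyond clipping, or realistic debris morphology. Passing tests
demonstrate that the *protocol logic* recovers known structure under a
faithful noise model — not that the defaults match any particular
instrument's absolute scales.

## Masks and features

The per-channel "default mask" is the set of pixels distinguishable
from background. Thresholding combines Otsu's method with a border-pixel
background estimate (mean ± 3σ of the 1-px frame), taking the stricter
of the two — Otsu alone bisects pure-noise images. Brightfield objects
are darker than background, so the comparison inverts. The largest
connected component is kept together with any component ≥ 25% of its
area, followed by a radius-1 morphological closing. An all-background
image yields an empty mask; features undefined on empty masks are NaN
and propagate as "missing" without raising.

Features follow the `<Feature>_<Channel>` naming convention (~30
columns): size/shape on the BF and SSC masks (area in µm², aspect ratio
= minor/major axis from second central moments, axis lengths, equivalent
diameter, perimeter, circularity 4πA/P², elongation = 1 − AR, solidity
= area / convex-hull area), gradient RMS on BF (RMS gradient magnitude
over the mask normalized by mean in-mask intensity — a focus/contrast
metric invariant to intensity scaling), raw max pixel on each
fluorescence channel's own mask (whole image when empty, so the
staining filter stays defined), signal-strength statistics for Ch02 and
Ch05 over the BF mask (the cell footprint; background = median of
off-mask pixels), and texture on SSC (homogeneity = 1/(1 + CV²),
contrast = IQR/median). The proprietary ~1000-feature catalogue of
commercial IFC software is deliberately not reproduced; classifier
feature *counts* are therefore not comparable to that software's.

## Quality gating

Stained events: raw max pixel > 100 counts in Ch02 **or** Ch05 (the
protocol's published cut). In-focus events: `GradientRMS_BF` at or
above a data-driven threshold, by default Otsu's split of the sample's
own gradient-RMS distribution computed on log10 values — per-event
contrast is approximately log-normal within each focus class, and the
log scale keeps the minority defocused mode from being swallowed by the
broad in-focus mode. The two filters commute (the pipeline applies
focus, then stain, and asserts the event-count ledger
`n_total = n_out_of_focus + n_unstained + n_retained`).

## Super-feature classifiers

Truth populations of 35–50 events per class (default 40) are tagged —
manually in the original protocol, automatically from synthetic ground
truth here (`auto_truth`: the first n retained events of each class in
event order). Construction, per target class against the union of the
other two:

1. z-normalize every feature on the truth union (population SD;
   zero-variance or incomplete columns dropped with a log entry);
2. rank features by |RD|, RD = (µ⁺ − µ⁻)/(σ⁺ + σ⁻), ties broken
   lexicographically for determinism;
3. greedy forward selection in rank order: a candidate feature joins the
   subset only if the subset score's own |RD| improves by more than
   1e-3; selection stops after 5 consecutive rejections or exhaustion.
   The subset's weights are re-estimated at each step by two-class
   Fisher LDA (pooled within-class covariance, ridge 1e-4). The RD
   ranking decides *which* features enter and in what order; LDA decides
   *how much* each contributes. With fixed RD-proportional weights the
   combined score plateaued well below the linear ceiling on the default
   conditions (balanced accuracy 0.85 vs 0.92), so joint re-estimation —
   the natural reading of "maximum separation by linear discriminant
   analysis" — is used;
4. the offset zeroes the midpoint of the two truth-group score means
   (positive scores on the target side), and weights+offset are rescaled
   so the truth-group score SDs sum to 1. This expresses every score in
   Fisher units, making the three classifiers' scores mutually
   comparable without changing the sign of any score or the shape of the
   score histograms.

Assignment: argmax over strictly positive scores; exact ties go to the
earlier class in the order S < SA < LA (logged); events with no positive
score, or with a missing selected feature, are `unclassified`. A
classifier whose final truth separation stays below |RD| = 0.5 is
flagged degenerate (its truth populations essentially overlap — the
all-noise case).

On the default 1000-event sample the three classifiers recover the
generated classes with balanced accuracy ≈ 0.92–0.93 across seeds, with
residual confusion concentrated at the 3-cell/4-cell SA/LA boundary —
the genuinely ambiguous region, since a 3-cell aggregate of large cells
can exceed a 4-cell aggregate of small cells in every size feature.

## Metabolic gating, CRP and mixed aggregates

Activity gates are axis-aligned half-open rectangles in the plane of
*compensated* median (Ch02, Ch05) intensity: dead = high Ch05; active =
high Ch02, low Ch05; mid-active = intermediate Ch02, low Ch05; anything
else = unstained. The gates are pairwise disjoint by construction, so
gating partitions the retained events. Compensation is a 2×2 linear
spillover correction applied to scalar intensities (`observed @ inv(S)`,
identity by default — no spillover matrix is published for this dye
pair, and the generator adds none unless configured).

No gate coordinates are published (the original gating was manual), so
default gates are *calibrated*: pure single-state singlet samples are
generated under the configured intensity model, and each cut is placed
at the density valley (Gaussian-KDE minimum between the cluster medians)
on the log-intensity axis — two cuts on Ch02 (dead|mid-active,
mid-active|active) and one on Ch05 (PI-negative|PI-positive). Gates are
serialized with every run for auditability and user-supplied gates
override calibration.

CRP (cellular redox potential) of a subpopulation is the median of the
compensated median Ch02 intensities of its events; on any default-model
sample with ≥ 50 cells per state, CRP(active) > CRP(mid-active) >
CRP(dead).

Aggregates gated mid-active are screened for heterogeneity: bright-green
local maxima (Ch02 above the active gate's lower edge) and bright-red
local maxima (Ch05 above the dead gate's lower edge) are located inside
the BF mask (minimum peak separation 2 px). The event is relabelled
`mixed` when both kinds of peak occur at spatially distinct positions —
some green/red peak pair ≥ 3 px apart (about one cell radius), i.e.
distinct cells rather than one doubly bright spot. Peak positions rather
than bright-*region* disjointness are used because touching live and
dead cells blend additively at their junction, which makes region
overlap uninformative. Truly intermediate cells light neither channel
above the gate edges, so homogeneous mid-active aggregates produce no
peaks at all; on synthetic data the rule detects ≥ 90% of live/dead
aggregates with no false positives on all-mid-active ones. Whether the
original protocol used spot counting or visual inspection is not
documented; this rule is a declared stand-in. Summaries report `mixed`
both as its own category and folded into mid-active for the conventional
three-category view.

## Statistics and reporting

Per-sample summaries carry exact integer counts and percentages
(100 × count / n_retained); class percentages and within-class activity
percentages each sum to 100 ± 0.01 by construction, asserted at run
end. Replicate groups are compared by classical one-way ANOVA
(between/within sums of squares; an all-identical input leaves F
undefined and is reported `ns`), starred at strict thresholds
p < 0.05 / 0.01 / 0.001. Replicate summaries use the sample SD (n−1);
the classifier internals use the population SD (n) — both conventions
are deliberate and local to their context. No multiple-testing
correction is applied (raw ANOVA p values are reported, noted in the
report manifest). Each input sample file is treated as one replicate,
grouped by its configured metadata.

## Numerical choices and limitations

* Coordinates are 0-based (row, col); masks share their image's grid.
* Aspect ratio of masks with ≤ 2 pixels is 1.0 by convention; axis
  lengths floor the moment eigenvalues at 1/12 (single-pixel variance).
* Circularity is clipped at 1.0 (digital perimeters underestimate).
* Determinism: all stochastic steps run off `numpy.random.default_rng`
  seeded from a single master seed; identical (config, seed) reproduce
  samples and summary CSVs byte for byte.
* Problem sizes: tests and the acceptance script use 1000-event samples
  (plus 100–500-event auxiliary samples) rather than the 5000-event
  files typical of real acquisitions; the generator default remains
  5000, and all measured properties are insensitive to this choice.
* The linear classifiers cannot express non-linear class boundaries;
  the SA class ("middle" in every size feature) relies on
  elongation-type features and is the accuracy bottleneck.
* Gradient RMS, homogeneity and contrast are declared stand-ins for the
  proprietary definitions of the commercial software; they preserve the
  documented orderings (blur decreases gradient RMS; speckle decreases
  homogeneity) but not numerical equivalence.
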