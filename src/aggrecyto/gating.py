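"""Focus/stain filtering, metabolic-state gating and CRP computation.

The analysis is restricted to stained, in-focus events. Stained events
are identified by raw max pixel > 100 counts in either fluorescence
channel; out-of-focus events are excluded on the brightfield gradient-RMS
contrast feature. Retained events are gated in the plane of compensated
median green (Ch02, redox dye) vs red (Ch05, propidium iodide) intensity
into active / mid-active / dead subpopulations, and each subpopulation's
cellular redox potential (CRP) is the median Ch02 intensity of its
events. Aggregates gated mid-active are additionally screened for spatial
co-occurrence of bright-green and bright-red cells, which distinguishes
truly intermediate cells from mixed live/dead aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage import filters

from .events import EventImageSet
from .imaging import Mask, spot_peaks
from .synthetic_data import (
    CELL_STATES,
    SampleConfig,
    generate_sample,
    single_state_config,
)

STAIN_THRESHOLD_DEFAULT = 100.0  # counts; staining-positivity cut on raw max pixel

ACTIVITY_LABELS = ("active", "mid_active", "dead", "unstained", "mixed")


@dataclass(frozen=True)
class GateRect:
    """Half-open rectangle [ch02_min, ch02_max) x [ch05_min, ch05_max)."""

    ch02_min: float = 0.0
    ch02_max: float = float("inf")
    ch05_min: float = 0.0
    ch05_max: float = float("inf")

    def contains(self, ch02, ch05) -> np.ndarray:
        ch02 = np.asarray(ch02, dtype=float)
        ch05 = np.asarray(ch05, dtype=float)
        return (
            (ch02 >= self.ch02_min)
            & (ch02 < self.ch02_max)
            & (ch05 >= self.ch05_min)
            & (ch05 < self.ch05_max)
        )

    def overlaps(self, other: "GateRect") -> bool:
        return (
            self.ch02_min < other.ch02_max
            and other.ch02_min < self.ch02_max
            and self.ch05_min < other.ch05_max
            and other.ch05_min < self.ch05_max
        )


@dataclass
class GateSet:
    """Thresholds, spillover matrix and activity gates for one analysis.

    ``gates`` maps ``active`` / ``mid_active`` / ``dead`` to pairwise
    disjoint rectangles in compensated (Ch02, Ch05) median-intensity
    space; events outside all gates are labelled ``unstained``. The 2x2
    ``spillover`` matrix (rows: source channel; columns: detector) must be
    invertible with unit diagonal.
    """

    gates: dict[str, GateRect]
    stain_threshold: float = STAIN_THRESHOLD_DEFAULT
    focus_threshold: float | None = None
    spillover: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        self.spillover = np.asarray(self.spillover, dtype=float)
        if self.spillover.shape != (2, 2):
            raise ValueError("spillover must be a 2x2 matrix")
        if not np.allclose(np.diag(self.spillover), 1.0):
            raise ValueError("spillover diagonal must be 1")
        if abs(np.linalg.det(self.spillover)) < 1e-12:
            raise ValueError("spillover matrix must be invertible")
        names = list(self.gates)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.gates[a].overlaps(self.gates[b]):
                    raise ValueError(f"gates {a!r} and {b!r} overlap")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stain_threshold": float(self.stain_threshold),
            "focus_threshold": None
            if self.focus_threshold is None
            else float(self.focus_threshold),
            "spillover": self.spillover.tolist(),
            "gates": {
                name: {
                    "ch02_min": g.ch02_min,
                    "ch02_max": g.ch02_max,
                    "ch05_min": g.ch05_min,
                    "ch05_max": g.ch05_max,
                }
                for name, g in self.gates.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        gates = {
            name: GateRect(
                ch02_min=float(g.get("ch02_min", 0.0)),
                ch02_max=float(g.get("ch02_max", np.inf)),
                ch05_min=float(g.get("ch05_min", 0.0)),
                ch05_max=float(g.get("ch05_max", np.inf)),
            )
            for name, g in d["gates"].items()
        }
        return cls(
            gates=gates,
            stain_threshold=float(d.get("stain_threshold", STAIN_THRESHOLD_DEFAULT)),
            focus_threshold=d.get("focus_threshold"),
            spillover=np.asarray(d.get("spillover", np.eye(2)), dtype=float),
        )

    @classmethod
    def from_yaml(cls, path) -> "GateSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# filters


def compute_focus_threshold(table: pd.DataFrame) -> float:
    """Data-driven focus cut: Otsu split of the GradientRMS_BF distribution.

    The split is computed on log10 values — per-event contrast is
    approximately log-normal within the in-focus and defocused
    subpopulations, and the log scale keeps the minority defocused mode
    from being swallowed by the broad in-focus mode.
    """
    vals = table["GradientRMS_BF"].dropna().to_numpy(dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no GradientRMS_BF values available")
    if np.ptp(vals) == 0:
        return float(vals[0])
    return float(10 ** filters.threshold_otsu(np.log10(vals)))


def focus_filter(table: pd.DataFrame, threshold: float | None = None) -> pd.Index:
    """Retain in-focus events: GradientRMS_BF >= threshold.

    With ``threshold=None`` the cut is placed by Otsu's method on the
    sample's own gradient-RMS distribution (the protocol names the
    feature, not a fixed cut-off).
    """
    if "GradientRMS_BF" not in table.columns or table["GradientRMS_BF"].isna().all():
        raise ValueError("GradientRMS_BF missing for all events")
    if threshold is None:
        threshold = compute_focus_threshold(table)
    vals = table["GradientRMS_BF"]
    return table.index[vals.ge(threshold).fillna(False)]


def stain_filter(
    table: pd.DataFrame, threshold: float = STAIN_THRESHOLD_DEFAULT
) -> pd.Index:
    """Retain stained events: raw max pixel > threshold in Ch02 or Ch05."""
    ch02 = table["RawMaxPixel_Ch02"]
    ch05 = table["RawMaxPixel_Ch05"]
    keep = ch02.gt(threshold).fillna(False) | ch05.gt(threshold).fillna(False)
    return table.index[keep]


# ---------------------------------------------------------------------------
# compensation


def compensate(ch02, ch05, spillover: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear spillover correction of paired (Ch02, Ch05) intensities.

    With observed = true @ S (S the 2x2 spillover matrix), returns
    observed @ inv(S). The identity matrix leaves values unchanged.
    """
    S = np.asarray(spillover, dtype=float)
    if S.shape != (2, 2):
        raise ValueError("spillover must be 2x2")
    if abs(np.linalg.det(S)) < 1e-12:
        raise ValueError("spillover matrix is singular")
    obs = np.column_stack([np.asarray(ch02, dtype=float), np.asarray(ch05, dtype=float)])
    true = np.linalg.solve(S.T, obs.T).T
    return true[:, 0], true[:, 1]


def compensated_medians(table: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Compensated per-event median fluorescence intensities."""
    c02, c05 = compensate(
        table["MedianPixel_Ch02"].to_numpy(dtype=float),
        table["MedianPixel_Ch05"].to_numpy(dtype=float),
        gates.spillover,
    )
    return pd.DataFrame({"Ch02": c02, "Ch05": c05}, index=table.index)


# ---------------------------------------------------------------------------
# metabolic gating


def metabolic_gate(table: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Assign one activity label per event from the (Ch02, Ch05) gates.

    Events outside every gate are ``unstained``. Gates are pairwise
    disjoint, so the assignment is a partition.
    """
    comp = compensated_medians(table, gates)
    labels = pd.Series("unstained", index=table.index, dtype=object)
    valid = comp.notna().all(axis=1)
    for name, rect in gates.gates.items():
        inside = rect.contains(comp["Ch02"], comp["Ch05"]) & valid.to_numpy()
        labels[inside] = name
    return labels


def aggregate_heterogeneity(
    event: EventImageSet,
    bf_mask: Mask,
    gates: GateSet,
    min_distance: int = 2,
    peak_separation: float = 3.0,
) -> str:
    """Classify a mid-active aggregate as ``homogeneous`` or ``mixed``.

    Locates bright-green (Ch02 above the active gate's lower edge) and
    bright-red (Ch05 above the dead gate's lower edge) local maxima inside
    the brightfield mask. The event is ``mixed`` when both kinds of spot
    are present at spatially distinct positions — some green/red peak
    pair at least ``peak_separation`` pixels (about one cell radius)
    apart, i.e. distinct cells rather than one doubly bright spot.
    Truly intermediate cells light neither channel above the gate edges,
    so homogeneous mid-active aggregates produce no peaks at all.
    Intended for events already gated mid-active; singlets are excluded
    by the pipeline.
    """
    if bf_mask.empty:
        return "homogeneous"
    rsg_thr = gates.gates["active"].ch02_min
    pi_thr = gates.gates["dead"].ch05_min
    ch02 = np.asarray(event["Ch02"], dtype=float)
    ch05 = np.asarray(event["Ch05"], dtype=float)

    green = spot_peaks(ch02, bf_mask, threshold_abs=rsg_thr, min_distance=min_distance)
    red = spot_peaks(ch05, bf_mask, threshold_abs=pi_thr, min_distance=min_distance)
    if len(green) < 1 or len(red) < 1:
        return "homogeneous"
    dists = np.sqrt(((green[:, None, :] - red[None, :, :]) ** 2).sum(axis=2))
    return "mixed" if dists.max() >= peak_separation else "homogeneous"


def crp(table: pd.DataFrame, ids, gates: GateSet | None = None) -> float:
    """Cellular redox potential of a subpopulation.

    Median of the compensated median Ch02 (green) intensities over the
    given event ids; NaN for an empty subpopulation.
    """
    ids = pd.Index(ids)
    if len(ids) == 0:
        return float("nan")
    sub = table.loc[ids]
    if gates is not None:
        comp = compensated_medians(sub, gates)
        vals = comp["Ch02"]
    else:
        vals = sub["MedianPixel_Ch02"]
    return float(np.nanmedian(vals.to_numpy(dtype=float)))


# ---------------------------------------------------------------------------
# gate calibration


def _valley(low_vals: np.ndarray, high_vals: np.ndarray) -> float:
    """Minimum-density point between two clusters on a log-intensity axis.

    Pools the two groups' log10 intensities, estimates the density with a
    Gaussian KDE and returns the intensity at the density minimum between
    the two group medians (falling back to the log-midpoint when the KDE
    is degenerate).
    """
    from scipy.stats import gaussian_kde

    lo = np.log10(np.clip(low_vals, 1e-3, None))
    hi = np.log10(np.clip(high_vals, 1e-3, None))
    m_lo, m_hi = np.median(lo), np.median(hi)
    if not m_lo < m_hi:
        raise ValueError("cluster medians are not ordered; cannot place a valley")
    pooled = np.concatenate([lo, hi])
    try:
        kde = gaussian_kde(pooled)
        grid = np.linspace(m_lo, m_hi, 256)
        split = grid[int(np.argmin(kde(grid)))]
    except np.linalg.LinAlgError:
        split = 0.5 * (m_lo + m_hi)
    return float(10**split)


def calibrate_gates(
    config: SampleConfig | None = None,
    seed: int = 0,
    n_per_state: int = 150,
    spillover: np.ndarray | None = None,
    stain_threshold: float = STAIN_THRESHOLD_DEFAULT,
) -> GateSet:
    """Derive default activity gates from single-state calibration samples.

    For each physiological state a pure in-focus singlet sample is
    generated under the supplied intensity model, and the gate edges are
    placed at the density valleys between adjacent state clusters on the
    log-intensity axes: two cuts on Ch02 (dead|mid-active and
    mid-active|active) and one cut on Ch05 (PI-negative|PI-positive).
    User-supplied gates override calibration in the pipeline.
    """
    from .imaging import extract_feature_table

    config = config or SampleConfig()
    medians: dict[str, pd.DataFrame] = {}
    for k, state in enumerate(CELL_STATES):
        cfg = single_state_config(state, base=config, n_events=n_per_state)
        events, _ = generate_sample(cfg, seed + 1000 * (k + 1))
        table = extract_feature_table(events)
        medians[state] = table[["MedianPixel_Ch02", "MedianPixel_Ch05"]]

    ch02 = {s: medians[s]["MedianPixel_Ch02"].to_numpy(dtype=float) for s in CELL_STATES}
    ch05 = {s: medians[s]["MedianPixel_Ch05"].to_numpy(dtype=float) for s in CELL_STATES}

    t2_lo = _valley(ch02["dead"], ch02["mid_active"])
    t2_hi = _valley(ch02["mid_active"], ch02["active"])
    nondead_ch05 = np.concatenate([ch05["active"], ch05["mid_active"]])
    t5 = _valley(nondead_ch05, ch05["dead"])

    gates = {
        "dead": GateRect(ch05_min=t5),
        "active": GateRect(ch02_min=t2_hi, ch05_max=t5),
        "mid_active": GateRect(ch02_min=t2_lo, ch02_max=t2_hi, ch05_max=t5),
    }
    return GateSet(
        gates=gates,
        stain_threshold=stain_threshold,
        spillover=np.eye(2) if spillover is None else np.asarray(spillover, dtype=float),
    )
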