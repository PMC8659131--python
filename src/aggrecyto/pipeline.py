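"""End-to-end orchestration: generate/load -> features -> filters ->
classifiers -> gating -> summary -> report.

A run persists every intermediate table (features, retained ids, trained
classifiers, scores, per-event labels, summaries) under the output
directory together with a YAML run manifest, and asserts the event-count
ledger at the end:

    n_total    = n_out_of_focus_excluded + n_unstained_excluded + n_retained
    n_retained = n_S + n_SA + n_LA + n_unclassified
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import classifier as clf
from . import gating, imaging, stats_report, synthetic_data
from .synthetic_data import SampleConfig

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input mode: ``synthetic`` (generate samples under
    ``sample_config``), ``image_dir`` (read TIFF samples via their
    manifest CSVs) or ``feature_csv`` (precomputed feature tables).
    ``samples`` lists (sample_id, group, path-or-None); in synthetic mode
    each listed sample is a replicate generated from a seed derived from
    ``seed``.
    """

    mode: str = "synthetic"
    sample_config: SampleConfig = field(default_factory=SampleConfig)
    samples: list[dict] = field(default_factory=lambda: [{"sample_id": "sample01", "group": "all"}])
    out_dir: str | Path = "aggrecyto_out"
    seed: int = 0
    gates: str | None = None  # YAML path or None for auto-calibration
    classifiers: str | None = None  # directory with classifier YAMLs, or None to train
    truth_n_per_class: int = 40
    stain_threshold: float = gating.STAIN_THRESHOLD_DEFAULT
    focus_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "image_dir", "feature_csv"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if not self.samples:
            raise ValueError("at least one sample must be configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sc = raw.pop("sample_config", {})
        if isinstance(sc, dict):
            for tup_key in (
                "image_size",
                "radius_range",
                "small_aggregate_cells",
                "large_aggregate_cells",
                "blur_in_focus",
                "blur_out_of_focus",
            ):
                if tup_key in sc:
                    sc[tup_key] = tuple(sc[tup_key])
            sample_config = SampleConfig(**sc)
        else:
            sample_config = SampleConfig()
        return cls(sample_config=sample_config, **raw)


@dataclass
class SampleResult:
    sample_id: str
    group: str
    features: pd.DataFrame
    truths: list | None
    retained: pd.Index
    n_total: int
    n_out_of_focus: int
    n_unstained_excluded: int
    scores: pd.DataFrame | None = None
    activity: pd.Series | None = None
    summary: stats_report.SampleSummary | None = None


def _acquire_sample(config: RunConfig, entry: dict, index: int):
    """Return (features, truths, events) for one configured sample."""
    sid = entry["sample_id"]
    if config.mode == "synthetic":
        sample_seed = config.seed + 100_000 * index
        events, truths = synthetic_data.generate_sample(config.sample_config, sample_seed)
        for ev in events:
            ev.event_id = f"{sid}:{ev.event_id}"
        truths = [replace(t, event_id=f"{sid}:{t.event_id}") for t in truths]
        table = imaging.extract_feature_table(events)
        return table, truths, events
    if config.mode == "image_dir":
        events, truths = synthetic_data.read_sample(entry["path"])
        table = imaging.extract_feature_table(events)
        return table, truths, events
    table = imaging.read_feature_table(entry["path"])
    return table, None, None


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run-manifest path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: acquire/generate + features -------------------------
    results: list[SampleResult] = []
    events_by_sample = {}
    for i, entry in enumerate(config.samples):
        sid = entry["sample_id"]
        table, truths, events = _acquire_sample(config, entry, i)
        table.to_csv(out_dir / f"features_{sid}.csv")
        events_by_sample[sid] = events

        # -- stage 2: focus and stain filters -------------------------
        in_focus = gating.focus_filter(table, threshold=config.focus_threshold)
        stained = gating.stain_filter(table, threshold=config.stain_threshold)
        retained = in_focus.intersection(stained)
        n_total = len(table)
        n_oof = n_total - len(in_focus)
        n_unstained = len(in_focus) - len(retained)
        log.info(
            "sample %s: %d events, %d out-of-focus excluded, %d unstained excluded, %d retained",
            sid, n_total, n_oof, n_unstained, len(retained),
        )
        results.append(
            SampleResult(
                sample_id=sid,
                group=entry.get("group", "all"),
                features=table,
                truths=truths,
                retained=retained,
                n_total=n_total,
                n_out_of_focus=n_oof,
                n_unstained_excluded=n_unstained,
            )
        )

    # -- stage 3: classifiers (train on first sample, or load) --------
    first = results[0]
    if config.classifiers:
        cdir = Path(config.classifiers)
        classifiers = {
            label: clf.LinearClassifier.from_yaml(cdir / f"classifier_{label}.yaml")
            for label in clf.CLASS_LABELS
        }
    else:
        if first.truths is None:
            raise ValueError(
                "classifier training requires ground truth; supply trained "
                "classifiers for feature_csv inputs"
            )
        truth = clf.auto_truth(
            first.features,
            first.truths,
            n_per_class=config.truth_n_per_class,
            eligible_ids=first.retained,
        )
        classifiers = clf.build_all_classifiers(first.features, truth)
    for label, c in classifiers.items():
        c.to_yaml(out_dir / f"classifier_{label}.yaml")

    # -- stage 4: gates (load or auto-calibrate) ----------------------
    if config.gates:
        gates = gating.GateSet.from_yaml(config.gates)
    else:
        gates = gating.calibrate_gates(
            config=config.sample_config if config.mode == "synthetic" else None,
            seed=config.seed,
            stain_threshold=config.stain_threshold,
        )
    gates.to_yaml(out_dir / "gates.yaml")

    # -- stage 5: per-sample scoring, gating, heterogeneity, summary --
    summaries = []
    for res in results:
        retained_table = res.features.loc[res.retained]
        scores = clf.score_events(classifiers, retained_table)
        scores.to_csv(out_dir / f"scores_{res.sample_id}.csv")
        res.scores = scores

        activity = gating.metabolic_gate(retained_table, gates)

        # mixed-vs-intermediate refinement for mid-active aggregates
        events = events_by_sample.get(res.sample_id)
        if events is not None:
            ev_by_id = {e.event_id: e for e in events}
            mid_aggregates = scores.index[
                (scores["assigned"].isin(["SA", "LA"])) & (activity == "mid_active")
            ]
            for ev_id in mid_aggregates:
                event = ev_by_id[ev_id]
                bf_mask = imaging.default_mask(event["Ch01"], "Ch01")
                if gating.aggregate_heterogeneity(event, bf_mask, gates) == "mixed":
                    activity[ev_id] = "mixed"
        res.activity = activity

        crp_values = {
            act: gating.crp(retained_table, activity.index[activity == act], gates)
            for act in ("active", "mid_active", "dead")
        }

        per_event = pd.DataFrame(
            {"assigned": scores["assigned"], "activity": activity}
        )
        per_event.to_csv(out_dir / f"events_{res.sample_id}.csv")

        summary = stats_report.summarize(
            scores["assigned"],
            activity,
            crp_values,
            sample_id=res.sample_id,
            group=res.group,
            n_total=res.n_total,
            n_out_of_focus=res.n_out_of_focus,
            n_unstained_excluded=res.n_unstained_excluded,
        )
        _assert_ledger(summary)
        res.summary = summary
        summaries.append(summary)

    # -- stage 6: ANOVA across replicate groups -----------------------
    comparisons = _group_comparisons(summaries)

    # -- stage 7: report ----------------------------------------------
    paths = stats_report.render_report(
        summaries,
        comparisons,
        out_dir,
        manifest_extra={
            "seed": config.seed,
            "mode": config.mode,
            "stain_threshold": float(config.stain_threshold),
            "gates_file": "gates.yaml",
            "classifier_files": [f"classifier_{label}.yaml" for label in clf.CLASS_LABELS],
        },
    )

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "samples": [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "n_total": r.n_total,
                "n_out_of_focus_excluded": r.n_out_of_focus,
                "n_unstained_excluded": r.n_unstained_excluded,
                "n_retained": len(r.retained),
            }
            for r in results
        ],
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    manifest_path = out_dir / "run_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def _assert_ledger(summary: stats_report.SampleSummary) -> None:
    """Event-count conservation checks; violation aborts the run."""
    lhs = summary.n_total
    rhs = summary.n_out_of_focus + summary.n_unstained_excluded + summary.n_retained
    if lhs != rhs:
        raise AssertionError(f"ledger violation: n_total {lhs} != excluded+retained {rhs}")
    if sum(summary.class_counts.values()) != summary.n_retained:
        raise AssertionError("ledger violation: class counts do not sum to n_retained")
    pct_sum = sum(summary.class_percentages().values())
    if abs(pct_sum - 100.0) > 0.01:
        raise AssertionError(f"class percentages sum to {pct_sum}, expected 100")


def _group_comparisons(summaries) -> list[stats_report.ComparisonResult]:
    """One-way ANOVA for each reported quantity across replicate groups."""
    df = pd.DataFrame([s.to_row() for s in summaries])
    groups = df["group"].unique()
    sizes = df.groupby("group").size()
    if len(groups) < 2 or (sizes < 2).any():
        return []
    comparisons = []
    quantities = ["pct_S", "pct_SA", "pct_LA", "pct_aggregates_total"] + [
        f"pct_{act}_{cls}"
        for cls in clf.CLASS_LABELS
        for act in ("active", "mid_active", "dead")
    ]
    for q in quantities:
        vals = [df.loc[df["group"] == g, q].to_list() for g in groups]
        comparisons.append(stats_report.anova(vals, quantity=q, labels=groups))
    return comparisons
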