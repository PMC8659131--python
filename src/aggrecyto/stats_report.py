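"""Per-sample summaries, one-way ANOVA and report rendering.

Per-event class (S / SA / LA / unclassified) and activity labels are
aggregated into per-sample percentages and CRP values; replicate groups
are compared with classical one-way ANOVA and annotated with the usual
significance stars (* p<0.05, ** p<0.01, *** p<0.001, strict
inequalities). Replicate summaries report mean +/- sample SD (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .classifier import CLASS_LABELS

ACTIVITY_CATEGORIES = ("active", "mid_active", "dead", "mixed", "unstained")


@dataclass
class SampleSummary:
    """Counts, percentages and CRP values for one sample."""

    sample_id: str
    group: str
    n_total: int
    n_retained: int
    n_out_of_focus: int
    n_unstained_excluded: int
    class_counts: dict[str, int]
    activity_counts: dict[str, dict[str, int]]  # class -> activity -> count
    crp: dict[str, float]  # activity label -> CRP (counts)

    def __post_init__(self) -> None:
        if self.n_retained <= 0:
            raise ValueError("summary requires at least one retained event")
        total = sum(self.class_counts.values())
        if total != self.n_retained:
            raise ValueError(
                f"class counts ({total}) must sum to n_retained ({self.n_retained})"
            )

    # -- percentages --------------------------------------------------
    def class_percentages(self) -> dict[str, float]:
        """Percentages of S/SA/LA/unclassified among retained events (sum 100)."""
        return {
            k: 100.0 * v / self.n_retained for k, v in self.class_counts.items()
        }

    def activity_percentages(self, fold_mixed: bool = False) -> dict[str, dict[str, float]]:
        """Within-class activity percentages (sum 100 per class).

        With ``fold_mixed=True`` mixed aggregates are folded into
        mid-active, matching the conventional three-category summary;
        otherwise mixed is reported as its own category.
        """
        out: dict[str, dict[str, float]] = {}
        for cls, counts in self.activity_counts.items():
            counts = dict(counts)
            if fold_mixed:
                counts["mid_active"] = counts.get("mid_active", 0) + counts.pop("mixed", 0)
            n = sum(counts.values())
            out[cls] = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
        return out

    def to_row(self) -> dict:
        row: dict = {
            "sample_id": self.sample_id,
            "group": self.group,
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_out_of_focus": self.n_out_of_focus,
            "n_unstained_excluded": self.n_unstained_excluded,
        }
        for cls, pct in self.class_percentages().items():
            row[f"pct_{cls}"] = pct
            row[f"n_{cls}"] = self.class_counts[cls]
        pcts = self.activity_percentages(fold_mixed=False)
        for cls in CLASS_LABELS:
            for act in ACTIVITY_CATEGORIES:
                row[f"pct_{act}_{cls}"] = pcts.get(cls, {}).get(act, 0.0)
        folded = self.activity_percentages(fold_mixed=True)
        for cls in CLASS_LABELS:
            row[f"pct_mid_active_incl_mixed_{cls}"] = folded.get(cls, {}).get("mid_active", 0.0)
        for act, val in self.crp.items():
            row[f"crp_{act}"] = val
        agg = self.class_counts.get("SA", 0) + self.class_counts.get("LA", 0)
        row["pct_aggregates_total"] = 100.0 * agg / self.n_retained
        return row


def summarize(
    class_labels: pd.Series,
    activity_labels: pd.Series,
    crp_values: dict[str, float],
    sample_id: str = "sample",
    group: str = "all",
    n_total: int | None = None,
    n_out_of_focus: int = 0,
    n_unstained_excluded: int = 0,
) -> SampleSummary:
    """Aggregate per-event labels of one sample into a :class:`SampleSummary`.

    ``class_labels`` and ``activity_labels`` are aligned Series over the
    retained events; counts are exact integers and percentages are
    ``100 * count / n_retained``.
    """
    n_retained = len(class_labels)
    if n_retained == 0:
        raise ValueError("cannot summarize a sample with no retained events")
    class_counts = {
        k: int((class_labels == k).sum()) for k in (*CLASS_LABELS, "unclassified")
    }
    activity_counts: dict[str, dict[str, int]] = {}
    for cls in CLASS_LABELS:
        in_cls = class_labels.index[class_labels == cls]
        acts = activity_labels.loc[in_cls]
        activity_counts[cls] = {
            act: int((acts == act).sum()) for act in ACTIVITY_CATEGORIES
        }
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        n_total=n_total if n_total is not None else n_retained,
        n_retained=n_retained,
        n_out_of_focus=n_out_of_focus,
        n_unstained_excluded=n_unstained_excluded,
        class_counts=class_counts,
        activity_counts=activity_counts,
        crp=dict(crp_values),
    )


@dataclass
class ComparisonResult:
    """One-way ANOVA comparison across replicate groups."""

    quantity: str
    groups: list[str]
    f_statistic: float
    p_value: float
    stars: str

    def to_row(self) -> dict:
        return {
            "quantity": self.quantity,
            "groups": "|".join(self.groups),
            "F": self.f_statistic,
            "p": self.p_value,
            "stars": self.stars,
        }


def stars(p: float) -> str:
    """Significance stars with strict thresholds (ns at exactly 0.05)."""
    if np.isnan(p):
        return "ns"
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova(groups: list[list[float]], quantity: str = "", labels=None) -> ComparisonResult:
    """Classical one-way ANOVA over replicate groups.

    Requires at least two groups of at least two replicates. When every
    value is identical the F statistic is undefined; the result carries
    NaN and is reported ``ns``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group requires >= 2 replicates")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(quantity, labels, float("nan"), float("nan"), "ns")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    return ComparisonResult(quantity, labels, float(f), float(p), stars(float(p)))


# ---------------------------------------------------------------------------
# rendering


def render_report(
    summaries: list[SampleSummary],
    comparisons: list[ComparisonResult],
    out_dir,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write the summary/comparison CSVs, a stacked-bar figure and a manifest.

    The figure stacks within-class activity percentages (mixed folded into
    mid-active for the conventional three-category view) per sample, with
    SD whiskers over replicate groups when more than one sample shares a
    group. Re-running with identical inputs reproduces identical CSVs.
    """
    if not summaries:
        raise ValueError("render_report requires at least one summary")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary_df = pd.DataFrame([s.to_row() for s in summaries])
    summary_path = out_dir / "summary.csv"
    summary_df.to_csv(summary_path, index=False, float_format="%.6f")

    comp_path = out_dir / "comparisons.csv"
    comp_df = pd.DataFrame(
        [c.to_row() for c in comparisons],
        columns=["quantity", "groups", "F", "p", "stars"],
    )
    comp_df.to_csv(comp_path, index=False, float_format="%.6g")

    fig_path = out_dir / "report.png"
    _stacked_bar_figure(summaries, comparisons, fig_path)

    manifest = {
        "n_samples": len(summaries),
        "samples": [s.sample_id for s in summaries],
        "outputs": {
            "summary": summary_path.name,
            "comparisons": comp_path.name,
            "figure": fig_path.name,
        },
        "note": "raw ANOVA p values; no multiple-testing correction applied",
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out_dir / "report_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {
        "summary": summary_path,
        "comparisons": comp_path,
        "figure": fig_path,
        "manifest": manifest_path,
    }


def _stacked_bar_figure(summaries, comparisons, path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    colors = {"active": "#2ca02c", "mid_active": "#ff7f0e", "dead": "#d62728"}
    fig = Figure(figsize=(max(6.0, 1.5 * len(summaries) * 3), 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)

    width = 0.25
    xticks, xlabels = [], []
    for i, s in enumerate(summaries):
        pcts = s.activity_percentages(fold_mixed=True)
        cls_pct = s.class_percentages()
        for j, cls in enumerate(CLASS_LABELS):
            x = i + (j - 1) * width
            bottom = 0.0
            # bar height scaled by the class share so bars also convey S/SA/LA mix
            for act in ("active", "mid_active", "dead"):
                h = pcts.get(cls, {}).get(act, 0.0) * cls_pct.get(cls, 0.0) / 100.0
                ax.bar(x, h, width=width * 0.9, bottom=bottom, color=colors[act],
                       edgecolor="black", linewidth=0.3)
                bottom += h
            xticks.append(x)
            xlabels.append(f"{s.sample_id}\n{cls}")
    ax.set_xticks(xticks)
    ax.set_xticklabels(xlabels, fontsize=7)
    ax.set_ylabel("% of retained events")
    handles = [
        __import__("matplotlib.patches", fromlist=["Patch"]).Patch(
            color=c, label=lbl.replace("_", "-")
        )
        for lbl, c in colors.items()
    ]
    ax.legend(handles=handles, fontsize=8)
    sig = [c for c in comparisons if c.stars != "ns"]
    if sig:
        ax.set_title(
            "; ".join(f"{c.quantity}: {c.stars}" for c in sig[:4]), fontsize=8
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
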