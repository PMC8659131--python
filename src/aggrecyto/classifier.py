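"""Fisher-ratio "super feature" linear classifiers for S / SA / LA.

Small manually (here: automatically, from synthetic ground truth) tagged
truth populations of singlets (S), small aggregates (SA, 2-3 cells) and
large aggregates (LA, >3 cells) drive the construction of three
one-vs-rest linear classifiers:

1. every feature is z-normalized on the union of the truth populations
   (mean 0, population SD 1; zero-variance features dropped);
2. features are ranked by the Fisher discrimination ratio
   ``RD = (mu+ - mu-) / (sigma+ + sigma-)`` between the target truth
   population and the union of the other two;
3. a greedy forward pass admits features in rank order, keeping one only
   while it improves the combined score's own |RD| — i.e. until maximum
   separation is reached — with the weights on the selected subset
   re-estimated at each step by two-class Fisher linear discriminant
   analysis (the RD ranking decides *which* features enter and in what
   order; LDA decides *how much* each contributes);
4. the score is shifted so the decision boundary (midpoint of the two
   truth-group means) sits at 0 and scaled to Fisher units
   (truth-group sigma+ + sigma- = 1) so the three classifiers' scores
   are mutually comparable.

Each event receives three scores; it is assigned to the highest positive
score, or left unclassified when no classifier claims it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

CLASS_LABELS = ("S", "SA", "LA")

#: mapping from generator event classes to classifier labels
EVENT_CLASS_TO_LABEL = {
    "singlet": "S",
    "small_aggregate": "SA",
    "large_aggregate": "LA",
}

TRUTH_SIZE_RANGE = (35, 50)


@dataclass
class TruthSet:
    """Disjoint sets of tagged event ids per class label."""

    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, ids in self.members.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown truth class {label!r}")
            overlap = seen.intersection(ids)
            if overlap:
                raise ValueError(f"truth sets overlap on {sorted(overlap)[:3]}...")
            seen.update(ids)
            lo, hi = TRUTH_SIZE_RANGE
            if not lo <= len(ids) <= hi:
                warnings.warn(
                    f"truth population {label} has {len(ids)} events "
                    f"(outside the customary {lo}-{hi} range)",
                    stacklevel=2,
                )

    def union(self) -> list[str]:
        out: list[str] = []
        for label in CLASS_LABELS:
            out.extend(self.members.get(label, []))
        return out

    def negatives(self, target: str) -> list[str]:
        out: list[str] = []
        for label in CLASS_LABELS:
            if label != target:
                out.extend(self.members.get(label, []))
        return out


@dataclass
class NormalizationParams:
    """Per-feature mean/SD fitted on the truth union (population SD)."""

    means: pd.Series
    stds: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.means.index)


def fit_normalization(table: pd.DataFrame, ids) -> NormalizationParams:
    """Fit z-normalization on the truth-union rows.

    Features with zero variance or missing values on the fitting set are
    dropped (with a log entry); the survivors have mean 0 and SD 1 on the
    fitting set by construction.
    """
    sub = table.loc[list(ids)]
    complete = sub.columns[sub.notna().all(axis=0)]
    dropped_nan = sorted(set(sub.columns) - set(complete))
    if dropped_nan:
        log.info("normalization: dropping features with missing values: %s", dropped_nan)
    sub = sub[complete]
    stds = sub.std(ddof=0)
    keep = stds[stds > 0].index
    dropped_const = sorted(set(complete) - set(keep))
    if dropped_const:
        log.info("normalization: dropping zero-variance features: %s", dropped_const)
    return NormalizationParams(means=sub[keep].mean(), stds=stds[keep])


def normalize(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Apply ``(x - mu) / sigma`` per retained feature."""
    return (table[params.features] - params.means) / params.stds


def fisher_rd(pos: np.ndarray, neg: np.ndarray) -> float:
    """Signed Fisher discrimination ratio ``(mu+ - mu-) / (sigma+ + sigma-)``.

    Population SDs; NaN (feature excluded) when both groups are constant.
    Rankings use the absolute value; the sign orients the weight.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each truth group needs >= 2 values")
    denom = pos.std() + neg.std()
    if denom == 0:
        return float("nan")
    return float((pos.mean() - neg.mean()) / denom)


def rank_features(
    table: pd.DataFrame, truth: TruthSet, target: str
) -> list[tuple[str, float]]:
    """Rank features by |RD| between the target truth group and the rest.

    Descending |RD|; ties broken lexicographically by feature name for
    determinism. Features with undefined RD are omitted.
    """
    pos_ids = truth.members.get(target, [])
    neg_ids = truth.negatives(target)
    if not neg_ids:
        raise ValueError("negative truth set is empty")
    pos = table.loc[pos_ids]
    neg = table.loc[neg_ids]
    scored: list[tuple[str, float]] = []
    for feat in table.columns:
        rd = fisher_rd(pos[feat].to_numpy(), neg[feat].to_numpy())
        if np.isfinite(rd):
            scored.append((feat, rd))
    scored.sort(key=lambda fr: (-abs(fr[1]), fr[0]))
    return scored


@dataclass
class LinearClassifier:
    """One-vs-rest "super feature": offset + weighted sum of z-features.

    ``rd_scores`` records the Fisher discrimination ratio that ranked each
    selected feature; ``weights`` are the jointly estimated LDA weights in
    Fisher units (truth-group score SDs sum to 1).
    """

    target: str
    features: list[str]
    weights: np.ndarray
    rd_scores: np.ndarray
    normalization: NormalizationParams
    offset: float
    degenerate: bool = False

    def score_series(self, table: pd.DataFrame) -> pd.Series:
        """Super-feature score per event; NaN when a selected feature is missing."""
        z = normalize(table, self.normalization)[self.features]
        vals = z.to_numpy(dtype=float) @ np.asarray(self.weights, dtype=float)
        return pd.Series(vals + self.offset, index=table.index)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "features": list(self.features),
            "weights": [float(w) for w in self.weights],
            "rd_scores": [float(r) for r in self.rd_scores],
            "offset": float(self.offset),
            "degenerate": bool(self.degenerate),
            "normalization": {
                "features": self.normalization.features,
                "means": [float(v) for v in self.normalization.means],
                "stds": [float(v) for v in self.normalization.stds],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearClassifier":
        norm = NormalizationParams(
            means=pd.Series(d["normalization"]["means"], index=d["normalization"]["features"]),
            stds=pd.Series(d["normalization"]["stds"], index=d["normalization"]["features"]),
        )
        return cls(
            target=d["target"],
            features=list(d["features"]),
            weights=np.asarray(d["weights"], dtype=float),
            rd_scores=np.asarray(d["rd_scores"], dtype=float),
            normalization=norm,
            offset=float(d["offset"]),
            degenerate=bool(d.get("degenerate", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LinearClassifier":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: final truth-group |RD| below which a classifier is flagged degenerate
#: (truth score distributions essentially overlap)
DEGENERATE_SEPARATION = 0.5

#: ridge added to the pooled within-class covariance before inversion
_LDA_RIDGE = 1e-4


def _fisher_weights(pos_z: np.ndarray, neg_z: np.ndarray) -> np.ndarray:
    """Two-class Fisher LDA direction on a feature subset (ridge-regularized)."""
    p = pos_z.shape[1]
    s_within = 0.5 * (np.cov(pos_z.T, ddof=0) + np.cov(neg_z.T, ddof=0))
    s_within = np.atleast_2d(s_within) + _LDA_RIDGE * np.eye(p)
    return np.linalg.solve(s_within, pos_z.mean(axis=0) - neg_z.mean(axis=0))


def build_classifier(
    table: pd.DataFrame,
    truth: TruthSet,
    target: str,
    tol: float = 1e-3,
    patience: int = 5,
) -> LinearClassifier:
    """Build the one-vs-rest super feature for ``target``.

    Greedy forward selection in RD-rank order: at each step the candidate
    subset adds the next-ranked feature, the subset's Fisher-LDA weights
    are re-estimated, and the feature is kept only if the combined
    score's own |RD| (between the truth groups) improves by more than
    ``tol``. Selection stops after ``patience`` consecutive rejections or
    feature exhaustion. A classifier whose final truth-group separation
    stays below :data:`DEGENERATE_SEPARATION` is flagged degenerate
    (typical of all-noise feature tables). The offset zeroes the midpoint
    of the two truth-group score means, scores are positive on the target
    side, and weights/offset are rescaled so that the truth-group score
    SDs sum to 1 (Fisher units), making scores comparable across the
    three classifiers.
    """
    params = fit_normalization(table, truth.union())
    z = normalize(table, params)
    ranked = rank_features(z.loc[truth.union()], truth, target)
    if not ranked:
        raise ValueError("no feature has a defined discrimination ratio")

    pos_ids = truth.members[target]
    neg_ids = truth.negatives(target)
    pos_z = z.loc[pos_ids]
    neg_z = z.loc[neg_ids]

    selected: list[str] = []
    best_sep = -np.inf
    rejections = 0
    for feat, _rd in ranked:
        cand = selected + [feat]
        zp = pos_z[cand].to_numpy(dtype=float)
        zn = neg_z[cand].to_numpy(dtype=float)
        w = _fisher_weights(zp, zn)
        sep = abs(fisher_rd(zp @ w, zn @ w))
        if sep > best_sep + tol:
            selected = cand
            best_sep = sep
            rejections = 0
        else:
            rejections += 1
            if rejections >= patience:
                break

    rd_by_feat = dict(ranked)
    zp = pos_z[selected].to_numpy(dtype=float)
    zn = neg_z[selected].to_numpy(dtype=float)
    weights = _fisher_weights(zp, zn)
    score_pos = zp @ weights
    score_neg = zn @ weights

    degenerate = best_sep < DEGENERATE_SEPARATION
    if degenerate:
        log.warning(
            "classifier %s degenerate: truth separation |RD|=%.3f < %.1f",
            target, best_sep, DEGENERATE_SEPARATION,
        )

    offset = -0.5 * (score_pos.mean() + score_neg.mean())
    scale = score_pos.std() + score_neg.std()
    if scale > 0:
        weights = weights / scale
        offset = offset / scale
    return LinearClassifier(
        target=target,
        features=selected,
        weights=np.asarray(weights, dtype=float),
        rd_scores=np.asarray([rd_by_feat[f] for f in selected], dtype=float),
        normalization=params,
        offset=float(offset),
        degenerate=degenerate,
    )


def build_all_classifiers(
    table: pd.DataFrame, truth: TruthSet, **kwargs
) -> dict[str, LinearClassifier]:
    return {label: build_classifier(table, truth, label, **kwargs) for label in CLASS_LABELS}


def score_events(
    classifiers: dict[str, LinearClassifier], table: pd.DataFrame
) -> pd.DataFrame:
    """Score every event with the three classifiers and assign a label.

    Assignment is the argmax over strictly positive scores; an exact tie
    goes to the lexicographically earlier class in the order S < SA < LA
    (logged). Events with no positive score — or with a missing selected
    feature, which yields a NaN score — are ``unclassified``.
    """
    scores = pd.DataFrame(index=table.index)
    for label in CLASS_LABELS:
        scores[f"score_{label}"] = classifiers[label].score_series(table)

    vals = scores.to_numpy(dtype=float)
    masked = np.where(np.isnan(vals) | (vals <= 0), -np.inf, vals)
    best = masked.max(axis=1)
    assigned = np.full(len(table), "unclassified", dtype=object)
    has_positive = best > -np.inf
    # argmax returns the first (class-order) index on exact ties: S < SA < LA
    winner = np.argmax(masked, axis=1)
    assigned[has_positive] = np.array(CLASS_LABELS, dtype=object)[winner[has_positive]]
    ties = (masked == best[:, None]).sum(axis=1) > 1
    for ev in table.index[ties & has_positive]:
        log.info("event %s: tied positive scores; assigned %s by class order", ev, assigned[table.index.get_loc(ev)])

    n_nan = int(np.isnan(vals).any(axis=1).sum())
    if n_nan:
        log.info("%d events had missing selected features and were left unclassified", n_nan)
    scores["assigned"] = assigned
    return scores


def auto_truth(
    table: pd.DataFrame,
    truths,
    n_per_class: int = 40,
    eligible_ids=None,
) -> TruthSet:
    """Tag truth populations automatically from synthetic ground truth.

    Takes the first ``n_per_class`` eligible (typically in-focus, stained)
    events of each class in event order — the automated stand-in for the
    manual tagging step of the original protocol. Errors if any class
    falls short.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be >= 1")
    eligible = set(table.index if eligible_ids is None else eligible_ids)
    by_label: dict[str, list[str]] = {label: [] for label in CLASS_LABELS}
    truth_by_id = {t.event_id: t for t in truths}
    for ev in table.index:
        t = truth_by_id.get(ev)
        if t is None or ev not in eligible:
            continue
        label = EVENT_CLASS_TO_LABEL.get(t.event_class)
        if label and len(by_label[label]) < n_per_class:
            by_label[label].append(ev)
    shortfall = {k: n_per_class - len(v) for k, v in by_label.items() if len(v) < n_per_class}
    if shortfall:
        raise ValueError(f"not enough eligible truth events; shortfall: {shortfall}")
    return TruthSet(members=by_label)
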