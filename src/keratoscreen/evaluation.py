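"""Dataset splitting, ROC/AUC, Hosmer grading, confusion-matrix metrics and
percentile normality ranges."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .scan import CLASS_ORDER
from .indexes import INDEX_NAMES, Profile

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "NormativeModel",
    "AUCResult",
    "stratified_split",
    "empirical_auc",
    "hosmer_grade",
    "confusion_matrix",
    "class_metrics",
    "normative_percentiles",
    "normality_flag",
    "ks_normality",
]

HOSMER_GRADES = (
    "No discrimination",
    "Poor discrimination",
    "Acceptable discrimination",
    "Excellent discrimination",
    "Outstanding discrimination",
)


def stratified_split(labels, train_fraction: float = 0.70, seed: int = 0):
    """Per-class random split into train/test index arrays.

    Each class of size n contributes round(train_fraction * n) training
    members (round half-up, so 10 -> 7/3 and 2663 -> 1864/799).  Disjoint,
    exhaustive, reproducible from the seed.
    """
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(math.floor(train_fraction * idx.size + 0.5))
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


class AUCResult(NamedTuple):
    """Oriented AUC (>= 0.5) and the orientation applied to reach it."""

    auc: float
    direction: int  # +1: higher scores indicate the positive class; -1: lower

    @property
    def raw(self) -> float:
        """P(score_pos > score_neg) + 0.5 P(tie) in the original orientation."""
        return self.auc if self.direction == 1 else 1.0 - self.auc


def empirical_auc(scores, labels) -> AUCResult:
    """Mann-Whitney AUC estimator: P(score_pos > score_neg) + 0.5 P(tie).

    ``labels`` are truthy for the positive class.  The result is oriented so
    the reported AUC is >= 0.5, with ``direction`` recording the flip.
    """
    scores = np.asarray(scores, dtype=float)
    pos_mask = np.asarray(labels).astype(bool)
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if auc >= 0.5:
        return AUCResult(float(auc), 1)
    return AUCResult(float(1.0 - auc), -1)


def hosmer_grade(auc: float) -> str:
    """Qualitative discrimination grade for an AUC.

    Bands: 0.5 exactly -> no discrimination; (0.5, 0.7) poor; [0.7, 0.8)
    acceptable; [0.8, 0.95) excellent; >= 0.95 outstanding (boundary values
    belong to the upper band).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc <= 0.5:
        return HOSMER_GRADES[0]
    if auc < 0.7:
        return HOSMER_GRADES[1]
    if auc < 0.8:
        return HOSMER_GRADES[2]
    if auc < 0.95:
        return HOSMER_GRADES[3]
    return HOSMER_GRADES[4]


@dataclass
class ConfusionMatrix:
    """5x5 counts, rows = true class, columns = assigned class, fixed order."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = np.nan
        return 100.0 * self.counts / sums

    def to_text(self) -> str:
        """Human-readable 'n (p%)' table."""
        pct = self.row_percentages()
        width = 16
        header = "True \\ Assigned".ljust(width) + "".join(
            c.rjust(width) for c in self.class_order
        )
        lines = [header]
        for i, cls in enumerate(self.class_order):
            cells = [
                f"{self.counts[i, j]} ({pct[i, j]:.2f}%)" for j in range(len(self.class_order))
            ]
            lines.append(cls.ljust(width) + "".join(c.rjust(width) for c in cells))
        return "\n".join(lines)


def confusion_matrix(true_labels, assigned_labels, class_order=CLASS_ORDER) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    assigned_labels = np.asarray(assigned_labels)
    if true_labels.shape != assigned_labels.shape:
        raise ValueError("label arrays must have equal length")
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, a in zip(true_labels, assigned_labels):
        counts[idx[str(t)], idx[str(a)]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # precision/recall/F1 forced to 0 by zero denominators


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest reduction of the confusion matrix for one class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    i = cm.class_order.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = cm.total - tp - fp - fn
    degenerate = False
    accuracy = (tp + tn) / cm.total
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return ClassMetrics(tp, fp, fn, tn, accuracy, precision, recall, f1, degenerate)


@dataclass
class NormativeModel:
    """Percentile normality thresholds and normative %TI profiles.

    Per index: p1/p5/p95/p99 of a designated normal cohort; values outside
    [p1, p99] are abnormal, inside (p5, p95) normal, in between borderline.
    """

    percentiles: dict[str, dict[str, float]]
    pti_p95: Profile
    epi_pti_p95: Profile
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.percentiles.items():
            if not (p["p1"] <= p["p5"] <= p["p95"] <= p["p99"]):
                raise ValueError(f"percentiles out of order for index {name}")

    def to_jsonable(self) -> dict:
        return {
            "percentiles": self.percentiles,
            "pti_p95": {"d": self.pti_p95.d.tolist(), "values": self.pti_p95.values.tolist()},
            "epi_pti_p95": {
                "d": self.epi_pti_p95.d.tolist(),
                "values": self.epi_pti_p95.values.tolist(),
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "NormativeModel":
        return cls(
            percentiles=d["percentiles"],
            pti_p95=Profile(np.array(d["pti_p95"]["d"]), np.array(d["pti_p95"]["values"])),
            epi_pti_p95=Profile(
                np.array(d["epi_pti_p95"]["d"]), np.array(d["epi_pti_p95"]["values"])
            ),
            provenance=d.get("provenance", {}),
        )


def percentile_profile(profiles: list[Profile], q: float = 95.0) -> Profile:
    """Pointwise percentile of a stack of %TI profiles (NaN bands ignored)."""
    d = profiles[0].d
    mat = np.vstack([p.values for p in profiles])
    with np.errstate(all="ignore"):
        vals = np.nanpercentile(mat, q, axis=0)
    return Profile(d=d.copy(), values=vals)


def normative_percentiles(
    index_table,
    pti_profiles: list[Profile],
    epi_profiles: list[Profile],
    provenance: dict | None = None,
) -> NormativeModel:
    """Empirical normative model from a normal cohort.

    ``index_table`` is a pandas DataFrame (or dict of arrays) with one column
    per index name; percentiles use linear interpolation between order
    statistics (numpy default).
    """
    import pandas as pd

    df = pd.DataFrame(index_table)
    percentiles = {}
    for name in INDEX_NAMES:
        if name not in df:
            raise ValueError(f"index table lacks column {name}")
        v = df[name].to_numpy(dtype=float)
        p1, p5, p95, p99 = np.percentile(v, [1, 5, 95, 99])
        percentiles[name] = {"p1": float(p1), "p5": float(p5), "p95": float(p95), "p99": float(p99)}
    return NormativeModel(
        percentiles=percentiles,
        pti_p95=percentile_profile(pti_profiles, 95.0),
        epi_pti_p95=percentile_profile(epi_profiles, 95.0),
        provenance=provenance or {},
    )


def normality_flag(value: float, thresholds: dict[str, float]) -> str:
    """'normal' inside (p5, p95), 'borderline' in [p1,p5] or [p95,p99], else 'abnormal'."""
    p1, p5, p95, p99 = (thresholds[k] for k in ("p1", "p5", "p95", "p99"))
    if value < p1 or value > p99:
        return "abnormal"
    if p5 < value < p95:
        return "normal"
    return "borderline"


def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal distribution.

    Returns (statistic, asymptotic p-value).  Reported for descriptive use
    only; nothing in the pipeline gates on it.
    """
    v = np.asarray(values, dtype=float)
    mu, sd = v.mean(), v.std(ddof=1)
    if sd <= 0:
        return 1.0, 0.0
    res = stats.kstest(v, "norm", args=(mu, sd))
    return float(res.statistic), float(res.pvalue)
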