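"""Agreement and diagnostic statistics for elasticity readings.

Covers the quantitative-index statistics used to evaluate elastography in a
clinical workflow: interobserver agreement of repeated stiffness readings
(intraclass correlation), per-lesion repeated-measurement summaries
(mean-of-repeats and range), ROC analysis of a stiffness score against a
benign/malignant label (pair-counting AUC, Youden threshold), and the
standard 2x2 diagnostic ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NumericalError, SchemaError

__all__ = [
    "RaterMatrix",
    "RepeatedMeasures",
    "ScoredCohort",
    "DiagnosticTable",
    "icc_agreement",
    "summarize_repeats",
    "roc_auc",
    "youden_threshold",
    "diagnostic_metrics",
]


@dataclass
class RaterMatrix:
    """Complete-case subjects x raters matrix of one stiffness metric."""

    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise SchemaError("rater matrix must be 2-D with >=2 subjects and >=2 raters")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(
                "rater matrix must be complete-case (finite everywhere); "
                "pairwise exclusion of missing entries is not supported"
            )

    @classmethod
    def from_csv(cls, path, metric_name: str = "") -> "RaterMatrix":
        df = pd.read_csv(path)
        num = df.select_dtypes("number")
        if num.shape[1] < 2:
            raise SchemaError("rater CSV needs >=2 numeric rater columns")
        return cls(num.to_numpy(), metric_name or "csv")


@dataclass
class RepeatedMeasures:
    """Repeated readings of one metric on one lesion (n >= 2)."""

    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise SchemaError("need at least 2 repeated readings")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("repeated readings must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class ScoredCohort:
    """Binary labels (malignant=1, benign=0) with a stiffness score per lesion."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise SchemaError("labels and scores must be equal-length 1-D arrays")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise SchemaError("labels must be binary 0/1")
        if not np.all(np.isfinite(self.scores)):
            raise SchemaError("scores must be finite")

    def require_both_classes(self) -> None:
        if len(set(self.labels.tolist())) < 2:
            raise SchemaError("both classes must be present for ROC analysis")

    @classmethod
    def from_csv(cls, path) -> "ScoredCohort":
        df = pd.read_csv(path)
        if not {"label", "score"} <= set(df.columns):
            raise SchemaError("cohort CSV needs 'label' and 'score' columns")
        return cls(df["label"].to_numpy(), df["score"].to_numpy())


@dataclass
class DiagnosticTable:
    """2x2 confusion counts for a positive-vs-negative call."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise SchemaError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise SchemaError("confusion table is empty")


# ---------------------------------------------------------------------------


def icc_agreement(matrix: RaterMatrix, form: str = "2,1") -> float:
    """Intraclass correlation from the two-way layout mean squares.

    Default form '2,1' is the two-way random-effects, absolute-agreement,
    single-measure ICC (Shrout–Fleiss ICC(2,1)) — the usual choice for
    interobserver agreement where raters are a random sample and systematic
    rater offsets should count against agreement. Forms '3,1' (consistency)
    and '2,k' (average-measure) are exposed for sensitivity analysis.
    """
    y = matrix.values
    n, k = y.shape
    grand = y.mean()
    if np.allclose(y, grand):
        raise NumericalError("zero total variance: ICC is undefined")
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "3,1":
        denom = msr + (k - 1) * mse
    elif form == "2,k":
        denom = msr + (msc - mse) / n
    else:
        raise SchemaError(f"unknown ICC form {form!r}; use '2,1', '3,1' or '2,k'")
    if denom == 0:
        raise NumericalError("degenerate mean squares: ICC is undefined")
    num = msr - mse
    return float(num / denom)


def summarize_repeats(measures: RepeatedMeasures) -> dict:
    """Mean of the repeats and their range (max - min)."""
    v = measures.values
    return {"mean": float(v.mean()), "range": float(v.max() - v.min()), "n": measures.n}


def roc_auc(cohort: ScoredCohort) -> dict:
    """AUC by the Mann–Whitney statistic (ties count 1/2) plus the ROC staircase.

    roc_points are (1-specificity, sensitivity) pairs swept from the
    strictest threshold to 'call everything positive', monotone
    non-decreasing in both coordinates.
    """
    cohort.require_both_classes()
    pos = cohort.labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(cohort.scores)  # average ranks share ties as 1/2
    auc = (float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-cohort.scores, kind="stable")
    labels = cohort.labels[order]
    scores = cohort.scores[order]
    distinct = np.r_[np.diff(scores) != 0, True]  # last index of each tie block
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    points = [(0.0, 0.0)] + [(fp / n0, tp / n1) for fp, tp in zip(fps, tps)]
    return {"auc": float(auc), "roc_points": points,
            "thresholds": scores[distinct].tolist()}


def youden_threshold(cohort: ScoredCohort) -> dict:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    The classification rule is score >= threshold => positive. Ties in J
    break toward higher specificity (fewer false positives). A marker with
    no threshold achieving J > 0 — e.g. an inverted marker where low scores
    indicate the positive class — is returned flagged ``inverted`` rather
    than silently re-oriented.
    """
    cohort.require_both_classes()
    pos = cohort.labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    best = None
    # candidate thresholds: each distinct score, plus one above the maximum
    candidates = np.r_[np.unique(cohort.scores), cohort.scores.max() + 1.0]
    for thr in candidates:
        call = cohort.scores >= thr
        sens = float(np.count_nonzero(call & pos)) / n1
        spec = float(np.count_nonzero(~call & ~pos)) / n0
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > best[0]:
            best = (key, float(thr), sens, spec)
    (_j, _spec, _thr), thr, sens, spec = best
    return {
        "threshold": thr,
        "sensitivity": sens,
        "specificity": spec,
        "youden": float(_j),
        "inverted": _j <= 0.0,
    }


def diagnostic_metrics(table: DiagnosticTable) -> dict:
    """Standard 2x2 ratios; a metric with a zero denominator is None."""

    def ratio(num: int, den: int):
        return None if den == 0 else num / den

    t = table
    return {
        "sensitivity": ratio(t.tp, t.tp + t.fn),
        "specificity": ratio(t.tn, t.tn + t.fp),
        "ppv": ratio(t.tp, t.tp + t.fp),
        "npv": ratio(t.tn, t.tn + t.fn),
        "accuracy": ratio(t.tp + t.tn, t.tp + t.fp + t.fn + t.tn),
    }
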