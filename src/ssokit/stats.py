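"""Diagnostic-accuracy and agreement statistics.

Covers the statistical surface of the analysis: 2x2 diagnostic metrics with
likelihood ratios, ROC curves with Youden-optimal cutoffs, k-fold
cross-validated AUC with an influence-function confidence interval, Cohen's
kappa, and two-way random-effects ICC with the Koo-Li reliability categories.

Two conditioning conventions for sensitivity/specificity are supported.
``outcome_conditional`` is the textbook definition (condition on the
reference outcome: sensitivity = a/(a+c)).  ``marker_conditional`` conditions
on marker status instead (sensitivity = a/(a+b), specificity = d/(c+d)); this
is the convention under which the published predictive-performance table's
percentages reproduce exactly from its counts, and is the default where that
table is being reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Confusion2x2",
    "DiagnosticSummary",
    "ROCResult",
    "CrossValAUC",
    "AgreementResult",
    "UndefinedMetricError",
    "diagnostic_summary",
    "roc_points",
    "youden_optimal_cutoff",
    "cv_auc",
    "cohens_kappa",
    "icc_two_way",
    "icc_category",
]


class UndefinedMetricError(ValueError):
    """A metric's defining margin or denominator is zero."""


@dataclass(frozen=True)
class Confusion2x2:
    """Marker-vs-reference counts.

    a: marker present & reference positive;  b: marker present & reference
    negative;  c: marker absent & reference positive;  d: marker absent &
    reference negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "Confusion2x2":
        """Swap the roles of marker and reference (b <-> c)."""
        return Confusion2x2(self.a, self.c, self.b, self.d)

    @classmethod
    def from_calls(cls, marker: np.ndarray, reference: np.ndarray) -> "Confusion2x2":
        marker = np.asarray(marker, dtype=bool)
        reference = np.asarray(reference, dtype=bool)
        if marker.shape != reference.shape:
            raise ValueError("marker and reference must have equal length")
        return cls(
            a=int(np.sum(marker & reference)),
            b=int(np.sum(marker & ~reference)),
            c=int(np.sum(~marker & reference)),
            d=int(np.sum(~marker & ~reference)),
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity/accuracy and likelihood ratios, full precision.

    Percent/2-decimal rounding happens only in :meth:`report`.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    convention: str

    def report(self) -> dict[str, float]:
        """Printed-precision view: percentages to 1 decimal, LRs to 2."""
        return {
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "accuracy_pct": round(100 * self.accuracy, 1),
            "lr_pos": round(self.lr_pos, 2),
            "lr_neg": round(self.lr_neg, 2),
            "convention": self.convention,
        }


def diagnostic_summary(table: Confusion2x2,
                       convention: str = "outcome_conditional") -> DiagnosticSummary:
    """Compute sensitivity, specificity, accuracy, LR+ and LR- from a 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if convention == "marker_conditional":
        pos_margin, neg_margin = a + b, c + d
        sens_num, spec_num = a, d
        pos_name, neg_name = "marker-present", "marker-absent"
    elif convention == "outcome_conditional":
        pos_margin, neg_margin = a + c, b + d
        sens_num, spec_num = a, d
        pos_name, neg_name = "reference-positive", "reference-negative"
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if pos_margin == 0:
        raise UndefinedMetricError(f"{pos_name} margin is zero; sensitivity undefined")
    if neg_margin == 0:
        raise UndefinedMetricError(f"{neg_name} margin is zero; specificity undefined")

    sens = sens_num / pos_margin
    spec = spec_num / neg_margin
    if spec == 1.0:
        raise UndefinedMetricError("specificity is 1; LR+ undefined")
    if spec == 0.0:
        raise UndefinedMetricError("specificity is 0; LR- undefined")
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        accuracy=(a + d) / table.total,
        lr_pos=sens / (1.0 - spec),
        lr_neg=(1.0 - sens) / spec,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# ROC / Youden / cross-validated AUC


@dataclass(frozen=True)
class ROCResult:
    """A full threshold sweep.

    Cutoffs are ordered from calling no case positive to calling every case
    positive, so tpr and fpr are nondecreasing along the sweep.  For
    ``direction="lower_is_positive"`` a case is called positive when its
    score is <= the cutoff (low splenic ratios mean adequate stress).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    direction: str


def roc_points(scores: np.ndarray, labels: np.ndarray,
               direction: str = "lower_is_positive") -> ROCResult:
    """Sweep all distinct score cutoffs (plus a call-nothing sentinel).

    AUC is the trapezoidal area under (fpr, tpr), which equals the
    tie-corrected pairwise concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present for a ROC curve")
    if direction == "lower_is_positive":
        cuts = np.concatenate([[-np.inf], np.unique(scores)])
        called = scores[None, :] <= cuts[:, None]
    elif direction == "higher_is_positive":
        cuts = np.concatenate([[np.inf], np.unique(scores)[::-1]])
        called = scores[None, :] >= cuts[:, None]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    tpr = (called & labels).sum(axis=1) / n_pos
    fpr = (called & ~labels).sum(axis=1) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    cutoff = _youden_from_sweep(cuts, tpr, fpr)
    return ROCResult(thresholds=cuts, tpr=tpr, fpr=fpr, auc=auc,
                     youden_cutoff=cutoff, direction=direction)


def _youden_from_sweep(cuts: np.ndarray, tpr: np.ndarray,
                       fpr: np.ndarray) -> float:
    """Optimal cutoff from a sweep ordered none-called -> all-called.

    The first J maximum calls the fewest cases positive (tie rule).  The
    reported cutoff is the midpoint between the optimal threshold score and
    the next distinct score in the sweep, so it sits between observed values
    while inducing the identical classification; at the sweep's ends the
    sentinel / extreme score is returned as is.
    """
    j = tpr - fpr
    best = int(np.argmax(j))  # first max = fewest cases called positive
    if 0 < best < len(cuts) - 1 and np.isfinite(cuts[best]):
        return float(0.5 * (cuts[best] + cuts[best + 1]))
    return float(cuts[best])


def youden_optimal_cutoff(roc: ROCResult) -> float:
    """Cutoff maximizing J = tpr - fpr; ties go to the fewest positive calls."""
    return _youden_from_sweep(roc.thresholds, roc.tpr, roc.fpr)


@dataclass(frozen=True)
class CrossValAUC:
    """k-fold cross-validated AUC with influence-function 95% CI."""

    k: int
    fold_aucs: np.ndarray
    cv_auc: float
    ci_low: float
    ci_high: float
    seed: int
    ci_method: str = "pooled influence function"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (self.ci_low <= self.cv_auc <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _stratified_folds(labels: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Indices of k folds, each with near-equal class composition."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise UndefinedMetricError(
                f"class {cls} has {idx.size} cases; cannot stratify into {k} folds")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _auc_influence(scores: np.ndarray, labels: np.ndarray,
                   auc: float, direction: str) -> np.ndarray:
    """Per-observation influence-curve values for the AUC of one fold."""
    # Orient so that higher score = positive, then concordance is standard.
    s = -scores if direction == "lower_is_positive" else scores
    pos = s[labels]
    neg = s[~labels]
    p = labels.mean()
    q = 1.0 - p
    ic = np.empty(scores.size)
    # positives: fraction of negatives ranked below (ties half)
    lt = np.searchsorted(np.sort(neg), s[labels], side="left")
    le = np.searchsorted(np.sort(neg), s[labels], side="right")
    ic[labels] = ((lt + 0.5 * (le - lt)) / neg.size - auc) / p
    # negatives: fraction of positives ranked above (ties half)
    gt = pos.size - np.searchsorted(np.sort(pos), s[~labels], side="right")
    ge = pos.size - np.searchsorted(np.sort(pos), s[~labels], side="left")
    ic[~labels] = ((gt + 0.5 * (ge - gt)) / pos.size - auc) / q
    return ic


def cv_auc(scores: np.ndarray, labels: np.ndarray, k: int = 5,
           seed: int = 0, direction: str = "lower_is_positive") -> CrossValAUC:
    """Stratified k-fold cross-validated AUC.

    Each fold's AUC is computed on the held-out fold alone; the estimate is
    their unweighted mean.  The 95% CI uses the influence-function variance
    estimator pooled over folds (each observation's influence evaluated at
    its own fold's AUC), the estimator documented for cross-validated AUC
    inference.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.Generator(np.random.PCG64(seed))
    folds = _stratified_folds(labels, k, rng)

    fold_aucs = []
    pooled_ic = np.empty(scores.size)
    for f in folds:
        roc = roc_points(scores[f], labels[f], direction)
        fold_aucs.append(roc.auc)
        pooled_ic[f] = _auc_influence(scores[f], labels[f], roc.auc, direction)
    fold_aucs = np.array(fold_aucs)
    est = float(fold_aucs.mean())
    se = float(np.sqrt(np.mean(pooled_ic**2) / scores.size))
    return CrossValAUC(
        k=k, fold_aucs=fold_aucs, cv_auc=est,
        ci_low=max(0.0, est - 1.959963984540054 * se),
        ci_high=min(1.0, est + 1.959963984540054 * se),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Agreement: Cohen's kappa and ICC(2,1)


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement and/or intraclass correlation."""

    kappa: float | None = None
    icc: float | None = None
    icc_category: str | None = None


def cohens_kappa(ratings_a: np.ndarray, ratings_b: np.ndarray) -> float:
    """Cohen's kappa for two binary raters: (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(ratings_a, dtype=bool)
    b = np.asarray(ratings_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be nonempty 1-D arrays of equal length")
    p_o = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        raise UndefinedMetricError("both raters constant; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def icc_category(icc: float) -> str:
    """Koo-Li reliability category for an ICC value."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_two_way(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is a subjects x raters matrix with no missing cells.  Uses
    the standard mean-squares formula

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the between-subject, between-rater and residual mean
    squares of the two-way ANOVA.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix, >= 2 each")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise UndefinedMetricError("zero between-subject variance; ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return AgreementResult(icc=float(icc), icc_category=icc_category(float(icc)))
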