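"""Diagnostic-accuracy machinery: ROC, Youden cutoff, likelihood ratios, Bayes.

The screening index is treated as a continuous test with the convention
*index ≥ cutoff ⇒ positive* (higher values indicate disease).  The module
builds the empirical ROC curve, estimates its area (the Mann–Whitney
probability that a random diseased subject outscores a random non-diseased
one) with DeLong or Hanley–McNeil 95% confidence intervals, selects the
Youden-optimal cutoff, and derives sensitivity, specificity, likelihood
ratios (log-method CIs), the diagnostic odds ratio (Woolf CI) and Bayesian
pretest→posttest probability updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "CiValue",
    "DiagnosticPerformance",
    "BayesResult",
    "empirical_roc",
    "auc_ci",
    "youden_optimal",
    "confusion_at",
    "confusion_from_rates",
    "likelihood_ratios",
    "diagnostic_odds_ratio",
    "performance_at",
    "posttest",
    "screen_subject",
]

_Z95 = 1.96  # fixed normal quantile for all 95% CIs


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts at a cutoff: diseased (tp+fn) vs non-diseased (fp+tn)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n_diseased == 0 or self.n_nondiseased == 0:
            raise ValueError("both groups must be non-empty")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_diseased

    @property
    def specificity(self) -> float:
        return self.tn / self.n_nondiseased

    def corrected(self) -> "ConfusionMatrixContinuity":
        """Haldane–Anscombe +0.5 continuity correction on every cell."""
        return ConfusionMatrixContinuity(
            self.tp + 0.5, self.fn + 0.5, self.fp + 0.5, self.tn + 0.5
        )


@dataclass(frozen=True)
class ConfusionMatrixContinuity:
    """Continuity-corrected cell values (non-integer, internal use)."""

    tp: float
    fn: float
    fp: float
    tn: float


def confusion_from_rates(se: float, sp: float, n_diseased: int, n_nondiseased: int) -> ConfusionMatrix:
    """Recover integer 2×2 counts from printed sensitivity/specificity.

    Rounds se·n₁ and sp·n₀ to the nearest integers — the inverse of how
    published reports derive the rates from counts.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("se and sp must be fractions in [0, 1]")
    tp = round(se * n_diseased)
    tn = round(sp * n_nondiseased)
    return ConfusionMatrix(tp=tp, fn=n_diseased - tp, fp=n_nondiseased - tn, tn=tn)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: descending cutoffs with (se, sp) pairs and the AUC.

    ``cutoffs[0]`` is a sentinel above the maximum score (se=0, sp=1); the
    remaining cutoffs are the distinct observed scores in descending order,
    under the score ≥ cutoff positivity rule.
    """

    cutoffs: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    diseased_scores: np.ndarray
    nondiseased_scores: np.ndarray


def _mann_whitney_auc(diseased: np.ndarray, nondiseased: np.ndarray) -> float:
    """AUC as the Mann–Whitney statistic: P(X_dis > X_non) + ½P(tie)."""
    n1, n0 = len(diseased), len(nondiseased)
    pooled = np.concatenate([diseased, nondiseased])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def empirical_roc(
    diseased_scores: Sequence[float],
    nondiseased_scores: Sequence[float],
    ci_method: str = "delong",
) -> RocCurve:
    """Build the empirical ROC curve for a higher-is-diseased score."""
    d = np.asarray(diseased_scores, dtype=float)
    nd = np.asarray(nondiseased_scores, dtype=float)
    if d.size == 0 or nd.size == 0:
        raise ValueError("both score groups must be non-empty")
    observed = np.unique(np.concatenate([d, nd]))[::-1]  # descending
    sentinel = observed[0] + 1.0
    cutoffs = np.concatenate([[sentinel], observed])
    se = np.array([(d >= c).mean() for c in cutoffs])
    sp = np.array([(nd < c).mean() for c in cutoffs])
    auc = _mann_whitney_auc(d, nd)
    ci = auc_ci(auc, d.size, nd.size, method=ci_method, scores=(d, nd))
    return RocCurve(
        cutoffs=cutoffs, se=se, sp=sp, auc=auc, auc_ci=ci,
        diseased_scores=d, nondiseased_scores=nd,
    )


def _delong_variance(d: np.ndarray, nd: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (d[:, None] > nd[None, :]).astype(float)
    cmp += 0.5 * (d[:, None] == nd[None, :])
    v10 = cmp.mean(axis=1)  # per-diseased placement
    v01 = cmp.mean(axis=0)  # per-nondiseased placement
    n1, n0 = len(d), len(nd)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auc_ci(
    auc: float,
    n1: int,
    n0: int,
    method: str = "hanley_mcneil",
    scores: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """95% CI for an AUC, clipped to [0, 1].

    ``hanley_mcneil`` needs only the summary AUC and group sizes (using the
    exponential approximation Q1 = A/(2−A), Q2 = 2A²/(1+A)); ``delong``
    needs the raw scores and uses the placement-value variance.
    """
    if n1 <= 0 or n0 <= 0:
        raise ValueError("group sizes must be positive")
    if method == "hanley_mcneil":
        a = auc
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    elif method == "delong":
        if scores is None:
            raise ValueError("delong CI requires the raw scores")
        d, nd = (np.asarray(s, dtype=float) for s in scores)
        var = _delong_variance(d, nd)
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")
    se = math.sqrt(max(var, 0.0))
    return (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se))


@dataclass(frozen=True)
class CiValue:
    """A point estimate with a 95% confidence interval.

    ``unbounded`` flags estimates that are 0 or infinite because a 2×2 cell
    is empty (and no continuity correction was requested).
    """

    value: float
    ci: tuple[float, float]
    unbounded: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class BayesResult:
    """One Bayes update: pretest probability → odds → ×LR → posttest."""

    pretest_prob: float
    pretest_odds: float
    lr_applied: float
    posttest_odds: float
    posttest_prob: float


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Test performance at one cutoff of the screening index."""

    cutoff: float
    se: float
    sp: float
    youden_j: float
    lr_pos: CiValue | None = None
    lr_neg: CiValue | None = None
    dor: CiValue | None = None
    degenerate: bool = False


def confusion_at(
    diseased_scores: Sequence[float],
    nondiseased_scores: Sequence[float],
    cutoff: float,
) -> ConfusionMatrix:
    """2×2 counts at a cutoff under the score ≥ cutoff positivity rule."""
    d = np.asarray(diseased_scores, dtype=float)
    nd = np.asarray(nondiseased_scores, dtype=float)
    if d.size == 0 or nd.size == 0:
        raise ValueError("both score groups must be non-empty")
    tp = int((d >= cutoff).sum())
    fp = int((nd >= cutoff).sum())
    return ConfusionMatrix(tp=tp, fn=d.size - tp, fp=fp, tn=nd.size - fp)


def youden_optimal(roc: RocCurve) -> DiagnosticPerformance:
    """Cutoff among the observed scores maximizing Youden's J = se + sp − 1.

    Ties are broken toward higher sensitivity, then the lower cutoff
    (screening favours catching cases).  If every score is identical the
    curve is degenerate: J = 0 and the result is flagged.
    """
    # skip the sentinel: candidate cutoffs are observed values only
    cutoffs, se, sp = roc.cutoffs[1:], roc.se[1:], roc.sp[1:]
    j = se + sp - 1.0
    order = sorted(
        range(len(cutoffs)), key=lambda i: (-j[i], -se[i], cutoffs[i])
    )
    best = order[0]
    degenerate = (
        len(np.unique(np.concatenate([roc.diseased_scores, roc.nondiseased_scores]))) == 1
    )
    if degenerate:
        return DiagnosticPerformance(
            cutoff=float(cutoffs[best]), se=float(se[best]), sp=float(sp[best]),
            youden_j=0.0, degenerate=True,
        )
    return DiagnosticPerformance(
        cutoff=float(cutoffs[best]), se=float(se[best]), sp=float(sp[best]),
        youden_j=float(j[best]),
    )


def likelihood_ratios(
    cm: ConfusionMatrix, correction: bool = False
) -> tuple[CiValue, CiValue]:
    """LR+ = se/(1−sp) and LR− = (1−se)/sp with 95% log-method CIs.

    Point estimates are exact count fractions.  The variance of ln LR+ is
    (1/tp − 1/(tp+fn)) + (1/fp − 1/(fp+tn)), and symmetrically for LR−
    with fn and tn.  An empty fp (or fn) cell makes LR+ infinite (LR− zero);
    such estimates are flagged ``unbounded`` unless the Haldane–Anscombe
    +0.5 correction is enabled.
    """
    c = cm.corrected() if correction else cm
    n1 = c.tp + c.fn
    n0 = c.fp + c.tn

    def _one(num_cell: float, denom_cell: float, num_n: float, denom_n: float) -> CiValue:
        # LR = (num_cell/num_n) / (denom_cell/denom_n)
        if denom_cell == 0:
            return CiValue(math.inf, (math.nan, math.nan), unbounded=True)
        value = (num_cell / num_n) / (denom_cell / denom_n)
        if num_cell == 0:
            return CiValue(0.0, (math.nan, math.nan), unbounded=True)
        var = (1 / num_cell - 1 / num_n) + (1 / denom_cell - 1 / denom_n)
        half = _Z95 * math.sqrt(max(var, 0.0))
        return CiValue(value, (value * math.exp(-half), value * math.exp(half)))

    lr_pos = _one(c.tp, c.fp, n1, n0)
    lr_neg = _one(c.fn, c.tn, n1, n0)
    return lr_pos, lr_neg


def diagnostic_odds_ratio(cm: ConfusionMatrix, correction: bool = False) -> CiValue:
    """DOR = (tp·tn)/(fn·fp) with a 95% Woolf log-method CI.

    Algebraically equal to LR+/LR−.  SE(ln DOR) = √(1/tp + 1/fn + 1/fp + 1/tn).
    Zero cells flag the estimate unless the +0.5 correction is enabled.
    """
    c = cm.corrected() if correction else cm
    if c.fn == 0 or c.fp == 0:
        return CiValue(math.inf, (math.nan, math.nan), unbounded=True)
    if c.tp == 0 or c.tn == 0:
        return CiValue(0.0, (math.nan, math.nan), unbounded=True)
    dor = (c.tp * c.tn) / (c.fn * c.fp)
    se = math.sqrt(1 / c.tp + 1 / c.fn + 1 / c.fp + 1 / c.tn)
    half = _Z95 * se
    return CiValue(dor, (dor * math.exp(-half), dor * math.exp(half)))


def performance_at(
    diseased_scores: Sequence[float],
    nondiseased_scores: Sequence[float],
    cutoff: float,
    correction: bool = False,
) -> DiagnosticPerformance:
    """Full diagnostic performance (se, sp, J, LR±, DOR with CIs) at a cutoff."""
    cm = confusion_at(diseased_scores, nondiseased_scores, cutoff)
    return performance_from_counts(cm, cutoff, correction=correction)


def performance_from_counts(
    cm: ConfusionMatrix, cutoff: float = math.nan, correction: bool = False
) -> DiagnosticPerformance:
    """Diagnostic performance from a 2×2 table (cutoff is informational)."""
    lr_pos, lr_neg = likelihood_ratios(cm, correction=correction)
    return DiagnosticPerformance(
        cutoff=cutoff,
        se=cm.sensitivity,
        sp=cm.specificity,
        youden_j=cm.sensitivity + cm.specificity - 1.0,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=diagnostic_odds_ratio(cm, correction=correction),
    )


def posttest(pretest_prob: float, lr: float) -> BayesResult:
    """Bayes update: posttest odds = pretest odds × likelihood ratio."""
    if not 0 < pretest_prob < 1:
        raise ValueError("pretest probability must be strictly between 0 and 1")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    pre_odds = pretest_prob / (1 - pretest_prob)
    post_odds = pre_odds * lr
    return BayesResult(
        pretest_prob=pretest_prob,
        pretest_odds=pre_odds,
        lr_applied=lr,
        posttest_odds=post_odds,
        posttest_prob=post_odds / (1 + post_odds),
    )


def screen_subject(
    ratio: float,
    cutoff: float,
    pretest_prob: float,
    perf: DiagnosticPerformance,
) -> tuple[str, BayesResult]:
    """Classify one subject's index and update their disease probability.

    A ratio at or above the cutoff is positive (apply LR+), otherwise
    negative (apply LR−).
    """
    if perf.lr_pos is None or perf.lr_neg is None:
        raise ValueError("performance object must carry LR+ and LR−")
    if ratio >= cutoff:
        return "positive", posttest(pretest_prob, perf.lr_pos.value)
    return "negative", posttest(pretest_prob, perf.lr_neg.value)
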