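"""Group-comparison statistics: descriptives, Levene, ANOVA, post-hoc tests.

The comparison workflow for each variable is the classic SPSS-style chain:
per-group mean ± SD, Levene's homogeneity-of-variance test (centered at the
group mean), a one-way ANOVA, and pairwise post-hoc comparisons whose method
is chosen by the Levene result — Scheffé under homogeneous variances,
Games–Howell (Welch-type t against the studentized-range distribution with
Welch–Satterthwaite degrees of freedom) under heterogeneous variances.
P-values are two-sided; no multiplicity correction is applied beyond the
post-hoc procedures themselves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonReport",
    "levene",
    "oneway_anova",
    "scheffe_pairwise",
    "games_howell_pairwise",
    "pooled_mean",
    "table1",
]

#: Levene p-value below which variances are treated as unequal.
LEVENE_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    group: Hashable
    n: int
    mean: float
    sd: float  # sample SD (n−1); 0.0 when n == 1


@dataclass
class ComparisonReport:
    """Full comparison chain for one variable across k groups."""

    variable: str
    levene_w: float
    levene_p: float
    anova_f: float
    anova_p: float
    posthoc_method: str  # "scheffe" | "games_howell"
    pairwise: dict[tuple[Hashable, Hashable], float] = field(default_factory=dict)


def _check_groups(groups: Sequence[Sequence[float]], min_size: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < min_size:
            raise ValueError(f"group {i} has {a.size} values; need ≥ {min_size}")
    return arrays


def levene(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's test for equal variances, centered at the group means.

    Equivalent to a one-way ANOVA on the absolute deviations from each
    group's mean; p from F(k−1, N−k).
    """
    arrays = _check_groups(groups)
    w, p = stats.levene(*arrays, center="mean")
    return float(w), float(p)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F test."""
    arrays = _check_groups(groups)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def scheffe_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[Hashable] | None = None,
) -> dict[tuple[Hashable, Hashable], float]:
    """Scheffé all-pairs post-hoc p-values (pooled error variance).

    For pair (i, j):  F_pair = (m_i − m_j)² / (MSW · (1/n_i + 1/n_j) · (k−1)),
    referred to F(k−1, N−k).  Reduces to the ANOVA p-value when k = 2.
    """
    arrays = _check_groups(groups)
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n_total - k)
    out: dict[tuple[Hashable, Hashable], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        if msw == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            f_pair = (a.mean() - b.mean()) ** 2 / (
                msw * (1 / a.size + 1 / b.size) * (k - 1)
            )
            p = float(stats.f.sf(f_pair, k - 1, n_total - k))
        out[(labels[i], labels[j])] = p
        out[(labels[j], labels[i])] = p
    return out


def games_howell_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[Hashable] | None = None,
) -> dict[tuple[Hashable, Hashable], float]:
    """Games–Howell all-pairs post-hoc p-values (no equal-variance assumption).

    For pair (i, j): t = (m_i − m_j)/√(s_i²/n_i + s_j²/n_j), with
    Welch–Satterthwaite degrees of freedom (kept fractional), and
    p = P(Q_{k,df} > t·√2) from the studentized-range distribution.

    Degenerate pairs with zero variance in both groups get p = 1 when the
    means agree and p = 0 when they differ.
    """
    arrays = _check_groups(groups)
    labels = list(labels) if labels is not None else list(range(len(arrays)))
    k = len(arrays)
    out: dict[tuple[Hashable, Hashable], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sa2n, sb2n = va / a.size, vb / b.size
        denom = sa2n + sb2n
        if denom == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t = abs(a.mean() - b.mean()) / math.sqrt(denom)
            df = denom**2 / (
                sa2n**2 / (a.size - 1) + sb2n**2 / (b.size - 1)
            )
            p = float(stats.studentized_range.sf(t * math.sqrt(2.0), k, df))
        out[(labels[i], labels[j])] = p
        out[(labels[j], labels[i])] = p
    return out


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of subgroup means (the pooled sample mean)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or means.size == 0:
        raise ValueError("means and ns must be non-empty and of equal length")
    if (ns <= 0).any():
        raise ValueError("sample sizes must be positive")
    return float((means * ns).sum() / ns.sum())


def table1(
    data: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
) -> tuple[pd.DataFrame, dict[str, ComparisonReport]]:
    """Descriptives and the full comparison chain for each variable.

    ``data`` holds one row per subject with a group-label column.  Returns a
    (group × variable) grid of GroupSummary entries as a tidy DataFrame
    (columns group, variable, n, mean, sd) and one :class:`ComparisonReport`
    per variable, with the post-hoc branch chosen by Levene's test at
    α = 0.05 (Games–Howell when p < 0.05, else Scheffé).
    """
    if group_col not in data.columns:
        raise ValueError(f"column {group_col!r} absent from data")
    for v in variables:
        if v not in data.columns:
            raise ValueError(f"variable {v!r} absent from data")
    group_labels = list(dict.fromkeys(data[group_col]))
    if len(group_labels) < 2:
        raise ValueError("need at least two groups")

    rows = []
    reports: dict[str, ComparisonReport] = {}
    for v in variables:
        series = [
            data.loc[data[group_col] == g, v].dropna().to_numpy(dtype=float)
            for g in group_labels
        ]
        for g, vals in zip(group_labels, series):
            rows.append(
                {
                    "group": g,
                    "variable": v,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else math.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
        usable = [(g, s) for g, s in zip(group_labels, series) if s.size >= 2]
        if len(usable) < 2:
            raise ValueError(f"variable {v!r}: fewer than two groups with n ≥ 2")
        labels = [g for g, _ in usable]
        arrays = [s for _, s in usable]
        w, lp = levene(arrays)
        f, ap = oneway_anova(arrays)
        if lp < LEVENE_ALPHA:
            method = "games_howell"
            pairwise = games_howell_pairwise(arrays, labels)
        else:
            method = "scheffe"
            pairwise = scheffe_pairwise(arrays, labels)
        reports[v] = ComparisonReport(
            variable=v, levene_w=w, levene_p=lp,
            anova_f=f, anova_p=ap,
            posthoc_method=method, pairwise=pairwise,
        )
    return pd.DataFrame(rows), reports
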