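"""Tie-corrected rank statistics: Kruskal-Wallis, Dunn's post hoc, Spearman.

All tests are the classical large-sample forms computed on mid-ranks.

Kruskal-Wallis on k groups with rank sums R_j over N pooled observations:

    H  = 12 / (N (N+1)) * sum_j R_j^2 / n_j  -  3 (N+1)
    Hc = H / (1 - sum_t (t^3 - t) / (N^3 - N))        (tie correction)

with p from the chi-square upper tail on k-1 degrees of freedom. Dunn's
pairwise z uses the tie-corrected rank variance

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - sum_t (t^3 - t) / (12 (N-1)))
                                    * (1/n_i + 1/n_j))

two-sided, with Bonferroni (default), Sidak or no family adjustment.
Spearman's rho is the Pearson correlation of mid-ranks, with the two-sided
t approximation t = rho sqrt((n-2) / (1 - rho^2)) on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

ADJUSTMENTS = ("none", "bonferroni", "sidak")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int          # degrees of freedom (KW) or sample size n (Spearman)
    p_value: float
    groups: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float
    adjustment: str


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(arrs):
        if len(g) == 0:
            raise ValidationError(f"group {i} has zero observations")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    if sum(map(len, arrs)) < 3:
        raise ValidationError("need at least 3 pooled observations")
    return arrs


def _pooled_ranks(arrs: list[np.ndarray]):
    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)                 # mid-ranks for ties
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    splits = np.cumsum([len(a) for a in arrs])[:-1]
    return np.split(ranks, splits), len(pooled), tie_sum


def kruskal_wallis(groups: Sequence, labels: Sequence[str] | None = None) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across k independent groups."""
    arrs = _check_groups(groups)
    labels = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(len(arrs)))
    group_ranks, N, tie_sum = _pooled_ranks(arrs)
    H = 12.0 / (N * (N + 1)) * sum(r.sum() ** 2 / len(r) for r in group_ranks) - 3.0 * (N + 1)
    denom = 1.0 - tie_sum / (N ** 3 - N)
    if denom <= 0:                               # all pooled observations identical
        return TestResult("kruskal_wallis", 0.0, len(arrs) - 1, 1.0, labels)
    Hc = H / denom
    p = float(sps.chi2.sf(Hc, df=len(arrs) - 1))
    return TestResult("kruskal_wallis", float(Hc), len(arrs) - 1, p, labels)


def dunn_posthoc(groups: Sequence, labels: Sequence[str] | None = None,
                 adjustment: str = "bonferroni") -> list[PairwiseResult]:
    """Dunn's rank-based pairwise comparisons with tie-corrected variance."""
    if adjustment not in ADJUSTMENTS:
        raise ValidationError(f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}")
    arrs = _check_groups(groups)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrs))]
    group_ranks, N, tie_sum = _pooled_ranks(arrs)
    rbar = [r.mean() for r in group_ranks]
    ns = [len(r) for r in group_ranks]
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    m = len(arrs) * (len(arrs) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        if var_term <= 0:                        # fully tied pooled sample
            z, p = 0.0, 1.0
        else:
            z = (rbar[i] - rbar[j]) / np.sqrt(var_term * (1.0 / ns[i] + 1.0 / ns[j]))
            p = float(2.0 * sps.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p * m)
        elif adjustment == "sidak":
            p_adj = 1.0 - (1.0 - p) ** m
        else:
            p_adj = p
        out.append(PairwiseResult((labels[i], labels[j]), float(z), p, float(p_adj), adjustment))
    return out


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties; two-sided t approximation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for a constant variable")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult("spearman", rho, n, p)
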