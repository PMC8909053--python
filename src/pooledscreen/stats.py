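"""Two-sample tests and multiple-testing corrections for per-gene dropout calls.

Implements the testing layer of the screen analysis: Welch's unequal-variance
t test, the Wilcoxon rank-sum test (exact for small tie-free samples, normal
approximation with tie and continuity corrections otherwise), Benjamini–
Hochberg FDR-adjusted p-values, and Storey q-values with a smoothed π₀
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
DEFAULT_EXACT_CUTOFF = 20


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns (t, Welch–Satterthwaite df, p). Degenerate conventions: if both
    groups have zero variance, p = 1 when the means agree and p = 0 (with a
    warning) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidConfigError("welch_t requires >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        warnings.warn("zero variance in both groups with unequal means; p = 0")
        return np.inf if a.mean() > b.mean() else -np.inf, float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_rank_sum(a, b, exact_cutoff: int = DEFAULT_EXACT_CUTOFF) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses the exact null distribution when the pooled sample is tie-free and
    of size ≤ ``exact_cutoff``; otherwise the normal approximation with
    mid-ranks, tie correction and continuity correction. Enumeration with
    ties is ambiguous, so the exact path refuses ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidConfigError("wilcoxon_rank_sum requires non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and len(pooled) <= exact_cutoff else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR-adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidConfigError("p-values must lie in [0,1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Pi0Estimate:
    """π₀ (proportion of true nulls) estimated on a λ grid with smoothing."""

    lambda_grid: np.ndarray
    raw_pi0: np.ndarray
    pi0: float


def estimate_pi0(p, lambda_grid=DEFAULT_LAMBDA_GRID) -> Pi0Estimate:
    """Storey's smoothed π₀: raw estimates #{p > λ}/(m(1−λ)) on a λ grid,
    a cubic smoother through them, evaluated at the largest λ, clamped to (0,1].

    Falls back to the conservative π₀ = 1 (with a warning) if the smoothed
    value is non-positive or the fit fails on tiny inputs.
    """
    p = np.asarray(p, dtype=float)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any((grid <= 0) | (grid >= 1)) or len(np.unique(grid)) != grid.size:
        raise InvalidConfigError("lambda grid must be distinct values in (0,1)")
    grid = np.sort(grid)
    m = p.size
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    try:
        if grid.size < 4:
            raise ValueError("grid too small for a cubic fit")
        poly = np.polynomial.Polynomial.fit(grid, raw, deg=3)
        pi0 = float(poly(grid.max()))
    except Exception:
        warnings.warn("pi0 smoothing failed; falling back to pi0 = 1")
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        warnings.warn(f"smoothed pi0 = {pi0:.3g} outside (0,1]; falling back to 1")
        pi0 = 1.0
    pi0 = min(pi0, 1.0)
    return Pi0Estimate(grid, raw, pi0)


def storey_q(
    p, lambda_grid=DEFAULT_LAMBDA_GRID, pi0: float | None = None
) -> tuple[np.ndarray, Pi0Estimate]:
    """Storey q-values: π₀-scaled BH-style step-up, monotonized, capped at 1.

    ``pi0`` overrides the smoothed estimate (π₀ = 1 reduces exactly to
    Benjamini–Hochberg adjusted p-values).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidConfigError("p-values must lie in [0,1]")
    if p.size == 0:
        raise InvalidConfigError("storey_q requires at least one p-value")
    est = estimate_pi0(p, lambda_grid)
    if pi0 is not None:
        if not 0 < pi0 <= 1:
            raise InvalidConfigError("pi0 override must lie in (0,1]")
        est = Pi0Estimate(est.lambda_grid, est.raw_pi0, float(pi0))
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = est.pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, est
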