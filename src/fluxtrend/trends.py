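"""Per-site robust trends and cross-site trend summaries.

Each site's annual series gets a Theil-Sen slope (median of all pairwise
slopes, breakdown point ~29%) with a one-tailed Mann-Kendall P value
(H1: trend > 0).  Across sites the module summarizes the sign distribution
(counts, kernel density, bootstrap test of "more increasing than by
chance") and estimates the panel mean trend with a random-slope mixed model
with AR(1) residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMSpec, fit_lmm

__all__ = [
    "TrendEstimate",
    "TrendDistribution",
    "theil_sen",
    "mann_kendall_p",
    "trend_sign_summary",
    "bootstrap_sign_test",
    "kernel_density",
    "mean_trend_lmm",
]


@dataclass
class TrendEstimate:
    """A slope with its SE, one-tailed P (H1: slope > 0) and sample size."""

    slope: float
    slope_se: float
    p_one_tailed: float
    n_years: int
    method: str = "theil_sen"
    intercept: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.p_one_tailed <= 1.0 or math.isnan(self.p_one_tailed)):
            raise ValueError("p_one_tailed outside [0, 1]")


@dataclass
class TrendDistribution:
    trends: list
    kde_grid: np.ndarray
    kde_density: np.ndarray
    frac_positive: float
    boot_p: float = float("nan")


def _mk_statistic(t: np.ndarray, y: np.ndarray) -> tuple:
    """Mann-Kendall S and its tie-corrected variance."""
    n = len(y)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(y[i + 1:] - y[i]) * np.sign(t[i + 1:] - t[i])))
    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var = (n * (n - 1) * (2 * n + 5) - tie_term(y) - tie_term(t)) / 18.0
    return s, var


def _mk_exact_p(t: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """Exact one-tailed P(S >= s_obs) under the permutation null.

    Uses the inversion-count recurrence for Kendall's S; valid only for
    distinct values and distinct times (no ties).
    """
    n = len(y)
    # f[k] = number of permutations of 1..m with k inversions
    f = np.array([1.0])
    for m in range(2, n + 1):
        g = np.convolve(f, np.ones(m))
        f = g
    total_pairs = n * (n - 1) // 2
    # S = total_pairs - 2 * inversions
    s_values = total_pairs - 2 * np.arange(len(f))
    prob = f / f.sum()
    return float(prob[s_values >= s_obs].sum())


def mann_kendall_p(
    t: np.ndarray, y: np.ndarray, method: str = "normal"
) -> float:
    """One-tailed Mann-Kendall P for H1: increasing trend.

    ``method="normal"`` (default) uses the normal approximation with tie
    and continuity corrections; ``"exact"`` enumerates the permutation
    distribution (n <= 10, no ties); ``"auto"`` picks exact when possible.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    s, var = _mk_statistic(t, y)
    n = len(y)
    has_ties = len(np.unique(y)) < n or len(np.unique(t)) < n
    if method == "auto":
        method = "exact" if (n <= 10 and not has_ties) else "normal"
    if method == "exact":
        if n > 10:
            raise ValueError("exact Mann-Kendall limited to n <= 10")
        if has_ties:
            raise ValueError("exact Mann-Kendall requires untied data")
        return _mk_exact_p(t, y, s)
    if var <= 0:
        return 0.5
    if s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    return float(stats.norm.sf(z))


def theil_sen(
    years: Sequence[float],
    values: Sequence[float],
    p_method: str = "normal",
) -> TrendEstimate:
    """Theil-Sen trend of an annual series.

    Slope is the median of all pairwise slopes (pairs with equal years are
    skipped); the SE is the half-width of Sen's 95% confidence interval
    divided by 1.96; P is the one-tailed Mann-Kendall probability of an
    increasing trend.  Pairs with a missing value are dropped.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    if len(y) < 3:
        raise ValueError("Theil-Sen needs at least 3 paired observations")
    if len(np.unique(t)) < 2:
        raise ValueError("all years identical")
    slope, intercept, lo, hi = stats.theilslopes(y, t, alpha=0.95)
    se = (hi - lo) / (2.0 * 1.959963984540054)
    p = mann_kendall_p(t, y, method=p_method)
    return TrendEstimate(
        slope=float(slope),
        slope_se=float(se),
        p_one_tailed=p,
        n_years=int(len(y)),
        method="theil_sen",
        intercept=float(intercept),
    )


def trend_sign_summary(
    trends: Sequence[TrendEstimate], alpha: float = 0.05
) -> dict:
    """Count increasing (slope strictly > 0) and significant sites.

    ``n_significant`` counts one-tailed P < alpha among the increasing
    sites; ``n_significant_all`` over all sites.
    """
    if len(trends) == 0:
        raise ValueError("empty trend list")
    pos = [tr for tr in trends if tr.slope > 0]
    sig_pos = [tr for tr in pos if tr.p_one_tailed < alpha]
    sig_all = [tr for tr in trends if tr.p_one_tailed < alpha]
    return {
        "n_sites": len(trends),
        "n_positive": len(pos),
        "n_nonpositive": len(trends) - len(pos),
        "n_significant": len(sig_pos),
        "n_significant_all": len(sig_all),
        "alpha": alpha,
    }


def bootstrap_sign_test(
    slopes: Sequence[float], B: int = 10000, seed: int = 0,
    method: str = "bootstrap",
) -> float:
    """Test that increasing sites outnumber decreasing ones.

    ``method="bootstrap"`` (default): site slopes are resampled with
    replacement B times; the statistic is the fraction of positive slopes
    in a resample, and the reported P is the proportion of resamples where
    that fraction is <= 0.5 (one-tailed, H1: a majority of sites
    increasing).

    ``method="sign_permutation"``: exact binomial tail — the probability
    of at least the observed number of positive slopes when each sign is
    an independent fair coin.
    """
    slopes = np.asarray(list(slopes), dtype=float)
    n = len(slopes)
    if n < 2:
        raise ValueError("sign test needs at least 2 sites")
    if method == "sign_permutation":
        k = int(np.sum(slopes > 0))
        return float(stats.binom.sf(k - 1, n, 0.5))
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'sign_permutation'")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    pos = (slopes > 0).astype(float)
    draws = rng.integers(0, n, size=(B, n))
    frac = pos[draws].mean(axis=1)
    return float(np.mean(frac <= 0.5))


def kernel_density(
    slopes: Sequence[float],
    bandwidth: Optional[float] = None,
    grid_size: int = 512,
) -> tuple:
    """Gaussian KDE of per-site slopes; returns (grid, density, %positive).

    Bandwidth defaults to Silverman's rule.  The positive share is the
    density mass above zero, as a percentage of the total mass on the grid.
    """
    x = np.asarray(list(slopes), dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("kernel density needs at least 2 distinct slopes")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / x.std(ddof=1))
    bw = kde.factor * x.std(ddof=1)
    lo, hi = x.min() - 4 * bw, x.max() + 4 * bw
    grid = np.linspace(lo, hi, grid_size)
    density = kde(grid)
    total = np.trapezoid(density, grid)
    pos_mass = np.trapezoid(np.where(grid > 0, density, 0.0), grid)
    return grid, density, float(100.0 * pos_mass / total)


def trend_distribution(
    trends: Sequence[TrendEstimate],
    B: int = 10000,
    seed: int = 0,
    bandwidth: Optional[float] = None,
) -> TrendDistribution:
    """Bundle KDE, positive fraction and bootstrap P for a set of trends."""
    slopes = [tr.slope for tr in trends]
    grid, dens, _ = kernel_density(slopes, bandwidth=bandwidth)
    frac = float(np.mean(np.asarray(slopes) > 0))
    boot = bootstrap_sign_test(slopes, B=B, seed=seed)
    return TrendDistribution(
        trends=list(trends),
        kde_grid=grid,
        kde_density=dens,
        frac_positive=frac,
        boot_p=boot,
    )


def mean_trend_lmm(
    panel: pd.DataFrame,
    response: str,
    random_slope: bool = True,
    random_intercept: bool = True,
    ar1: bool = True,
    reml: bool = True,
    multi_start: bool = True,
) -> TrendEstimate:
    """Panel mean trend: fixed year effect with site random intercept and
    slope and AR(1) within-site residuals.

    The one-tailed P uses the large-sample normal ratio of the fixed slope
    to its SE.
    """
    spec = LMMSpec(
        response=response,
        fixed_terms=("year",),
        random_intercept=random_intercept,
        random_slope=random_slope,
        ar1=ar1,
        reml=reml,
    )
    fit = fit_lmm(panel, spec, multi_start=multi_start)
    slope, se = fit.fixed_effect("year")
    p = float(stats.norm.sf(slope / se)) if se > 0 else (0.0 if slope > 0 else 1.0)
    n = int(panel.dropna(subset=[response, "year"]).shape[0])
    return TrendEstimate(
        slope=slope, slope_se=se, p_one_tailed=p, n_years=n, method="lmm"
    )
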