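"""Across-site regression of per-site trends on site characteristics.

Sites differ in climate, deposition load, stand age and structure; this
module asks which of those site-level characteristics explain the spread
of the per-site trends.  The model is ordinary least squares weighted by
the number of observation years per site, built by greedy forward
selection on AICc, screened for collinearity with variance inflation
factors, and summarized with PMVD (proportional marginal variance
decomposition) relative-importance shares.

PMVD averages the sequential R2 increment of each predictor over all
orderings of entry, with data-dependent ordering weights proportional to
the inverse products of the remaining-set increments; unlike the equal-
weight (LMG) average it assigns exactly zero importance to a predictor
whose full-model coefficient is zero, and the shares still sum to the
full-model R2.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SpatialModel",
    "forward_select_wls",
    "vif",
    "pmvd",
    "lmg",
    "expand_predictors",
]

logger = logging.getLogger(__name__)

_VIF_CAP = 1e6


def expand_predictors(
    table: pd.DataFrame, candidates: Sequence
) -> tuple:
    """Expand candidate names to numeric design columns.

    Categorical (object/category/bool) candidates become 0/1 indicator
    columns against the first level in sorted order as reference;
    tuple candidates become product (interaction) columns, their parents
    recorded for marginality.  Returns ``(frame, columns, parents)`` where
    ``parents`` maps an interaction column to its two parent columns.
    """
    work = pd.DataFrame(index=table.index)
    columns: list = []
    parents: dict = {}

    def expand_single(name: str) -> list:
        s = table[name]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(s.dropna().unique())
            cols = []
            for lev in levels[1:]:
                col = f"{name}[{lev}]"
                work[col] = (s == lev).astype(float)
                cols.append(col)
            return cols
        work[name] = s.astype(float)
        return [name]

    single_cols: dict = {}
    for cand in candidates:
        if isinstance(cand, str):
            single_cols[cand] = expand_single(cand)
            columns.extend(single_cols[cand])
    for cand in candidates:
        if not isinstance(cand, str):
            a, b = cand
            for ca in single_cols.get(a) or expand_single(a):
                for cb in single_cols.get(b) or expand_single(b):
                    col = f"{ca}:{cb}"
                    work[col] = work[ca] * work[cb]
                    columns.append(col)
                    parents[col] = (ca, cb)
    return work, columns, parents


def _wls_r2(y, X, w):
    """Weighted R2 of y on X (intercept added), around the weighted mean."""
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.WLS(y, Xc, weights=w).fit()
    mu = np.average(y, weights=w)
    tss = float(np.sum(w * (y - mu) ** 2))
    rss = float(np.sum(w * res.resid**2))
    return 1.0 - rss / tss if tss > 0 else 0.0


def _wls_aicc(y, X, w):
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.WLS(y, Xc, weights=w).fit()
    k = Xc.shape[1] + 1  # coefficients + residual variance
    n = len(y)
    if n - k - 1 <= 0:
        return np.inf
    return float(-2 * res.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class SpatialModel:
    """A selected weighted site-level regression with diagnostics."""

    response: str
    predictors: list
    results: object  # statsmodels WLS results
    weights: np.ndarray
    r2: float
    vif: dict
    importance: dict
    design: pd.DataFrame
    y: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        res = self.results
        return pd.DataFrame(
            {
                "coef": res.params,
                "se": res.bse,
                "p_value": res.pvalues,
            }
        )


def forward_select_wls(
    site_table: pd.DataFrame,
    response: str,
    candidates: Sequence,
    weights: Optional[Sequence[float]] = None,
    compute_importance: bool = True,
    criterion: str = "aicc",
    alpha_enter: float = 0.05,
) -> SpatialModel:
    """Greedy forward selection of a weighted site-level regression.

    Starting from the intercept-only model, repeatedly adds the candidate
    column that most lowers the AICc of the weighted fit (or, with
    ``criterion="p_enter"``, the most significant addition with
    P < ``alpha_enter``), stopping when no addition improves.  Interaction
    candidates (tuples) obey marginality: they only become eligible when
    both parent columns are in.  Perfectly collinear candidates are
    skipped with a log entry.

    Weights default to a column ``n_years`` (observation years per site).
    """
    work = site_table.dropna(subset=[response]).copy()
    if weights is None:
        if "n_years" not in work.columns:
            raise KeyError("no weights given and no n_years column")
        w = work["n_years"].to_numpy(dtype=float)
    else:
        w = np.asarray(list(weights), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    y = work[response].to_numpy(dtype=float)
    design, columns, parents = expand_predictors(work, candidates)
    design = design.fillna(design.mean())

    selected: list = []
    current_score = _wls_aicc(y, design[[]], w) if criterion == "aicc" else None
    while True:
        eligible = []
        for c in columns:
            if c in selected:
                continue
            if c in parents and not all(p in selected for p in parents[c]):
                continue
            if len(selected) + 3 > len(y):
                continue  # keep at least 2 more sites than model terms
            eligible.append(c)
        if not eligible:
            break
        best_col, best_score = None, None
        for c in eligible:
            X = design[selected + [c]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
                logger.info("skipping collinear candidate %s", c)
                continue
            if criterion == "aicc":
                score = _wls_aicc(y, X, w)
            else:
                res = sm.WLS(y, sm.add_constant(X), weights=w).fit()
                score = float(res.pvalues[-1])
            if best_score is None or score < best_score:
                best_col, best_score = c, score
        if best_col is None:
            break
        if criterion == "aicc":
            if best_score >= current_score:
                break
            current_score = best_score
        else:
            if best_score >= alpha_enter:
                break
        selected.append(best_col)

    X = design[selected]
    res = sm.WLS(y, sm.add_constant(X.to_numpy(), has_constant="add"), weights=w).fit()
    r2 = _wls_r2(y, X.to_numpy(), w) if selected else 0.0
    vifs = vif(design[selected], w) if len(selected) >= 1 else {}
    importance = (
        pmvd(y, design[selected], w) if (compute_importance and selected) else {}
    )
    return SpatialModel(
        response=response,
        predictors=selected,
        results=res,
        weights=w,
        r2=r2,
        vif=vifs,
        importance=importance,
        design=design[selected],
        y=y,
    )


def vif(design: pd.DataFrame, weights: Optional[np.ndarray] = None) -> dict:
    """Variance inflation factors of the design columns.

    ``VIF_j = 1/(1 - R2_j)`` from the (weighted) regression of column j on
    the remaining columns.  A single-column design has VIF 1 by
    convention; near-perfect collinearity is capped at 1e6.
    """
    cols = list(design.columns)
    if len(cols) == 1:
        return {cols[0]: 1.0}
    w = np.ones(len(design)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for c in cols:
        others = [o for o in cols if o != c]
        r2 = _wls_r2(design[c].to_numpy(), design[others].to_numpy(), w)
        out[c] = float(min(1.0 / max(1.0 - r2, 1.0 / _VIF_CAP), _VIF_CAP))
    return out


def _subset_r2_table(y, X, w):
    """R2 for every subset of columns, keyed by bitmask."""
    p = X.shape[1]
    r2 = np.zeros(2**p)
    for mask in range(1, 2**p):
        idx = [j for j in range(p) if mask >> j & 1]
        r2[mask] = _wls_r2(y, X[:, idx], w)
    return r2


def pmvd(
    y: Sequence[float],
    design: pd.DataFrame,
    weights: Optional[Sequence[float]] = None,
    tol: float = 1e-10,
) -> dict:
    """PMVD relative-importance shares (exhaustive ordering enumeration).

    The weight of an entry ordering r is proportional to
    ``prod_{i=1}^{p-1} 1 / (R2_full - R2(first i of r))``; orderings that
    exhaust the explainable variance early dominate in the limit, which is
    what gives zero-coefficient predictors exactly zero share.  Shares sum
    to the full-model R2.  Limited to p <= 10 predictors (p! orderings);
    use :func:`lmg` beyond that.
    """
    cols = list(design.columns)
    p = len(cols)
    if p == 0:
        return {}
    if p > 10:
        raise ValueError("PMVD enumeration limited to p <= 10; use lmg()")
    y = np.asarray(list(y), dtype=float)
    X = design.to_numpy(dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(list(weights), dtype=float)
    r2 = _subset_r2_table(y, X, w)
    full = r2[-1]
    if p == 1:
        return {cols[0]: float(full)}
    scale = max(full, tol)

    # group orderings by the number of vanishing remaining-set increments;
    # the group with the most zeros dominates in the limiting weight
    best_zeros = -1
    acc: dict = {}
    total_w = 0.0
    for perm in itertools.permutations(range(p)):
        mask = 0
        zeros = 0
        log_w = 0.0
        factors_ok = True
        prefix_r2 = [0.0] * p
        for i in range(p):
            mask |= 1 << perm[i]
            prefix_r2[i] = r2[mask]
        for i in range(p - 1):
            f = full - prefix_r2[i]
            if f <= tol * scale:
                zeros += 1
            else:
                log_w -= math.log(f)
        if zeros > best_zeros:
            best_zeros = zeros
            acc = {c: 0.0 for c in cols}
            total_w = 0.0
        if zeros == best_zeros:
            wgt = math.exp(log_w)
            total_w += wgt
            prev = 0.0
            for i in range(p):
                inc = prefix_r2[i] - prev
                prev = prefix_r2[i]
                acc[cols[perm[i]]] += wgt * inc
    return {c: float(v / total_w) for c, v in acc.items()}


def lmg(
    y: Sequence[float],
    design: pd.DataFrame,
    weights: Optional[Sequence[float]] = None,
) -> dict:
    """Equal-ordering-weight (LMG) importance shares.

    Provided as the fallback beyond the PMVD enumeration limit; note LMG
    does not have the zero-coefficient exclusion property.
    """
    cols = list(design.columns)
    p = len(cols)
    if p == 0:
        return {}
    y = np.asarray(list(y), dtype=float)
    X = design.to_numpy(dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(list(weights), dtype=float)
    r2 = _subset_r2_table(y, X, w)
    shares = {c: 0.0 for c in cols}
    n_perm = math.factorial(p)
    for perm in itertools.permutations(range(p)):
        mask = 0
        prev = 0.0
        for j in perm:
            mask |= 1 << j
            inc = r2[mask] - prev
            prev = r2[mask]
            shares[cols[j]] += inc / n_perm
    return {c: float(v) for c, v in shares.items()}
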