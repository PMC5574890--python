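"""Linear mixed models with site-level random effects and AR(1) residuals.

The panel analyses in this package repeatedly need one model family: a
Gaussian linear mixed model where each site contributes a random intercept
and a random slope in (centered) year, and within-site residuals follow a
first-order autoregressive process across years.  Neither statsmodels'
``MixedLM`` nor any other installed Python fitter supports the AR(1)
within-group correlation, so the engine is implemented here directly on the
marginal likelihood.

Model, for site *i* with :math:`n_i` annual rows:

.. math::

    y_i = X_i \\beta + Z_i b_i + \\varepsilon_i, \\qquad
    b_i \\sim N(0, G), \\qquad
    \\varepsilon_i \\sim N(0, \\sigma^2 R_i(\\phi))

with :math:`G = \\mathrm{diag}(\\tau_0^2, \\tau_1^2)` (uncorrelated random
intercept and year-slope) and :math:`R_i(\\phi)_{st} = \\phi^{|t_s - t_t|}`
using the absolute year gap, so missing years inside a site are handled by
the continuous-AR1 convention rather than pretending rows are equally
spaced.

Estimation profiles :math:`\\sigma^2` and :math:`\\beta` analytically and
optimizes the remaining relative-variance / correlation parameters
numerically from a fixed set of starting points, so a fit is deterministic
given its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "LMMSpec",
    "LMMFit",
    "fit_lmm",
    "predict_lmm",
    "aicc",
    "normalize_terms",
    "build_design",
]

Term = tuple  # tuple of column names; ("year",) means centered year
TermLike = Union[str, Sequence[str]]

_LOG2PI = math.log(2.0 * math.pi)
#: floor for the profiled residual variance; keeps the likelihood finite on
#: noise-free (exactly linear) inputs.
_SIGMA2_FLOOR = 1e-12

# fixed multi-start grid for the variance-parameter search, in the
# (log g0, log g1, psi) parameterization; chosen once for reproducibility.
_STARTS = (
    (-2.3, -2.3, 0.0),
    (0.7, -4.6, 0.31),
)


def normalize_terms(terms: Sequence[TermLike]) -> list[Term]:
    """Normalize a fixed-effect term list to tuples of column names.

    Strings become 1-tuples (main effects); sequences become interaction
    tuples.  Within a term the factor order is sorted so ``("a","b")`` and
    ``("b","a")`` name the same interaction; duplicates are dropped while
    preserving first-seen order.
    """
    out: list[Term] = []
    for t in terms:
        if isinstance(t, str):
            tt: Term = (t,)
        else:
            tt = tuple(sorted(t))
        if tt not in out:
            out.append(tt)
    return out


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one mixed model on a site-year panel.

    ``fixed_terms`` lists main effects (column names) and interactions
    (tuples of column names); an intercept is always included.  The special
    column name ``"year"`` refers to calendar year centered at the panel
    midpoint (centering only moves the intercept, never the slope).
    """

    response: str
    fixed_terms: tuple = ()
    group: str = "site"
    year: str = "year"
    random_intercept: bool = True
    random_slope: bool = True
    ar1: bool = True
    reml: bool = False

    def terms(self) -> list[Term]:
        return normalize_terms(self.fixed_terms)


@dataclass
class LMMFit:
    """A fitted mixed model (see :func:`fit_lmm`)."""

    spec: LMMSpec
    terms: list
    term_names: list
    beta: np.ndarray
    cov_beta: np.ndarray
    var_intercept: float
    var_slope: float
    phi: float
    sigma2: float
    loglik: float
    n_obs: int
    n_groups: int
    k_params: int
    aicc: float
    converged: bool
    year_center: float
    blups: dict = field(default_factory=dict)

    def fixed_effect(self, name: str) -> tuple:
        """Return (estimate, SE) of a named fixed effect."""
        j = self.term_names.index(name)
        return float(self.beta[j]), float(np.sqrt(self.cov_beta[j, j]))

    @property
    def bic(self) -> float:
        """Bayesian information criterion, ``-2 logL + k log n``."""
        return -2.0 * self.loglik + self.k_params * math.log(self.n_obs)

    def to_dict(self) -> dict:
        """JSON-serializable summary."""
        return {
            "response": self.spec.response,
            "terms": self.term_names,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in np.sqrt(np.diag(self.cov_beta))],
            "var_intercept": self.var_intercept,
            "var_slope": self.var_slope,
            "phi": self.phi,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n_obs": self.n_obs,
            "k_params": self.k_params,
            "reml": self.spec.reml,
            "converged": self.converged,
        }


def build_design(
    df: pd.DataFrame, terms: Sequence[Term], year_center: float, year_col: str = "year"
) -> tuple:
    """Build the fixed-effect design matrix (intercept first).

    Returns ``(X, names)``.  Interaction columns are elementwise products
    of their factors; the pseudo-column ``"year"`` is ``year - year_center``.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for t in terms:
        v = np.ones(n)
        for c in t:
            if c == year_col:
                v = v * (df[year_col].to_numpy(dtype=float) - year_center)
            else:
                v = v * df[c].to_numpy(dtype=float)
        cols.append(v)
        names.append(":".join(t))
    return np.column_stack(cols), names


def _required_columns(spec: LMMSpec) -> list:
    cols = {spec.response, spec.group, spec.year}
    for t in spec.terms():
        cols.update(t)
    return sorted(cols)


def _ar1_corr(phi: float, dy: np.ndarray) -> np.ndarray:
    """AR(1) correlation matrix ``phi**|dyear|`` on a (possibly gapped) grid.

    Year gaps are integers, so a negative ``phi`` is raised to integral
    powers explicitly (``np.power`` with a negative base and float exponent
    would yield NaN).
    """
    if phi == 0.0:
        return np.eye(dy.shape[0])
    if phi > 0.0:
        W = np.power(phi, dy)
    else:
        sign = np.where(np.asarray(dy, dtype=int) % 2 == 0, 1.0, -1.0)
        W = sign * np.power(abs(phi), dy)
    np.fill_diagonal(W, 1.0)
    return W


class _PanelData:
    """Per-site arrays prepared once per fit, padded to a common length.

    Padding rows carry zero design/response and an identity covariance
    block, which leaves every likelihood quantity (log-determinants,
    cross-products) unchanged while letting each objective evaluation run
    as one batched Cholesky/solve over all sites at once.
    """

    def __init__(self, df: pd.DataFrame, spec: LMMSpec):
        cols = _required_columns(spec)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"panel is missing required columns: {missing}")
        work = df.dropna(subset=cols).copy()
        if len(work) == 0:
            raise ValueError("no complete-case rows for the requested model")
        self.year_center = float(work[spec.year].mean())
        X, self.names = build_design(work, spec.terms(), self.year_center, spec.year)
        y = work[spec.response].to_numpy(dtype=float)
        yc = work[spec.year].to_numpy(dtype=float) - self.year_center
        years = work[spec.year].to_numpy(dtype=float)
        self.groups = []
        self.group_keys = []
        for key, idx in work.groupby(spec.group, sort=True).indices.items():
            self.group_keys.append(key)
            self.groups.append(
                (X[idx], y[idx], yc[idx], np.abs(years[idx][:, None] - years[idx][None, :]))
            )
        self.n = len(work)
        self.p = X.shape[1]
        self.n_groups = len(self.groups)

        m = self.n_groups
        nmax = max(len(g[1]) for g in self.groups)
        p = self.p
        self.Xp = np.zeros((m, nmax, p))
        self.yp = np.zeros((m, nmax))
        self.ycp = np.zeros((m, nmax))
        self.dyp = np.zeros((m, nmax, nmax))
        self.pair_mask = np.zeros((m, nmax, nmax), dtype=bool)
        for i, (Xi, yi, yci, dyi) in enumerate(self.groups):
            ni = len(yi)
            self.Xp[i, :ni] = Xi
            self.yp[i, :ni] = yi
            self.ycp[i, :ni] = yci
            self.dyp[i, :ni, :ni] = dyi
            self.pair_mask[i, :ni, :ni] = True
        self.eye_pad = np.broadcast_to(np.eye(nmax), (m, nmax, nmax))
        self.dy_parity = np.where(self.dyp.astype(int) % 2 == 0, 1.0, -1.0)


def _profiled(
    data: _PanelData,
    g0: float,
    g1: float,
    phi: float,
    reml: bool,
) -> tuple:
    """Profile beta and sigma2 at fixed relative variances / correlation.

    Returns ``(neg2ll, beta, XtWiX_inv, sigma2, logdet_sum)`` where W is the
    per-site scaled marginal covariance Z D Z' + R(phi).
    """
    p = data.p
    if phi == 0.0:
        W = np.array(data.eye_pad)
    else:
        if phi > 0:
            A = np.power(phi, data.dyp)
        else:
            A = data.dy_parity * np.power(abs(phi), data.dyp)
        W = np.where(data.pair_mask, A, data.eye_pad)
    if g0 > 0.0:
        W = W + g0 * data.pair_mask
    if g1 > 0.0:
        W = W + g1 * (data.ycp[:, :, None] * data.ycp[:, None, :])
    L = np.linalg.cholesky(W)
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
    rhs = np.concatenate([data.Xp, data.yp[:, :, None]], axis=2)
    sol = np.linalg.solve(W, rhs)
    cross = np.einsum("mij,mik->jk", rhs, sol)
    XtWX = cross[:p, :p]
    XtWy = cross[:p, p]
    ytWy = float(cross[p, p])
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), _SIGMA2_FLOOR)
    n = data.n
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        neg2 = dof * (_LOG2PI + math.log(sigma2)) + logdet + logdet_xtwx + dof
    else:
        sigma2 = rss / n
        neg2 = n * (_LOG2PI + math.log(sigma2)) + logdet + n
    return neg2, beta, np.linalg.inv(XtWX), sigma2, logdet


def fit_lmm(panel: pd.DataFrame, spec: LMMSpec, multi_start: bool = True) -> LMMFit:
    """Fit the mixed model defined by ``spec`` on complete-case rows.

    Rows with a missing value in any referenced column are dropped.  At
    least two sites are required when a random term is on; a single-site
    panel may still be fitted as a plain AR(1)-GLS regression with the
    random terms disabled.

    The relative variance components and the AR(1) correlation are found by
    Nelder-Mead from a fixed grid of starting values (deterministic), with
    :math:`\\sigma^2` and :math:`\\beta` profiled analytically at every step.
    """
    data = _PanelData(panel, spec)
    use_ri = spec.random_intercept
    use_rs = spec.random_slope
    use_ar = spec.ar1
    if (use_ri or use_rs) and data.n_groups < 2:
        raise ValueError("random effects require at least 2 sites")
    for X, y, _, _ in data.groups:
        if len(y) < 1:
            raise ValueError("empty group")

    active = int(use_ri) + int(use_rs) + int(use_ar)

    def unpack(theta):
        i = 0
        g0 = g1 = 0.0
        phi = 0.0
        if use_ri:
            g0 = math.exp(min(theta[i], 20.0))
            i += 1
        if use_rs:
            g1 = math.exp(min(theta[i], 20.0))
            i += 1
        if use_ar:
            phi = 0.99 * math.tanh(theta[i])
        return g0, g1, phi

    converged = True
    if active == 0:
        g0, g1, phi = 0.0, 0.0, 0.0
    else:
        def objective(theta):
            try:
                return _profiled(data, *unpack(theta), spec.reml)[0]
            except np.linalg.LinAlgError:
                return np.inf

        starts = _STARTS if multi_start else _STARTS[:1]
        best = None
        for s in starts:
            x0 = []
            i = 0
            for flag in (use_ri, use_rs):
                if flag:
                    x0.append(s[i])
                i += 1
            if use_ar:
                x0.append(s[2])
            res = minimize(
                objective,
                np.asarray(x0),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400 * max(active, 1)},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success) or best.fun < np.inf
        g0, g1, phi = unpack(best.x)

    neg2, beta, xtwx_inv, sigma2, _ = _profiled(data, g0, g1, phi, spec.reml)
    cov_beta = sigma2 * xtwx_inv
    loglik = -0.5 * neg2

    k = data.p + active + 1  # fixed effects + variance/correlation params + sigma2
    n = data.n
    aicc_val = float("nan")
    if n - k - 1 > 0:
        aic = -2.0 * loglik + 2.0 * k
        aicc_val = aic + 2.0 * k * (k + 1) / (n - k - 1)

    # empirical BLUPs of the site effects, conditional on the variance
    # components (computed in the sigma2-scaled parameterization, which
    # cancels the common factor)
    blups = {}
    D = np.diag([g0, g1])
    for key, (X, y, yc, dy) in zip(data.group_keys, data.groups):
        if not (use_ri or use_rs):
            blups[key] = (0.0, 0.0)
            continue
        W = _ar1_corr(phi, dy) + g0 + g1 * np.outer(yc, yc)
        Z = np.column_stack([np.ones(len(y)), yc])
        resid = y - X @ beta
        b = D @ Z.T @ np.linalg.solve(W, resid)
        blups[key] = (float(b[0]), float(b[1]))

    return LMMFit(
        spec=spec,
        terms=spec.terms(),
        term_names=data.names,
        beta=beta,
        cov_beta=cov_beta,
        var_intercept=float(g0 * sigma2),
        var_slope=float(g1 * sigma2),
        phi=float(phi),
        sigma2=float(sigma2),
        loglik=float(loglik),
        n_obs=n,
        n_groups=data.n_groups,
        k_params=k,
        aicc=aicc_val,
        converged=converged,
        year_center=data.year_center,
        blups=blups,
    )


def predict_lmm(
    fit: LMMFit,
    newdata: pd.DataFrame,
    include_random: bool = False,
) -> pd.DataFrame:
    """Predict the response for ``newdata``.

    Fixed-only prediction is :math:`X\\hat\\beta`; with ``include_random``
    the site BLUPs (intercept + year slope) are added.  Sites unseen during
    fitting get a zero random part and are flagged in the ``unseen_site``
    column.  SEs come from the fixed-effect covariance, conditional on the
    estimated variance components.
    """
    spec = fit.spec
    X, _ = build_design(newdata, fit.terms, fit.year_center, spec.year)
    pred = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X), 0.0))
    unseen = np.zeros(len(newdata), dtype=bool)
    if include_random:
        yc = newdata[spec.year].to_numpy(dtype=float) - fit.year_center
        sites = newdata[spec.group].to_numpy()
        for j, s in enumerate(sites):
            if s in fit.blups:
                b0, b1 = fit.blups[s]
                pred[j] += b0 + b1 * yc[j]
            else:
                unseen[j] = True
    return pd.DataFrame(
        {"prediction": pred, "se": se, "unseen_site": unseen}, index=newdata.index
    )


def profile_loglik(
    panel: pd.DataFrame,
    spec: LMMSpec,
    rel_var_intercept: float = 0.0,
    rel_var_slope: float = 0.0,
    phi: float = 0.0,
) -> float:
    """Profiled log-likelihood at fixed variance/correlation parameters.

    The relative variances are the random-effect variances divided by the
    residual variance; beta and sigma2 are profiled out.  By construction
    the value at any point is <= the log-likelihood of the corresponding
    :func:`fit_lmm` optimum.
    """
    data = _PanelData(panel, spec)
    neg2 = _profiled(data, rel_var_intercept, rel_var_slope, phi, spec.reml)[0]
    return -0.5 * neg2


def aicc(fit: LMMFit) -> float:
    """Second-order Akaike criterion of a fit.

    ``AICc = AIC + 2k(k+1)/(n-k-1)`` with *k* counting fixed effects,
    variance/correlation parameters and the residual variance.  Undefined
    (raises) when ``n <= k + 1``.
    """
    n, k = fit.n_obs, fit.k_params
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    aic = -2.0 * fit.loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)
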