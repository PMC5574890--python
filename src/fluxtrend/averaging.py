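"""AICc multimodel inference over anomaly/interaction mixed models.

The saturated model for a flux (or LAI) anomaly combines four interaction
blocks — {mean S deposition, S anomaly, CO2}, {mean N deposition, N
anomaly, CO2}, {MATc, MAT anomaly, CO2}, {MAPc, SPEI, CO2} — plus the
extra interactions mean S x mean N, MATc x MAPc, and CO2 x stand age; flux
models additionally carry the LAI anomaly as a covariate.  CO2 enters once
as a main effect even though it is listed in every block.

All admissible submodels (marginality: an interaction only with both
parents present) are fitted by maximum likelihood, ranked by AICc, and the
models within ``delta_max`` AICc units of the best are refit by REML and
averaged with Akaike weights, substituting zero for a term's coefficient
in models that exclude it ("full" averaging).  Unconditional SEs use the
revised Burnham-Anderson estimator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import LMMSpec, fit_lmm, normalize_terms, predict_lmm

__all__ = [
    "SaturatedSpec",
    "AveragedModel",
    "saturated_terms",
    "enumerate_models",
    "count_models",
    "rank_models",
    "average_model",
    "fit_model_set",
]

logger = logging.getLogger(__name__)

Term = tuple


@dataclass(frozen=True)
class SaturatedSpec:
    """Term pool of a saturated anomaly model.

    ``mains`` and ``interactions`` are canonical term tuples; build one
    with :func:`saturated_terms` or supply custom pools.
    """

    response: str
    mains: tuple
    interactions: tuple
    marginality: bool = True


def saturated_terms(
    response: str,
    include_lai: bool = True,
    stand_age: bool = True,
) -> SaturatedSpec:
    """The saturated model pool for a flux anomaly response.

    ``include_lai=False`` drops the LAI-anomaly covariate (used when LAI
    itself is the response); ``stand_age=False`` drops the CO2 x stand-age
    interaction for panels without age metadata.
    """
    blocks = [
        ("Sdep_c", "Sdep_an", "CO2_an"),
        ("Ndep_c", "Ndep_an", "CO2_an"),
        ("MAT_c", "MAT_an", "CO2_an"),
        ("MAP_c", "SPEI", "CO2_an"),
    ]
    mains: list = []
    inters: list = []
    for block in blocks:
        for m in block:
            t = (m,)
            if t not in mains:
                mains.append(t)
        for a, b in itertools.combinations(block, 2):
            t = tuple(sorted((a, b)))
            if t not in inters:
                inters.append(t)
    for extra in (("Sdep_c", "Ndep_c"), ("MAT_c", "MAP_c")):
        t = tuple(sorted(extra))
        if t not in inters:
            inters.append(t)
    if stand_age:
        mains.append(("stand_age",))
        inters.append(tuple(sorted(("CO2_an", "stand_age"))))
    if include_lai:
        mains.append(("LAI_max_an",))
    return SaturatedSpec(
        response=response, mains=tuple(mains), interactions=tuple(inters)
    )


def _canonical(spec: SaturatedSpec) -> tuple:
    mains = tuple(sorted(normalize_terms(spec.mains)))
    inters = tuple(sorted(normalize_terms(spec.interactions)))
    return mains, inters


def count_models(spec: SaturatedSpec) -> int:
    """Number of admissible submodels (without materializing them)."""
    mains, inters = _canonical(spec)
    total = 0
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            present = set(subset)
            if spec.marginality:
                allowed = sum(
                    1 for it in inters if all((p,) in present for p in it)
                )
            else:
                allowed = len(inters)
            total += 2**allowed
    return total


def enumerate_models(spec: SaturatedSpec, cap: int = 100000) -> list:
    """All admissible term sets, in a deterministic canonical order.

    Under marginality an interaction is a candidate only when both its
    main effects are in the model.  Raises if the count exceeds ``cap`` —
    constrain the pool (or raise the cap explicitly) instead of silently
    fitting an astronomical model set.
    """
    n = count_models(spec)
    if n > cap:
        raise ValueError(
            f"enumeration would produce {n} models (> cap {cap}); "
            "restrict the term pools or raise cap"
        )
    mains, inters = _canonical(spec)
    models: list = []
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            present = set(subset)
            if spec.marginality:
                allowed = [it for it in inters if all((p,) in present for p in it)]
            else:
                allowed = list(inters)
            for k in range(len(allowed) + 1):
                for ints in itertools.combinations(allowed, k):
                    models.append(tuple(sorted(subset + ints)))
    return models


def fit_model_set(
    panel: pd.DataFrame,
    spec: SaturatedSpec,
    term_sets: Sequence[tuple],
    reml: bool = False,
    **lmm_kwargs,
) -> list:
    """Fit each term set (ML by default, for AICc ranking).

    Returns ``[(terms, fit-or-None), ...]``; non-convergent or failed fits
    carry ``None`` and are logged.
    """
    fits: list = []
    n_failed = 0
    for terms in term_sets:
        mspec = LMMSpec(
            response=spec.response, fixed_terms=terms, reml=reml, **lmm_kwargs
        )
        try:
            fit = fit_lmm(panel, mspec)
            if not (fit.converged and np.isfinite(fit.aicc)):
                fit = None
        except (ValueError, np.linalg.LinAlgError):
            fit = None
        if fit is None:
            n_failed += 1
        fits.append((terms, fit))
    if n_failed:
        logger.info("model set: %d of %d fits excluded", n_failed, len(term_sets))
    return fits


def rank_models(fits: Sequence[tuple]) -> pd.DataFrame:
    """AICc deltas and Akaike weights over the converged fits."""
    rows = [(terms, fit) for terms, fit in fits if fit is not None]
    if not rows:
        raise ValueError("no converged fits to rank")
    aiccs = np.array([fit.aicc for _, fit in rows])
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    out = pd.DataFrame(
        {
            "terms": [t for t, _ in rows],
            "aicc": aiccs,
            "delta": delta,
            "weight": w,
        }
    )
    return out.sort_values("delta", kind="mergesort").reset_index(drop=True)


@dataclass
class AveragedModel:
    """Weighted multimodel coefficient set (full averaging).

    ``coefficients`` rows: term name, averaged estimate (zero substituted
    where absent), unconditional SE, relative importance (summed weight of
    retained models containing the term).
    """

    response: str
    retained: pd.DataFrame  # terms, aicc, delta, weight
    fits: list  # REML refits aligned with retained rows
    coefficients: pd.DataFrame
    delta_max: float

    def predict(self, newdata: pd.DataFrame, include_random: bool = False) -> pd.Series:
        """Weight-averaged prediction across the retained models."""
        pred = np.zeros(len(newdata))
        for w, fit in zip(self.retained["weight"], self.fits):
            pred += w * predict_lmm(fit, newdata, include_random)["prediction"].to_numpy()
        return pd.Series(pred, index=newdata.index, name="prediction")

    def term_estimate(self, name: str) -> tuple:
        row = self.coefficients.loc[self.coefficients["term"] == name]
        if len(row) == 0:
            return 0.0, 0.0
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])

    def has_term(self, column: str) -> bool:
        """Does any retained model reference the given panel column?"""
        for terms in self.retained["terms"]:
            for t in terms:
                if column in t:
                    return True
        return False


def average_model(
    panel: pd.DataFrame,
    spec: SaturatedSpec,
    term_sets: Optional[Sequence[tuple]] = None,
    delta_max: float = 4.0,
    cap: int = 100000,
    conditional: bool = False,
    **lmm_kwargs,
) -> AveragedModel:
    """Enumerate (or take) candidate models, rank by ML-AICc, refit the
    retained set by REML and average.

    Retained set: models with ``delta < delta_max`` relative to the best
    (the best model is always retained), weights renormalized over it.
    Averaged coefficient per term is the weighted mean with zero
    substituted where the term is absent (``conditional=True`` averages
    only over models containing the term instead).  Unconditional SE per
    term follows the revised Burnham-Anderson estimator
    ``sum_m w_m * sqrt(var_m + (beta_m - beta_bar)^2)``.
    """
    if term_sets is None:
        term_sets = enumerate_models(spec, cap=cap)
    ml_fits = fit_model_set(panel, spec, term_sets, reml=False, **lmm_kwargs)
    ranking = rank_models(ml_fits)
    retained = ranking[ranking["delta"] < delta_max].copy()
    retained["weight"] = retained["weight"] / retained["weight"].sum()

    reml_fits: list = []
    for terms in retained["terms"]:
        mspec = LMMSpec(response=spec.response, fixed_terms=terms, reml=True, **lmm_kwargs)
        reml_fits.append(fit_lmm(panel, mspec))

    # collect the union of term names across retained models
    all_names: list = []
    for fit in reml_fits:
        for nm in fit.term_names:
            if nm not in all_names:
                all_names.append(nm)

    rows = []
    weights = retained["weight"].to_numpy()
    for nm in all_names:
        betas = np.zeros(len(reml_fits))
        variances = np.zeros(len(reml_fits))
        present = np.zeros(len(reml_fits), dtype=bool)
        for j, fit in enumerate(reml_fits):
            if nm in fit.term_names:
                i = fit.term_names.index(nm)
                betas[j] = fit.beta[i]
                variances[j] = fit.cov_beta[i, i]
                present[j] = True
        importance = float(weights[present].sum())
        if conditional:
            wsel = weights[present] / weights[present].sum()
            est = float(wsel @ betas[present])
            se = float(
                wsel @ np.sqrt(variances[present] + (betas[present] - est) ** 2)
            )
        else:
            est = float(weights @ betas)
            se = float(weights @ np.sqrt(variances + (betas - est) ** 2))
        rows.append({"term": nm, "estimate": est, "se": se, "importance": importance})

    coef = pd.DataFrame(rows, columns=["term", "estimate", "se", "importance"])
    return AveragedModel(
        response=spec.response,
        retained=retained.reset_index(drop=True),
        fits=reml_fits,
        coefficients=coef,
        delta_max=delta_max,
    )
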