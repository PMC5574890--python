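"""Counterfactual attribution of response trends to individual drivers.

The averaged model predicts the response over the panel twice: once with
all covariates as observed, and once with one temporal driver (CO2, S/N
deposition anomaly, MAT anomaly, SPEI, LAI anomaly) replaced, per site, by
that site's median value.  Both prediction series get a mixed-model trend
(random slopes, AR(1)); the difference of the two trends is the driver's
temporal contribution to the response trend.  The part of the observed
trend not accounted for by any driver is the "unknown" contribution, and a
driver's sensitivity is its contribution divided by the driver's own
trend, with first-order error propagation throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .averaging import AveragedModel
from .trends import TrendEstimate, mean_trend_lmm

__all__ = [
    "ContributionRecord",
    "AttributionResult",
    "SensitivityRecord",
    "contribution",
    "decompose",
    "sensitivity",
    "offset_ratio",
]


@dataclass
class ContributionRecord:
    """Temporal contribution of one driver to the response trend."""

    driver: str
    contribution: float
    contribution_se: float
    p_value: float  # two-sided normal P that the contribution differs from 0
    held_constant: bool = True


@dataclass
class AttributionResult:
    observed_trend: float
    observed_se: float
    model_trend: float
    model_se: float
    contributions: list
    unknown: float
    unknown_se: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "driver": c.driver,
                "contribution": c.contribution,
                "se": c.contribution_se,
                "p_value": c.p_value,
            }
            for c in self.contributions
        ]
        rows.append(
            {
                "driver": "unknown",
                "contribution": self.unknown,
                "se": self.unknown_se,
                "p_value": float("nan"),
            }
        )
        return pd.DataFrame(rows)


@dataclass
class SensitivityRecord:
    """Contribution divided by the driver's own trend."""

    driver: str
    sensitivity: float
    sensitivity_se: float
    p_value: float  # one-sided normal P for the sign of the sensitivity
    driver_trend: float
    driver_trend_se: float


def _two_sided_p(est: float, se: float) -> float:
    if se <= 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def _prediction_trend(
    avg_model: AveragedModel,
    panel: pd.DataFrame,
    include_random: bool,
    **trend_kwargs,
) -> TrendEstimate:
    work = panel.copy()
    work["_pred"] = avg_model.predict(work, include_random=include_random)
    return mean_trend_lmm(work, "_pred", **trend_kwargs)


def contribution(
    avg_model: AveragedModel,
    panel: pd.DataFrame,
    driver: str,
    include_random: bool = True,
    full_trend: Optional[TrendEstimate] = None,
    **trend_kwargs,
) -> ContributionRecord:
    """Contribution of ``driver`` (a panel column) to the response trend.

    Predicts with the averaged model over the panel, then again with the
    driver column replaced by its per-site median, and differences the two
    mixed-model trends.  The SE combines the two trend SEs as independent
    (conservative).  A driver absent from every retained model contributes
    exactly zero with zero SE (flagged ``held_constant=False``).

    ``full_trend`` lets :func:`decompose` reuse the full-model trend fit.
    """
    if driver not in panel.columns:
        raise KeyError(f"driver column {driver!r} not in panel")
    if not avg_model.has_term(driver):
        return ContributionRecord(
            driver=driver, contribution=0.0, contribution_se=0.0,
            p_value=1.0, held_constant=False,
        )
    if full_trend is None:
        full_trend = _prediction_trend(avg_model, panel, include_random, **trend_kwargs)
    held = panel.copy()
    held[driver] = held.groupby("site")[driver].transform("median")
    held_trend = _prediction_trend(avg_model, held, include_random, **trend_kwargs)
    est = full_trend.slope - held_trend.slope
    se = math.hypot(full_trend.slope_se, held_trend.slope_se)
    return ContributionRecord(
        driver=driver,
        contribution=float(est),
        contribution_se=float(se),
        p_value=_two_sided_p(est, se),
    )


def decompose(
    avg_model: AveragedModel,
    panel: pd.DataFrame,
    drivers: Sequence[str],
    response: Optional[str] = None,
    include_random: bool = True,
    **trend_kwargs,
) -> AttributionResult:
    """Full decomposition: observed trend, per-driver contributions, and
    the unknown remainder.

    ``unknown = observed - sum(contributions)`` holds exactly by
    construction; its SE treats the terms as independent.  The observed
    trend comes from the data (mixed model on the response column); the
    full-model predicted trend is also reported so the two can be
    compared.
    """
    response = response or avg_model.response
    observed = mean_trend_lmm(panel, response, **trend_kwargs)
    full_trend = _prediction_trend(avg_model, panel, include_random, **trend_kwargs)
    contribs = [
        contribution(
            avg_model, panel, d,
            include_random=include_random,
            full_trend=full_trend,
            **trend_kwargs,
        )
        for d in drivers
    ]
    total = sum(c.contribution for c in contribs)
    unknown = observed.slope - total
    unknown_se = math.sqrt(
        observed.slope_se**2 + sum(c.contribution_se**2 for c in contribs)
    )
    return AttributionResult(
        observed_trend=float(observed.slope),
        observed_se=float(observed.slope_se),
        model_trend=float(full_trend.slope),
        model_se=float(full_trend.slope_se),
        contributions=contribs,
        unknown=float(unknown),
        unknown_se=float(unknown_se),
    )


def sensitivity(
    contrib: ContributionRecord, driver_trend: TrendEstimate
) -> SensitivityRecord:
    """Sensitivity = contribution / driver trend, with quotient-rule SE.

    For contribution c +/- sc and driver trend t +/- st (t != 0):
    ``s = c/t`` and ``se = |s| * sqrt((sc/c)^2 + (st/t)^2)`` assuming
    independence; when c = 0 the SE degenerates to ``sc/|t|``.
    """
    t, st = driver_trend.slope, driver_trend.slope_se
    if t == 0:
        raise ZeroDivisionError("driver trend is zero; sensitivity undefined")
    c, sc = contrib.contribution, contrib.contribution_se
    s = c / t
    if c == 0:
        se = sc / abs(t)
    else:
        se = abs(s) * math.sqrt((sc / c) ** 2 + (st / t) ** 2)
    p = float(stats.norm.sf(abs(s) / se)) if se > 0 else (1.0 if s == 0 else 0.0)
    return SensitivityRecord(
        driver=contrib.driver,
        sensitivity=float(s),
        sensitivity_se=float(se),
        p_value=p,
        driver_trend=float(t),
        driver_trend_se=float(st),
    )


def offset_ratio(
    contrib_a: ContributionRecord, contrib_b: ContributionRecord
) -> tuple:
    """How much of contribution b is offset by (opposing) contribution a.

    Returns ``(percentage, se)`` where percentage = 100*|a/b|, with
    quotient-rule error propagation; the sign convention (a opposing b) is
    the caller's to interpret.  Undefined when b = 0.
    """
    a, sa = contrib_a.contribution, contrib_a.contribution_se
    b, sb = contrib_b.contribution, contrib_b.contribution_se
    if b == 0:
        raise ZeroDivisionError("reference contribution is zero")
    ratio = 100.0 * abs(a / b)
    if a == 0:
        se = 100.0 * sa / abs(b)
    else:
        se = ratio * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    return float(ratio), float(se)
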