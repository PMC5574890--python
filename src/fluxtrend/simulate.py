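"""Synthetic multi-site annual flux panels with known ground truth.

The generator emulates the statistical structure of a network of 23
temperate/boreal eddy-covariance forests observed for 10-20 years each
between 1992 and 2013: a shared atmospheric CO2 series rising ~2 ppm yr-1,
site-specific wet S and N deposition declining multiplicatively (~4.6% and
~1.1% per year), stationary AR(1) climate (MAT, SPEI), and annual fluxes
(NEP, GPP, Re) plus maximum LAI responding linearly to driver anomalies
with configurable true sensitivities, site random intercepts/slopes and
AR(1) residual noise.

Because the generator is linear with no interactions, the ground-truth
contribution of driver j to a response trend is exactly
``true_beta[j] * realized mean trend of driver j``, which is what the
attribution machinery is tested against.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticPanel",
    "generate_drivers",
    "generate_fluxes",
    "generate_panel",
    "published_trends_fixture",
]

#: driver key -> panel column
DRIVER_COLUMNS = {
    "CO2": "CO2",
    "Sdep": "Sdep",
    "Ndep": "Ndep",
    "MAT": "MAT",
    "SPEI": "SPEI",
    "LAI": "LAI_max",
}

RESPONSES = ("NEP", "GPP", "Re", "LAI_max")


def _default_true_beta() -> dict:
    # flux sensitivities in g C m-2 yr-1 per driver unit; central published
    # estimates for a 23-forest network (CO2 in ppm, deposition in
    # kg ha-1 yr-1, MAT in degC, SPEI in SD, LAI in m2 m-2)
    return {
        "NEP": {"CO2": 4.8, "Sdep": 24.0, "Ndep": 0.0, "MAT": 0.0, "SPEI": 0.0},
        "GPP": {"CO2": 4.49, "Sdep": -31.24, "Ndep": 14.41, "MAT": 0.0, "SPEI": 0.0},
        "Re": {"CO2": -0.29, "Sdep": -74.01, "Ndep": 15.62, "MAT": 0.0, "SPEI": 0.0},
        "LAI_max": {"CO2": 0.008, "Sdep": 0.05, "Ndep": 0.0, "MAT": 0.0, "SPEI": 0.0},
    }


def _default_level_ranges() -> dict:
    return {
        "NEP": (100.0, 700.0),
        "GPP": (900.0, 2000.0),
        "Re": (700.0, 1500.0),
        "LAI_max": (2.0, 6.0),
    }


def _default_random_slope_sd() -> dict:
    return {"NEP": 5.0, "GPP": 7.0, "Re": 7.0, "LAI_max": 0.01}


def _default_resid_sd() -> dict:
    return {"NEP": 25.0, "GPP": 35.0, "Re": 35.0, "LAI_max": 0.15}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic network.

    Defaults mirror the observed conditions: 23 sites, series of 10-20
    years within 1992-2013, CO2 +2.0 ppm yr-1, S deposition -4.6% yr-1,
    N deposition -1.1% yr-1, stationary MAT/SPEI.  Within-site flux noise
    magnitudes are not published for such networks; the defaults here
    (documented in the methods note) give trend SEs of the same order as
    the published per-site trend tables.
    """

    n_sites: int = 23
    year_range: tuple = (1992, 2013)
    site_span: tuple = (10, 20)
    co2_start: float = 356.0
    co2_trend: float = 2.0
    co2_noise_sd: float = 0.4
    sdep_site_means: tuple = (1.0, 3.0)
    sdep_rel_trend: float = -0.046
    ndep_site_means: tuple = (4.0, 12.0)
    ndep_rel_trend: float = -0.011
    dep_noise_cv: float = 0.05
    dep_decline: str = "geometric"  # or "linear"
    mat_site_means: tuple = (2.0, 12.0)
    mat_sd: float = 0.7
    map_site_means: tuple = (500.0, 1500.0)
    map_cv: float = 0.1
    spei_sd: float = 1.0
    climate_ar1: float = 0.3
    true_beta: dict = field(default_factory=_default_true_beta)
    level_ranges: dict = field(default_factory=_default_level_ranges)
    random_intercept_sd: float = 60.0
    random_slope_sd: dict = field(default_factory=_default_random_slope_sd)
    resid_sd: dict = field(default_factory=_default_resid_sd)
    resid_ar1: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not abs(self.resid_ar1) < 1:
            raise ValueError("resid_ar1 must satisfy |resid_ar1| < 1")
        if not abs(self.climate_ar1) < 1:
            raise ValueError("climate_ar1 must satisfy |climate_ar1| < 1")
        if self.site_span[0] < 3:
            raise ValueError("site_span minimum must be >= 3")
        if self.site_span[0] > self.site_span[1]:
            raise ValueError("site_span must be (min, max) with min <= max")
        span_years = self.year_range[1] - self.year_range[0] + 1
        if self.site_span[1] > span_years:
            raise ValueError("site_span maximum exceeds year_range length")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        for name, d in (("random_slope_sd", self.random_slope_sd),
                        ("resid_sd", self.resid_sd)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] must be >= 0")
        if self.dep_decline not in ("geometric", "linear"):
            raise ValueError("dep_decline must be 'geometric' or 'linear'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPanel:
    """A generated panel plus the hidden ground truth.

    ``truth`` maps each response to per-driver true contributions to the
    mean response trend (beta_j times the realized mean within-site OLS
    trend of driver j) and the deterministic mean trend; ``site_effects``
    holds the drawn random intercepts/slopes per response and site.
    """

    panel: pd.DataFrame
    config: SimulationConfig
    truth: dict
    site_effects: dict


def _site_layout(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Contiguous year block per site, placed within year_range."""
    y0, y1 = cfg.year_range
    layout = {}
    for i in range(cfg.n_sites):
        span = int(rng.integers(cfg.site_span[0], cfg.site_span[1] + 1))
        start = int(rng.integers(y0, y1 - span + 2))
        layout[f"S{i + 1:02d}"] = np.arange(start, start + span)
    return layout


def _ar1_series(rng, n, sd, rho):
    """Stationary AR(1) series, marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def generate_drivers(config: SimulationConfig) -> pd.DataFrame:
    """Generate the driver columns of a synthetic panel.

    CO2 is one shared ramp (start + trend*(year - first year) + noise) for
    all sites; S and N deposition decline from site-specific starting means
    at the configured relative rates (geometric by default, optionally
    linear); MAT and SPEI are stationary AR(1) around site means; MAP is
    stationary noise around site means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    all_years = np.arange(y0, y1 + 1)
    co2_global = (
        config.co2_start
        + config.co2_trend * (all_years - y0)
        + rng.normal(0.0, config.co2_noise_sd, size=len(all_years))
    )
    co2_by_year = dict(zip(all_years, co2_global))

    layout = _site_layout(config, rng)
    rows = []
    for site, years in layout.items():
        n = len(years)
        t_local = years - years[0]
        sdep0 = rng.uniform(*config.sdep_site_means)
        ndep0 = rng.uniform(*config.ndep_site_means)
        if config.dep_decline == "geometric":
            sdep = sdep0 * (1.0 + config.sdep_rel_trend) ** t_local
            ndep = ndep0 * (1.0 + config.ndep_rel_trend) ** t_local
        else:
            sdep = sdep0 * (1.0 + config.sdep_rel_trend * t_local)
            ndep = ndep0 * (1.0 + config.ndep_rel_trend * t_local)
        if config.dep_noise_cv > 0:
            sdep = sdep * np.exp(rng.normal(0.0, config.dep_noise_cv, n))
            ndep = ndep * np.exp(rng.normal(0.0, config.dep_noise_cv, n))
        mat = rng.uniform(*config.mat_site_means) + _ar1_series(
            rng, n, config.mat_sd, config.climate_ar1
        )
        spei = _ar1_series(rng, n, config.spei_sd, config.climate_ar1)
        map_mean = rng.uniform(*config.map_site_means)
        mapv = map_mean * (1.0 + rng.normal(0.0, config.map_cv, n))
        for j, yr in enumerate(years):
            rows.append(
                {
                    "site": site,
                    "year": int(yr),
                    "CO2": co2_by_year[yr],
                    "Sdep": sdep[j],
                    "Ndep": ndep[j],
                    "MAT": mat[j],
                    "MAP": mapv[j],
                    "SPEI": spei[j],
                }
            )
    return pd.DataFrame(rows)


def _ols_slope(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def generate_fluxes(
    config: SimulationConfig, drivers: pd.DataFrame
) -> SyntheticPanel:
    """Add flux and LAI responses to a driver panel.

    Per site, the response anomaly is the sum of ``true_beta[driver] *
    driver anomaly`` over drivers, plus a site random intercept, a site
    random slope in (year - site midyear), and AR(1) residual noise; the
    reported column is site base level + anomaly.  LAI is generated first
    (its own betas) so flux responses may also load on the LAI anomaly via
    ``true_beta[response]["LAI"]``.
    """
    config.validate()
    if len(drivers) == 0:
        raise ValueError("empty driver panel")
    y0, y1 = config.year_range
    if drivers["year"].min() < y0 or drivers["year"].max() > y1:
        raise ValueError("driver panel years fall outside the configured year_range")
    if drivers["site"].nunique() != config.n_sites:
        raise ValueError(
            f"driver panel has {drivers['site'].nunique()} sites, "
            f"config expects {config.n_sites}"
        )
    rng = np.random.default_rng(int(config.seed) + 1)
    panel = drivers.sort_values(["site", "year"]).reset_index(drop=True)

    # per-site driver anomalies (value minus site mean over observed years)
    anomalies = {}
    for key, col in DRIVER_COLUMNS.items():
        if col not in panel.columns:
            continue
        anomalies[key] = panel[col] - panel.groupby("site")[col].transform("mean")

    site_effects: dict = {}
    truth: dict = {}
    # generate LAI first so flux responses can use its anomaly
    order = ["LAI_max", "NEP", "GPP", "Re"]
    for resp in order:
        betas = config.true_beta.get(resp, {})
        lo, hi = config.level_ranges[resp]
        slope_sd = config.random_slope_sd[resp]
        resid_sd = config.resid_sd[resp]
        int_sd = config.random_intercept_sd if resp != "LAI_max" else 0.5
        values = np.empty(len(panel))
        effects = {}
        deterministic = np.zeros(len(panel))
        for drv, beta in betas.items():
            if beta == 0.0 or drv not in anomalies:
                continue
            deterministic += beta * anomalies[drv].to_numpy()
        for site, idx in panel.groupby("site").indices.items():
            years = panel.loc[idx, "year"].to_numpy(dtype=float)
            base = rng.uniform(lo, hi)
            b0 = rng.normal(0.0, int_sd)
            b1 = rng.normal(0.0, slope_sd)
            noise = _ar1_series(rng, len(idx), resid_sd, config.resid_ar1)
            yc = years - years.mean()
            values[idx] = base + b0 + b1 * yc + deterministic[idx] + noise
            effects[site] = {"intercept": b0, "slope": b1, "base_level": base}
        panel[resp] = values
        site_effects[resp] = effects

        # ground truth: per-driver contribution = beta * mean realized trend
        contrib = {}
        mean_slope_total = 0.0
        for drv, beta in betas.items():
            col = DRIVER_COLUMNS[drv]
            if col not in panel.columns:
                continue
            site_slopes = [
                _ols_slope(g["year"], g[col]) for _, g in panel.groupby("site")
            ]
            contrib[drv] = beta * float(np.mean(site_slopes))
        truth[resp] = {
            "contributions": contrib,
            "deterministic_trend": float(np.sum(list(contrib.values()))),
            "beta": dict(betas),
        }
        if resp == "LAI_max":
            # refresh LAI anomaly now that the column exists
            anomalies["LAI"] = panel["LAI_max"] - panel.groupby("site")[
                "LAI_max"
            ].transform("mean")

    cols = ["site", "year", "NEP", "GPP", "Re", "LAI_max", "CO2", "Ndep",
            "Sdep", "MAT", "MAP", "SPEI"]
    panel = panel[cols]
    return SyntheticPanel(
        panel=panel, config=config, truth=truth, site_effects=site_effects
    )


def generate_panel(config: Optional[SimulationConfig] = None) -> SyntheticPanel:
    """Convenience: drivers + fluxes in one call."""
    cfg = config or SimulationConfig()
    return generate_fluxes(cfg, generate_drivers(cfg))


def published_trends_fixture() -> pd.DataFrame:
    """Published per-site characteristics and Theil-Sen trends (23 forests).

    Columns: forest, code, climate, forest_type, stand_age,
    logging_maturity_age, corrected_maturity_age, initial_year, final_year,
    n_years, and for each of NEP/GPP/Re/LAI the trend, its SE and the
    one-tailed P.  The LAI trend is missing (not zero) for the one site
    without a usable LAI series.
    """
    ref = importlib.resources.files("fluxtrend").joinpath("data/published_site_trends.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
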