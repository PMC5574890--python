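"""Site-year panel IO and preprocessing.

A panel is a tidy table with one row per (site, year): carbon fluxes (NEP,
GPP, Re in g C m-2 yr-1), maximum LAI (m2 m-2), atmospheric CO2 (ppm), wet
N and S deposition (kg ha-1 yr-1) and climate (MAT degC, MAP mm, SPEI).
Anomaly columns carry the suffix ``_an`` and site-mean columns ``_c``; the
anomaly convention throughout is

    anomaly = annual value - site mean over that site's observed years

so per-site anomalies of a complete column sum to zero.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "DEFAULT_COLUMNS",
    "read_panel",
    "write_panel",
    "compute_anomalies",
    "qc_fill_co2",
    "corrected_maturity_age",
    "cumulative_deposition",
    "warm_season_aggregate",
    "site_summary",
]

#: canonical panel columns; ``read_panel`` requires site and year plus any
#: subset the caller asks for.
DEFAULT_COLUMNS = [
    "site",
    "year",
    "NEP",
    "GPP",
    "Re",
    "LAI_max",
    "CO2",
    "Ndep",
    "Sdep",
    "MAT",
    "MAP",
    "SPEI",
]

ANOMALY_SUFFIX = "_an"
SITEMEAN_SUFFIX = "_c"


def read_panel(
    path,
    sep: str = ",",
    required: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read a delimited panel file, validating structure.

    Requires a header row; ``required`` defaults to ``["site", "year"]``.
    Raises ``KeyError`` naming any missing required column and
    ``ValueError`` listing duplicated (site, year) pairs.  Unknown columns
    are preserved.
    """
    df = pd.read_csv(path, sep=sep)
    required = list(required) if required is not None else ["site", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"panel file {path} is missing required columns: {missing}")
    if "year" in df.columns:
        years = df["year"]
        if not np.allclose(years, np.round(years), equal_nan=True):
            raise ValueError("year column must be integral")
        df["year"] = years.astype(int)
    dup = df.duplicated(subset=["site", "year"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["site", "year"]].drop_duplicates()
        pairs = [f"({r.site}, {r.year})" for r in offenders.itertuples()]
        raise ValueError(f"duplicate (site, year) rows: {', '.join(pairs)}")
    return df


def write_panel(panel: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a panel to delimited text at full float precision."""
    panel.to_csv(path, sep=sep, index=False)


def compute_anomalies(
    panel: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Add site-mean (``_c``) and anomaly (``_an``) columns.

    The site mean is taken over that site's observed (non-missing) years;
    missing cells are excluded from the mean and stay missing in the
    anomaly column.  A column that is entirely missing for a site yields
    missing mean and anomalies (never zero).
    """
    out = panel.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in panel")
        means = out.groupby("site")[col].transform("mean")
        out[col + SITEMEAN_SUFFIX] = means
        out[col + ANOMALY_SUFFIX] = out[col] - means
    return out


def corrected_maturity_age(stand_age: float, logging_maturity_age: float) -> float:
    """Stand age divided by the species' logging maturity age.

    A stand-development index: values above 1 indicate stands older than
    their usual logging maturity.  Reported to 2 decimals in tabular
    output; full precision returned here.
    """
    if not (stand_age > 0 and logging_maturity_age > 0):
        raise ValueError("stand_age and logging_maturity_age must be > 0")
    return stand_age / logging_maturity_age


def _attribute_descents(years: np.ndarray, values: np.ndarray) -> set:
    """Pick the culprit index for every descending year-over-year pair.

    Annual background CO2 grows monotonically, so within a descending pair
    the implausible member is the local extremum: a value below both
    neighbours (a dip) or above both (a spike).  When neither neighbour
    exists (series edge) the single available comparison decides; the
    default attribution for an interior descent with no clear extremum is
    the value that dropped below its predecessor.
    """
    n = len(values)
    flagged: set = set()
    for k in range(n - 1):
        if values[k + 1] >= values[k]:
            continue
        lo, hi = k + 1, k  # lower member, upper member of the descent
        lo_is_dip = lo < n - 1 and values[lo] < values[lo + 1]
        hi_is_spike = hi > 0 and values[hi] > values[hi - 1]
        if lo_is_dip:
            flagged.add(lo)
        elif hi_is_spike:
            flagged.add(hi)
        elif hi == 0 and lo + 1 < n and values[hi] > values[lo + 1]:
            # leading value sits above the next two years: a start spike
            flagged.add(hi)
        else:
            # default: blame the value that dropped below its predecessor
            flagged.add(lo)
    return flagged


def qc_fill_co2(
    series: pd.Series,
    reference: Optional[pd.Series] = None,
    normal_increase: float = 2.0,
    jump_factor: float = 3.0,
) -> tuple:
    """QC an annual CO2 series and gap-fill the removed values.

    A value is implausible when it breaks the expected monotone growth of
    background CO2 (it is lower than the previous year's value or higher
    than the next year's, attributed to the local dip/spike) or when its
    year-over-year increase exceeds ``jump_factor`` times the normal
    increase of ~2 ppm per year.  Flagged values are removed, then filled
    by a penalized smoothing spline (smoothing chosen by generalized
    cross-validation) fitted to the retained values; with fewer than 4
    retained points the fill falls back to linear interpolation between
    retained neighbours, then to the supplied reference series, else the
    value stays missing.

    Parameters
    ----------
    series : pd.Series
        Annual CO2 (ppm) indexed by integer year; gaps allowed.
    reference : pd.Series, optional
        Global background series (e.g. Mauna Loa) indexed by year.

    Returns
    -------
    (filled, flags) : (pd.Series, pd.DataFrame)
        ``flags`` has columns ``year``, ``reason`` with one row per flagged
        or unfillable year.
    """
    s = series.sort_index()
    obs = s.dropna()
    years = obs.index.to_numpy(dtype=float)
    vals = obs.to_numpy(dtype=float)
    flags: list = []

    flagged_idx = _attribute_descents(years, vals)
    for k in flagged_idx:
        flags.append({"year": int(years[k]), "reason": "breaks monotone growth"})
    # jump rule, measured against the previous retained (unflagged) value so
    # that the recovery after a flagged dip does not itself get flagged
    for k in range(1, len(vals)):
        if k in flagged_idx:
            continue
        prev = k - 1
        while prev >= 0 and prev in flagged_idx:
            prev -= 1
        if prev < 0:
            continue
        gap = years[k] - years[prev]
        if (vals[k] - vals[prev]) / gap > jump_factor * normal_increase:
            flags.append({"year": int(years[k]), "reason": "excessive increase"})
            flagged_idx.add(k)

    keep = np.array([k for k in range(len(vals)) if k not in flagged_idx], dtype=int)
    filled = s.copy()
    to_fill = [int(years[k]) for k in flagged_idx]
    to_fill += [int(y) for y in s.index[s.isna()]]
    for y in sorted(set(to_fill)):
        filled.loc[y] = np.nan
        value = np.nan
        if len(keep) >= 4:
            spl = make_smoothing_spline(years[keep], vals[keep])
            value = float(spl(float(y)))
        elif len(keep) >= 2:
            ky, kv = years[keep], vals[keep]
            if ky.min() < y < ky.max():
                value = float(np.interp(float(y), ky, kv))
        if math.isnan(value) and reference is not None and y in reference.index:
            ref_val = reference.loc[y]
            if not pd.isna(ref_val):
                value = float(ref_val)
                flags.append({"year": int(y), "reason": "filled from reference"})
        if math.isnan(value):
            flags.append({"year": int(y), "reason": "unfilled"})
        else:
            filled.loc[y] = value

    flags_df = pd.DataFrame(flags, columns=["year", "reason"]).drop_duplicates()
    return filled, flags_df.reset_index(drop=True)


def cumulative_deposition(
    panel: pd.DataFrame,
    column: str,
    window: int = 5,
    mode: str = "strict",
) -> pd.DataFrame:
    """Add a past-deposition column: sum over the previous ``window`` years.

    For year t the new column ``{column}_cum{window}`` sums the column over
    years t-window .. t-1 within the site.  Under ``mode="strict"`` the sum
    is missing when any contributing year is absent or missing; under
    ``"lenient"`` it is the sum of whatever is available (missing only when
    nothing is).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    out = panel.copy()
    new_col = f"{column}_cum{window}"
    out[new_col] = np.nan
    for site, grp in panel.groupby("site"):
        by_year = grp.set_index("year")[column]
        for idx, row in grp.iterrows():
            yrs = range(int(row["year"]) - window, int(row["year"]))
            vals = [by_year.get(y, np.nan) for y in yrs]
            arr = np.asarray(vals, dtype=float)
            if mode == "strict":
                if not np.isnan(arr).any():
                    out.loc[idx, new_col] = arr.sum()
            else:
                if not np.isnan(arr).all():
                    out.loc[idx, new_col] = np.nansum(arr)
    return out


def warm_season_aggregate(
    monthly: pd.DataFrame,
    min_fraction: float = 1.0,
    months: Sequence[int] = range(4, 10),
) -> pd.DataFrame:
    """Aggregate monthly climate records to warm-season annual values.

    April-September (inclusive) of the same calendar year: MAT and SPEI
    are averaged, MAP is summed.  A year's value is missing unless at
    least ``min_fraction`` of the warm-season months are present for that
    variable.  Expects columns ``year``, ``month`` plus any of ``MAT``,
    ``MAP``, ``SPEI``; a ``site`` column, if present, is part of the key.
    """
    months = set(int(m) for m in months)
    need = math.ceil(min_fraction * len(months))
    keys = ["site", "year"] if "site" in monthly.columns else ["year"]
    warm = monthly[monthly["month"].isin(months)]
    rows = []
    for key, grp in warm.groupby(keys):
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        for col, how in (("MAT", "mean"), ("SPEI", "mean"), ("MAP", "sum")):
            if col not in grp.columns:
                continue
            v = grp[col].dropna()
            rec[f"{col}_warm"] = getattr(v, how)() if len(v) >= need else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def site_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-site coverage: first/last year and row count (n_years)."""
    g = panel.groupby("site")["year"]
    return pd.DataFrame(
        {
            "initial_year": g.min(),
            "final_year": g.max(),
            "n_years": g.count(),
        }
    ).reset_index()
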