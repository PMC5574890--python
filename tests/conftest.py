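import numpy as np
import pandas as pd
import pytest

import fluxtrend as ft
from fluxtrend.panel import compute_anomalies


@pytest.fixture(scope="session")
def synth():
    """One seeded synthetic panel shared across tests."""
    return ft.generate_panel(ft.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def anomaly_panel(synth):
    return compute_anomalies(
        synth.panel, ["NEP", "GPP", "Re", "LAI_max", "CO2", "Sdep", "Ndep", "MAT", "SPEI"]
    )


@pytest.fixture(scope="session")
def published_trends():
    return ft.published_trends_fixture()


@pytest.fixture()
def toy_panel():
    """Two sites, three years, hand-checkable values."""
    return pd.DataFrame(
        {
            "site": ["A"] * 3 + ["B"] * 3,
            "year": [2000, 2001, 2002] * 2,
            "NEP": [10.0, 12.0, 14.0, 5.0, 6.0, 7.0],
            "CO2": [370.0, 372.0, 374.0] * 2,
        }
    )


def noise_free_linear_panel(beta_co2=4.8, n_sites=6, n_years=12, co2_trend=2.0):
    """Exactly linear panel: NEP anomaly = beta * CO2 anomaly, no noise."""
    rows = []
    for i in range(n_sites):
        base = 200.0 + 40.0 * i
        for t in range(n_years):
            year = 1995 + t
            co2 = 360.0 + co2_trend * t
            rows.append({"site": f"S{i}", "year": year, "CO2": co2, "NEP": base})
    df = pd.DataFrame(rows)
    df = compute_anomalies(df, ["CO2"])
    df["NEP"] = df["NEP"] + beta_co2 * df["CO2_an"]
    df = compute_anomalies(df.drop(columns=["NEP_an", "NEP_c"], errors="ignore"), ["NEP"])
    return df


@pytest.fixture()
def linear_panel():
    return noise_free_linear_panel()
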