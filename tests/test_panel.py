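"""Panel IO, anomalies, CO2 QC, derived covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxtrend.panel import (
    compute_anomalies,
    corrected_maturity_age,
    cumulative_deposition,
    qc_fill_co2,
    read_panel,
    site_summary,
    warm_season_aggregate,
    write_panel,
)


class TestReadWrite:
    def test_roundtrip_preserves_values(self, synth, tmp_path):
        path = tmp_path / "panel.csv"
        write_panel(synth.panel, path)
        back = read_panel(path)
        pd.testing.assert_frame_equal(back, synth.panel.reset_index(drop=True))

    def test_toy_file_shape_and_dtypes(self, toy_panel, tmp_path):
        path = tmp_path / "toy.csv"
        write_panel(toy_panel, path)
        df = read_panel(path)
        assert len(df) == 6
        assert df["year"].dtype == np.int64 or df["year"].dtype == int

    def test_duplicate_site_year_rejected_with_names(self, tmp_path):
        df = pd.DataFrame(
            {"site": ["siteA", "siteA"], "year": [2001, 2001], "NEP": [1.0, 2.0]}
        )
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="siteA.*2001"):
            read_panel(path)

    def test_missing_required_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"site": ["A"], "year": [2000]}).to_csv(path, index=False)
        with pytest.raises(KeyError, match="NEP"):
            read_panel(path, required=["site", "year", "NEP"])

    def test_unknown_columns_preserved(self, tmp_path):
        df = pd.DataFrame({"site": ["A"], "year": [2000], "extra": [42.0]})
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        assert "extra" in read_panel(path).columns


class TestAnomalies:
    def test_hand_example(self):
        df = pd.DataFrame(
            {"site": ["A"] * 3, "year": [1, 2, 3], "v": [10.0, 12.0, 14.0]}
        )
        out = compute_anomalies(df, ["v"])
        assert out["v_c"].tolist() == [12.0, 12.0, 12.0]
        assert out["v_an"].tolist() == [-2.0, 0.0, 2.0]

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_centering_identity(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "site": np.repeat(["A", "B"], 5),
                "year": np.tile(np.arange(5), 2),
                "v": rng.normal(size=10),
            }
        )
        out = compute_anomalies(df, ["v"])
        for _, grp in out.groupby("site"):
            assert grp["v_an"].sum() == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(grp["v_an"] + grp["v_c"], grp["v"])

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame(
            {"site": ["A"] * 3, "year": [1, 2, 3], "v": [10.0, np.nan, 14.0]}
        )
        out = compute_anomalies(df, ["v"])
        assert out["v_c"].iloc[0] == pytest.approx(12.0)  # mean over observed
        assert np.isnan(out["v_an"].iloc[1])

    def test_all_missing_site_gives_missing_not_zero(self):
        df = pd.DataFrame(
            {"site": ["A", "A", "B", "B"], "year": [1, 2, 1, 2],
             "v": [1.0, 3.0, np.nan, np.nan]}
        )
        out = compute_anomalies(df, ["v"])
        assert out[out.site == "B"]["v_an"].isna().all()

    def test_reproduces_generator_anomalies(self, synth, anomaly_panel):
        # generator adds beta * driver anomaly; recompute one driver anomaly
        panel = synth.panel
        co2_an = panel["CO2"] - panel.groupby("site")["CO2"].transform("mean")
        np.testing.assert_allclose(anomaly_panel["CO2_an"], co2_an, atol=1e-12)


class TestQcFillCo2:
    def test_clean_increasing_series_untouched(self):
        s = pd.Series([370.0, 372.0, 374.0], index=[2000, 2001, 2002])
        filled, flags = qc_fill_co2(s)
        assert len(flags) == 0
        pd.testing.assert_series_equal(filled, s)

    def test_dip_below_predecessor_flagged_and_refilled(self):
        s = pd.Series([370.0, 365.0, 374.0], index=[2000, 2001, 2002])
        filled, flags = qc_fill_co2(s)
        assert flags["year"].tolist() == [2001]
        assert 370.0 < filled.loc[2001] < 374.0

    def test_excessive_jump_flagged(self):
        s = pd.Series([370.0, 372.0, 390.0, 376.0], index=range(2000, 2004))
        filled, flags = qc_fill_co2(s)
        assert 2002 in flags["year"].tolist()
        assert 2003 not in flags["year"].tolist()
        assert filled.loc[2002] < 390.0

    def test_spline_fill_on_longer_series(self):
        years = list(range(2000, 2010))
        vals = [360.0 + 2.0 * t for t in range(10)]
        vals[4] = 350.0  # dip
        s = pd.Series(vals, index=years)
        filled, flags = qc_fill_co2(s)
        assert flags["year"].tolist() == [2004]
        assert filled.loc[2004] == pytest.approx(368.0, abs=1.0)

    def test_reference_substitution_when_too_few_points(self):
        s = pd.Series([370.0, 365.0, np.nan], index=[2000, 2001, 2002])
        ref = pd.Series([370.5, 372.5, 374.5], index=[2000, 2001, 2002])
        filled, flags = qc_fill_co2(s, reference=ref)
        assert filled.loc[2001] == pytest.approx(372.5)
        assert filled.loc[2002] == pytest.approx(374.5)

    def test_unfilled_without_reference(self):
        s = pd.Series([370.0, 365.0, np.nan], index=[2000, 2001, 2002])
        filled, flags = qc_fill_co2(s)
        assert np.isnan(filled.loc[2002])
        assert "unfilled" in flags["reason"].tolist()

    def test_idempotent_on_own_output(self):
        years = list(range(2000, 2012))
        rng = np.random.default_rng(4)
        vals = 360.0 + 2.0 * np.arange(12) + rng.normal(0, 0.3, 12)
        vals[3] = 348.0
        vals[8] = 390.0
        s = pd.Series(vals, index=years)
        filled, _ = qc_fill_co2(s)
        refilled, flags2 = qc_fill_co2(filled)
        assert len(flags2) == 0
        pd.testing.assert_series_equal(filled, refilled)


class TestCorrectedMaturityAge:
    @pytest.mark.parametrize(
        "age,maturity,expected",
        [(80, 90, 0.89), (118, 95, 1.24), (75, 75, 1.00)],
    )
    def test_published_ratios(self, age, maturity, expected):
        assert round(corrected_maturity_age(age, maturity), 2) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            corrected_maturity_age(0, 90)
        with pytest.raises(ValueError):
            corrected_maturity_age(80, -1)


class TestCumulativeDeposition:
    def _panel(self, values):
        return pd.DataFrame(
            {"site": "A", "year": range(2000, 2000 + len(values)), "Sdep": values}
        )

    def test_constant_series(self):
        out = cumulative_deposition(self._panel([1.0] * 6), "Sdep", window=5)
        assert out["Sdep_cum5"].iloc[5] == pytest.approx(5.0)

    def test_strict_boundary_missing(self):
        out = cumulative_deposition(self._panel([1.0] * 6), "Sdep", window=5)
        assert out["Sdep_cum5"].iloc[:5].isna().all()

    def test_hand_sum(self):
        out = cumulative_deposition(
            self._panel([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), "Sdep", window=5
        )
        assert out["Sdep_cum5"].iloc[5] == pytest.approx(15.0)

    def test_lenient_mode_sums_available(self):
        panel = self._panel([1.0, np.nan, 3.0, 4.0, 5.0, 6.0])
        strict = cumulative_deposition(panel, "Sdep", window=5, mode="strict")
        lenient = cumulative_deposition(panel, "Sdep", window=5, mode="lenient")
        assert np.isnan(strict["Sdep_cum5"].iloc[5])
        assert lenient["Sdep_cum5"].iloc[5] == pytest.approx(13.0)

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(7)
        panel = self._panel(rng.uniform(0, 3, size=9))
        out = cumulative_deposition(panel, "Sdep", window=3)
        by_year = panel.set_index("year")["Sdep"]
        for _, row in out.iterrows():
            expected = sum(
                by_year.get(y, np.nan) for y in range(int(row.year) - 3, int(row.year))
            )
            if np.isnan(expected):
                assert np.isnan(row.Sdep_cum3)
            else:
                assert row.Sdep_cum3 == pytest.approx(expected)


class TestWarmSeason:
    def _monthly(self, mat=None, mapv=None):
        months = pd.DataFrame({"year": 2000, "month": range(1, 13)})
        if mat is not None:
            months["MAT"] = mat
        if mapv is not None:
            months["MAP"] = mapv
        return months

    def test_constant_temperature(self):
        out = warm_season_aggregate(self._monthly(mat=[10.0] * 12))
        assert out["MAT_warm"].iloc[0] == pytest.approx(10.0)

    def test_map_sums_to_600(self):
        out = warm_season_aggregate(self._monthly(mapv=[100.0] * 12))
        assert out["MAP_warm"].iloc[0] == pytest.approx(600.0)

    def test_month_index_mean(self):
        out = warm_season_aggregate(self._monthly(mat=list(range(1, 13))))
        assert out["MAT_warm"].iloc[0] == pytest.approx(6.5)

    def test_missing_months_blank_value(self):
        m = self._monthly(mat=[10.0] * 12)
        m.loc[m["month"] == 5, "MAT"] = np.nan
        out = warm_season_aggregate(m)  # default requires all 6 months
        assert np.isnan(out["MAT_warm"].iloc[0])
        out2 = warm_season_aggregate(m, min_fraction=0.5)
        assert out2["MAT_warm"].iloc[0] == pytest.approx(10.0)


def test_site_summary_counts(synth):
    s = site_summary(synth.panel).set_index("site")
    for site, grp in synth.panel.groupby("site"):
        assert s.loc[site, "n_years"] == len(grp)
        assert s.loc[site, "final_year"] - s.loc[site, "initial_year"] + 1 == len(grp)
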