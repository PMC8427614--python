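"""Seed densities, weather windows, standardization and design assembly."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mastmix as mm
from mastmix.covariates import (
    CovariateError,
    MissingDataError,
    back_transform_seed,
    seed_rain_table,
)


def _seed_frame(landform, period, totals_by_species):
    rows = []
    for species, totals in totals_by_species.items():
        for t, c in enumerate(totals, start=1):
            rows.append(
                dict(landform=landform, trap_id=t, period=period, species=species,
                     seeds=int(c))
            )
    return pd.DataFrame(rows)


class TestSeedDensity:
    def test_single_trap_arithmetic(self):
        df = _seed_frame("basin", 2009, {"fagus": [24]})
        fagus, conifer = mm.seed_density(df, "basin", 2009)
        assert fagus == pytest.approx(100.0)  # 24 seeds / 0.24 m^2
        assert conifer == 0.0

    def test_all_zero_traps(self):
        df = _seed_frame("basin", 2009, {"fagus": [0] * 81, "picea": [0] * 81})
        assert mm.seed_density(df, "basin", 2009) == (0.0, 0.0)

    def test_mean_density_matches_direct_arithmetic(self, rng):
        totals = {sp: rng.integers(0, 200, 81) for sp in ("fagus", "picea", "abies")}
        df = _seed_frame("slope", 2011, totals)
        fagus, conifer = mm.seed_density(df, "slope", 2011)
        assert fagus == pytest.approx(totals["fagus"].sum() / (81 * 0.24))
        assert conifer == pytest.approx(
            (totals["picea"].sum() + totals["abies"].sum()) / (81 * 0.24)
        )

    def test_missing_stratum_is_signal_not_zero(self):
        df = _seed_frame("basin", 2009, {"fagus": [24]})
        with pytest.raises(MissingDataError):
            mm.seed_density(df, "slope", 2009)

    @given(st.integers(1, 30), st.data())
    @settings(max_examples=25, deadline=None)
    def test_pooling_invariance(self, n_traps, data):
        """Conifer density from pooled per-trap counts equals the sum of
        independently computed per-species densities (linearity of the mean)."""
        picea = data.draw(st.lists(st.integers(0, 100), min_size=n_traps,
                                   max_size=n_traps))
        abies = data.draw(st.lists(st.integers(0, 100), min_size=n_traps,
                                   max_size=n_traps))
        df = _seed_frame("basin", 2000, {"picea": picea, "abies": abies})
        _, pooled = mm.seed_density(df, "basin", 2000)
        _, only_p = mm.seed_density(
            _seed_frame("basin", 2000, {"picea": picea}), "basin", 2000
        )
        _, only_a = mm.seed_density(
            _seed_frame("basin", 2000, {"abies": abies}), "basin", 2000
        )
        assert pooled == pytest.approx(only_p + only_a, rel=1e-12)


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert mm.log_transform(0.0) == 0.0

    def test_e_minus_one(self):
        assert mm.log_transform(np.e - 1) == pytest.approx(1.0)

    def test_monotone_on_grid(self, rng):
        x = np.sort(rng.uniform(0, 500, 50))
        y = mm.log_transform(x)
        assert (np.diff(y) >= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mm.log_transform(-0.1)

    def test_back_transform_inverts(self, rng):
        x = rng.uniform(0, 465, 20)
        np.testing.assert_allclose(back_transform_seed(mm.log_transform(x)), x)


class TestMastPeriod:
    @pytest.mark.parametrize(
        "date,period",
        [
            (dt.date(2007, 7, 1), 2006),
            (dt.date(2011, 5, 15), 2010),
            (dt.date(2011, 10, 5), 2010),
        ],
    )
    def test_session_year_maps_to_previous_seed_year(self, date, period):
        assert mm.assign_mast_period(date) == period


class TestNightCovariates:
    def _hourly(self, values, night_of):
        start = pd.Timestamp(night_of) - pd.Timedelta(hours=5)
        idx = pd.date_range(start, periods=len(values), freq="h")
        return pd.Series(values, index=idx)

    def test_constant_series(self):
        night = dt.date(2010, 6, 16)
        temps = self._hourly([10.0] * 12, night)
        precip = pd.Series([3.5], index=[pd.Timestamp("2010-06-15")])
        t, pr = mm.night_covariates(temps, precip, night)
        assert t == 10.0
        assert pr == 3.5

    def test_linear_ramp(self):
        night = dt.date(2010, 6, 16)
        temps = self._hourly(list(range(12)), night)
        precip = pd.Series([0.0], index=[pd.Timestamp("2010-06-15")])
        t, _ = mm.night_covariates(temps, precip, night)
        assert t == pytest.approx(5.5)

    def test_windowed_slice_mean(self, rng):
        night = dt.date(2010, 6, 16)
        vals = rng.normal(8, 3, 30)
        start = pd.Timestamp("2010-06-15 12:00")
        temps = pd.Series(vals, index=pd.date_range(start, periods=30, freq="h"))
        precip = pd.Series([1.0], index=[pd.Timestamp("2010-06-15")])
        t, _ = mm.night_covariates(temps, precip, night)
        window = temps.loc["2010-06-15 19:00":"2010-06-16 06:00"]
        assert t == pytest.approx(window.mean())

    def test_missing_hours_flagged(self):
        night = dt.date(2010, 6, 16)
        temps = self._hourly([10.0] * 6, night)  # half the window
        precip = pd.Series([0.0], index=[pd.Timestamp("2010-06-15")])
        with pytest.raises(MissingDataError):
            mm.night_covariates(temps, precip, night)


class TestStandardize:
    def test_simple_example(self):
        z, (c, s) = mm.standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (c, s) == (2.0, 1.0)

    def test_constant_rejected(self):
        with pytest.raises(CovariateError):
            mm.standardize([5.0, 5.0, 5.0])

    def test_inverse_identity(self, rng):
        x = rng.normal(3, 7, 40)
        z, (c, s) = mm.standardize(x)
        np.testing.assert_allclose(z * s + c, x, rtol=1e-12)

    def test_idempotent(self, rng):
        x = rng.normal(0, 2, 25)
        z, _ = mm.standardize(x)
        z2, (c2, s2) = mm.standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        assert c2 == pytest.approx(0.0, abs=1e-12)
        assert s2 == pytest.approx(1.0, rel=1e-12)


class TestGridArea:
    @pytest.mark.parametrize(
        "n,spacing,ha",
        [(25, 15.0, 0.5625), (44, 15.0, 0.99), (1, 100.0, 1.0)],
    )
    def test_station_cells(self, n, spacing, ha):
        assert mm.grid_area(n, spacing) == pytest.approx(ha)


@pytest.fixture(scope="module")
def built():
    study, _ = mm.generate_study(mm.ScenarioConfig(n_years=6), seed=3)
    design = mm.build_design(study, "MFb")
    return study, design


class TestBuildDesign:
    def test_columns(self, built):
        _, design = built
        assert design.x_names[0] == "intercept"
        site_cols = [n for n in design.x_names if n.startswith("site[") and n.endswith("]")]
        assert sorted(site_cols) == ["site[AVs]", "site[PFb]", "site[PFs]", "site[WTs]"]
        assert "site[MFb]" not in design.x_names  # reference omitted
        inter = [n for n in design.x_names if n.endswith(":fagus_seed")]
        assert len(inter) == 4
        assert design.z_names == [
            "intercept", "night_of_session", "temp", "temp_sq", "precip",
            "temp_x_precip",
        ]

    def test_standardized_columns_center_scale(self, built):
        _, design = built
        for name in ("fagus_seed", "conifer_seed", "julian"):
            col = design.X[:, design.column(name)]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_interaction_is_elementwise_product(self, built):
        _, design = built
        fagus = design.X[:, design.column("fagus_seed")]
        for site in ("AVs", "WTs"):
            dummy = design.X[:, design.column(f"site[{site}]")]
            inter = design.X[:, design.column(f"site[{site}]:fagus_seed")]
            np.testing.assert_allclose(inter, dummy * fagus)

    def test_no_silent_session_drops(self, built):
        study, design = built
        assert design.n_sessions + len(design.excluded) == len(study.sessions)

    def test_sessions_without_seed_data_reported(self):
        scenario = mm.ScenarioConfig(n_years=6)
        # drop the first two masting periods, as in years without monitoring
        scenario.unmonitored_periods = (scenario.first_year - 1, scenario.first_year)
        study, _ = mm.generate_study(scenario, seed=3)
        design = mm.build_design(study, "MFb")
        assert len(design.excluded) > 0
        assert all("no seed rain" in reason for _, reason in design.excluded)

    def test_unknown_reference_site(self, built):
        study, _ = built
        with pytest.raises(CovariateError, match="reference site"):
            mm.build_design(study, "XXX")

    def test_pooled_interaction_coding(self, built):
        study, _ = built
        design = mm.build_design(study, "MFb", interaction_sites=["AVs", "WTs"])
        assert "open_sites:fagus_seed" in design.x_names
        assert not any(n.startswith("site[") and n.endswith(":fagus_seed")
                       for n in design.x_names)

    def test_offset_is_log_area(self, built):
        study, design = built
        areas = {s: study.sites[s].area_ha for s in study.sites}
        expected = np.log([areas[s] for s in design.site_ids])
        np.testing.assert_allclose(design.offset_log_area, expected)


def test_seed_rain_table_covers_all_strata(tiny_study):
    recs = seed_rain_table(tiny_study.seed_counts)
    assert len(recs) == 1
    r = recs[0]
    assert (r.landform, r.period) == ("basin", 2009)
    assert r.fagus_per_m2 == pytest.approx((12 + 0 + 30) / 3 / 0.24)
    assert r.fagus_log == pytest.approx(np.log1p(r.fagus_per_m2))
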