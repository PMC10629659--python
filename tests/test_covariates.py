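"""Stage-windowed climate, trasp and design assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kbb_endoexo import trasp, window_means
from kbb_endoexo.covariates import (LAG_LABELS, WINDOWS, assemble_design,
                                    design_column_names, site_covariates)
from kbb_endoexo.surveys import process_surveys


class TestTrasp:
    def test_north_and_south_endpoints(self):
        assert trasp(30.0) == pytest.approx(0.0, abs=1e-12)
        assert trasp(210.0) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_turn_is_neutral(self):
        assert trasp(120.0) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=360.0))
    @settings(max_examples=60, derandomize=True)
    def test_range_and_symmetry_about_north(self, x):
        assert 0.0 <= trasp(30.0 + x) <= 1.0
        assert trasp(30.0 + x) == pytest.approx(trasp(30.0 - x), abs=1e-12)

    @given(st.floats(min_value=-720, max_value=720))
    @settings(max_examples=40, derandomize=True)
    def test_periodicity(self, a):
        assert trasp(a) == pytest.approx(trasp(a + 360.0), abs=1e-9)

    def test_flat_cell_is_neutral(self):
        assert trasp(float("nan")) == 0.5
        out = trasp(np.array([30.0, np.nan]))
        assert out[1] == 0.5


class TestWindowMeans:
    def test_overwinter_mean_with_december_from_previous_year(self, toy_climate):
        # Dec(1999)=22, Jan=11, Feb=12, Mar=13 -> mean 14.5 for year 2000
        w = window_means(toy_climate, generation=1)
        assert w.loc[("S1", 2000), "MT_OW"] == pytest.approx((22 + 11 + 12 + 13) / 4)

    def test_overwinter_example_value(self):
        rows = [("S", 1999, 12, -8.0, -4, -12, 30), ("S", 2000, 1, -10.0, -6, -14, 30),
                ("S", 2000, 2, -6.0, -2, -10, 30), ("S", 2000, 3, 0.0, 4, -4, 30)]
        clim = pd.DataFrame(rows, columns=["site", "year", "month", "MT", "AT", "IT", "PT"])
        w = window_means(clim, generation=1)
        assert w.loc[("S", 2000), "MT_OW"] == pytest.approx(-6.0)

    def test_single_month_window_passes_through(self, toy_climate):
        w = window_means(toy_climate, generation=1)
        june = toy_climate.query("year == 2000 and month == 6")
        assert w.loc[("S1", 2000), "MT_JN"] == pytest.approx(float(june["MT"].iloc[0]))

    def test_matches_bruteforce_mean(self, default_climate):
        w = window_means(default_climate, generation=2)
        site = default_climate["site"].iloc[0]
        year = int(default_climate.query("site == @site")["year"].median())
        for var in ("MT", "AT", "IT", "PT"):
            expect = default_climate.query(
                "site == @site and year == @year and month == 7")[var].mean()
            assert w.loc[(site, year), f"{var}_JL"] == pytest.approx(expect, abs=1e-12)
        # multi-month window, generation 1 spring
        w1 = window_means(default_climate, generation=1)
        expect = default_climate.query(
            "site == @site and year == @year and month in (4, 5)")["PT"].mean()
        assert w1.loc[(site, year), "PT_SP"] == pytest.approx(expect, abs=1e-12)

    def test_constant_series_gives_constant_windows(self):
        rows = [("S", 2000, m, 7.0, 12.0, 2.0, 40.0) for m in range(1, 13)]
        rows.append(("S", 1999, 12, 7.0, 12.0, 2.0, 40.0))
        clim = pd.DataFrame(rows, columns=["site", "year", "month", "MT", "AT", "IT", "PT"])
        w = window_means(clim, generation=1)
        for col in w.columns:
            assert w.loc[("S", 2000), col] == pytest.approx(7.0 if col.startswith("MT")
                                                            else 12.0 if col.startswith("AT")
                                                            else 2.0 if col.startswith("IT")
                                                            else 40.0)

    def test_missing_month_gives_nan_window(self, toy_climate):
        clim = toy_climate[~((toy_climate.year == 2000) & (toy_climate.month == 3))]
        w = window_means(clim, generation=1)
        assert np.isnan(w.loc[("S1", 2000), "MT_OW"])
        assert not np.isnan(w.loc[("S1", 2000), "MT_SP"])

    def test_pt_sum_option(self, toy_climate):
        w = window_means(toy_climate, generation=1, pt_agg="sum")
        # spring months Apr+May of 2000: PT 54 + 55
        assert w.loc[("S1", 2000), "PT_SP"] == pytest.approx(54 + 55)
        # temperatures still averaged
        assert w.loc[("S1", 2000), "MT_SP"] == pytest.approx((14 + 15) / 2)


class TestDesign:
    def test_column_names_and_count(self):
        g1 = design_column_names(1)
        assert len(g1) == 18
        assert g1[:2] == ["PS", "PF"]
        assert g1[2:5] == ["MT_OW", "MT_SP", "MT_JN"]
        assert g1[-4:] == ["Canopy", "Elevation", "Slope", "Trasp"]
        g2 = design_column_names(2)
        assert g2[:2] == ["CF", "PS"]
        assert "MT_JL" in g2 and "PT_AG" in g2

    def test_assemble_design_shape_and_conservation(self, tiny_bundle):
        dens = process_surveys(tiny_bundle.surveys)
        w = window_means(tiny_bundle.climate, 1)
        ds, log = assemble_design(dens, w, tiny_bundle.topo, "PA", 1)
        assert list(ds.X.columns) == design_column_names(1)
        assert log["eligible_rows"] + log["missing_lag_or_lambda"] + \
            log["missing_covariate"] == log["candidate_rows"]
        assert len(ds.X) == log["eligible_rows"]
        assert len(ds.y) == len(ds.X)

    def test_missing_march_climate_drops_gen1_row(self, tiny_bundle):
        dens = process_surveys(tiny_bundle.surveys)
        site = dens["site"].iloc[0]
        clim = tiny_bundle.climate
        clim = clim[~((clim.site == site) & (clim.year == 2004) & (clim.month == 3))]
        w = window_means(clim, 1)
        ds, _ = assemble_design(dens, w, tiny_bundle.topo, "PA", 1)
        assert (site, 2004) not in ds.X.index

    def test_pooled_design_keeps_population_labels(self, tiny_bundle):
        dens = process_surveys(tiny_bundle.surveys)
        w = window_means(tiny_bundle.climate, 2)
        ds, _ = assemble_design(dens, w, tiny_bundle.topo, None, 2)
        assert ds.population == "All"
        assert set(ds.population_labels) == {"PA", "PB"}

    def test_zero_eligible_rows_raises(self, tiny_bundle):
        dens = process_surveys(tiny_bundle.surveys)
        w = window_means(tiny_bundle.climate.iloc[0:0], 1)  # no climate at all
        with pytest.raises(ValueError, match="no eligible rows"):
            assemble_design(dens, w, tiny_bundle.topo, "PA", 1)

    def test_lag_labels_match_convention(self):
        assert LAG_LABELS == {1: ("PS", "PF"), 2: ("CF", "PS")}
        assert list(WINDOWS[1]) == ["OW", "SP", "JN"]
        assert list(WINDOWS[2]) == ["JN", "JL", "AG"]

    def test_site_covariates_applies_trasp(self, default_topo):
        sc = site_covariates(default_topo)
        assert ((sc["Trasp"] >= 0) & (sc["Trasp"] <= 1)).all()
        assert list(sc.columns) == ["Canopy", "Elevation", "Slope", "Trasp"]
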