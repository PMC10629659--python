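"""Model/Results surface: standardization, full fits, balanced bootstrap."""

import numpy as np
import pandas as pd
import pytest

from kbb_endoexo import (EndoExoModel, GAConfig, ModelDataset,
                         bootstrap_balanced_fit, fit_population,
                         make_design_dataset, standardize, unstandardize)
from kbb_endoexo.model import balanced_indices

FAST_GA = GAConfig(population_size=20, generations=25)


class TestStandardize:
    def test_zscore_example(self):
        Z, stat = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(Z["a"], [-1.0, 0.0, 1.0])
        assert stat.loc["a", "sd"] == pytest.approx(1.0)

    def test_constant_column_dropped(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        Z, stat = standardize(X)
        assert list(Z.columns) == ["a"]
        assert stat.loc["c", "sd"] == 0.0

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))

    def test_roundtrip(self, rng):
        X = pd.DataFrame(rng.normal(2.0, 3.0, size=(20, 4)),
                         columns=list("abcd"))
        Z, stat = standardize(X)
        back = unstandardize(Z, stat)
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-12)
        assert np.allclose(Z.mean(), 0.0, atol=1e-9)
        assert np.allclose(Z.std(ddof=1), 1.0, atol=1e-9)


class TestFit:
    def test_recovers_active_set_with_signs(self):
        ds, truth = make_design_dataset(400, noise_sd=0.2, seed=4)
        res = fit_population(ds, ga_config=FAST_GA, seed=4, run_rf=False)
        active = truth[truth != 0]
        assert set(active.index) <= set(res.selected)
        for v, b in active.items():
            assert np.sign(res.params[v]) == np.sign(b)

    def test_results_surface(self):
        ds, _ = make_design_dataset(120, seed=9)
        res = fit_population(ds, ga_config=FAST_GA, seed=9)
        assert res.nobs == 120
        assert 0.0 <= res.rsquared <= 1.0
        assert res.rsquared_adj <= res.rsquared
        assert (res.bse > 0).all()
        assert res.rf_oob_r2 is not None
        assert len(res.rf_importances) == 18
        assert "adj. R2" in res.summary()
        d = res.to_dict()
        assert set(d["coef"]) == set(res.selected)
        preds = res.predict(ds.X)
        assert len(preds) == 120
        # predictions actually explain the response
        assert np.corrcoef(preds, ds.y)[0, 1] ** 2 > 0.5

    def test_seed_determinism(self):
        ds, _ = make_design_dataset(100, seed=2)
        a = fit_population(ds, ga_config=FAST_GA, seed=77, run_rf=False)
        b = fit_population(ds, ga_config=FAST_GA, seed=77, run_rf=False)
        pd.testing.assert_series_equal(a.params, b.params)
        assert a.selected == b.selected

    def test_constant_response_rejected(self):
        ds, _ = make_design_dataset(50, seed=1)
        ds.y[:] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_population(ds, ga_config=FAST_GA, seed=1)

    def test_too_few_rows_rejected(self):
        ds, _ = make_design_dataset(8, seed=1)
        with pytest.raises(ValueError, match="rows"):
            fit_population(ds, ga_config=FAST_GA)

    def test_adjusted_r2_bounds(self):
        ds, _ = make_design_dataset(60, noise_sd=1.5, seed=3)
        res = fit_population(ds, ga_config=FAST_GA, seed=3, run_rf=False)
        assert res.rsquared_adj <= res.rsquared <= 1.0

    def test_lower_noise_never_hurts_fit(self):
        """Median R² over seeds is monotone as generator noise shrinks."""
        med = []
        for noise in (1.0, 0.4, 0.1):
            r2 = []
            for s in range(5):
                ds, _ = make_design_dataset(150, noise_sd=noise, seed=100 + s)
                r2.append(fit_population(ds, ga_config=FAST_GA, seed=s,
                                         run_rf=False).rsquared)
            med.append(np.median(r2))
        assert med[0] <= med[1] <= med[2]


def _pooled_dataset(rng, n_big=200, n_small=20, slope_big=0.5, slope_small=-0.5):
    """Two populations sharing a design but with opposite slopes on x1."""
    X = pd.DataFrame(rng.normal(size=(n_big + n_small, 3)),
                     columns=["x1", "x2", "x3"])
    labels = pd.Series(["big"] * n_big + ["small"] * n_small)
    slope = np.where(labels == "big", slope_big, slope_small)
    y = pd.Series(slope * X["x1"].to_numpy() + rng.normal(0, 0.2, len(X)))
    return ModelDataset(population="All", generation=1, X=X, y=y,
                        population_labels=labels)


class TestBootstrapBalanced:
    def test_balanced_indices_quota_contract(self, rng):
        labels = pd.Series(["a"] * 30 + ["b"] * 7 + ["c"] * 15)
        idx = balanced_indices(rng, labels, quota=7)
        drawn = labels.iloc[idx].value_counts()
        assert drawn.to_dict() == {"a": 7, "b": 7, "c": 7}

    def test_determinism(self, rng):
        ds = _pooled_dataset(rng)
        a = bootstrap_balanced_fit(ds, ga_config=FAST_GA, B=20, seed=5)
        b = bootstrap_balanced_fit(ds, ga_config=FAST_GA, B=20, seed=5)
        pd.testing.assert_series_equal(a.params, b.params)
        assert a.n_bootstrap == b.n_bootstrap == 20

    def test_balancing_counters_oversampling(self, rng):
        """With one population 10x oversampled and a deviant slope, the
        balanced estimate sits nearer the unweighted mean of the two
        population truths (zero) than the naive pooled fit does."""
        ds = _pooled_dataset(rng)
        naive = fit_population(ds, ga_config=FAST_GA, seed=3, run_rf=False)
        naive_x1 = naive.params.get("x1", 0.0)
        bal = bootstrap_balanced_fit(ds, ga_config=FAST_GA, B=30, seed=3)
        bal_x1 = bal.params.get("x1", 0.0)
        assert abs(bal_x1) < abs(naive_x1)

    def test_requires_two_populations(self, rng):
        ds = _pooled_dataset(rng)
        ds.population_labels[:] = "one"
        with pytest.raises(ValueError, match="populations"):
            bootstrap_balanced_fit(ds, B=5, seed=1)

    def test_small_b_warns(self, rng, caplog):
        ds = _pooled_dataset(rng)
        import logging
        with caplog.at_level(logging.WARNING, logger="kbb_endoexo.model"):
            bootstrap_balanced_fit(ds, ga_config=FAST_GA, B=5, seed=1)
        assert any("unstable" in r.message for r in caplog.records)


class TestModelConstruction:
    def test_from_dataset_and_direct_equivalence(self):
        ds, _ = make_design_dataset(60, seed=8)
        m1 = EndoExoModel.from_dataset(ds)
        m2 = EndoExoModel(ds.y.to_numpy(), ds.X, population="SYN", generation=1)
        r1 = m1.fit(ga_config=FAST_GA, seed=1, run_rf=False)
        r2 = m2.fit(ga_config=FAST_GA, seed=1, run_rf=False)
        pd.testing.assert_series_equal(r1.params, r2.params)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            EndoExoModel(rng.normal(size=5), pd.DataFrame(rng.normal(size=(6, 2))))
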