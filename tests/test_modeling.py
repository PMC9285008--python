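import dataclasses

import numpy as np
import pandas as pd
import pytest

from paddywave.modeling import (
    evaluate,
    fit_msr,
    fit_rf,
    fuse_stages,
    stage_combination_grid,
    stage_combinations,
)
from paddywave.spectra_io import STAGES
from paddywave.synthetic_data import SynthConfig, make_three_year_benchmark


def _frame(cols: dict, n=30, seed=0):
    idx = pd.Index([f"P{i:02d}" for i in range(n)], name="plot_id")
    return pd.DataFrame(cols, index=idx)


class TestFuseStages:
    def test_single_stage_unchanged(self):
        t = {"heading": _frame({"heading_NDVI": np.arange(30.0)})}
        out = fuse_stages(t, ("heading",))
        assert out.equals(t["heading"])

    def test_column_counts_add(self):
        t = {
            "heading": _frame({"heading_a": np.arange(30.0), "heading_b": np.arange(30.0)}),
            "milky": _frame({"milky_a": np.arange(30.0)}),
        }
        assert fuse_stages(t, ("heading", "milky")).shape[1] == 3

    def test_empty_combo_rejected(self):
        with pytest.raises(ValueError):
            fuse_stages({}, ())

    def test_canonical_15_combinations(self):
        combos = stage_combinations()
        assert len(combos) == 15
        assert combos[0] == ("elongation",)
        assert combos[4] == ("elongation", "heading")
        assert combos[-1] == STAGES
        sizes = [len(c) for c in combos]
        assert sizes == sorted(sizes)  # singles, pairs, triples, quad


class TestStepwise:
    def test_noiseless_single_variable_recovery(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 1, 30)
        x2 = rng.normal(0, 1, 30)
        X = _frame({"x1": x1, "x2": x2})
        y = 2.0 + 3.0 * x1
        m = fit_msr(X, y)
        assert m.retained == ["x1"]
        assert m.intercept == pytest.approx(2.0, abs=1e-8)
        assert m.coefficients["x1"] == pytest.approx(3.0, abs=1e-8)

    def test_duplicate_column_keeps_first(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, 30)
        X = _frame({"x1": x1, "x2": x1.copy()})
        y = 1.0 + 2.0 * x1 + rng.normal(0, 0.01, 30)
        m = fit_msr(X, y)
        assert m.retained == ["x1"]

    def test_constant_target_gives_intercept_only(self):
        rng = np.random.default_rng(2)
        X = _frame({"x1": rng.normal(0, 1, 30)})
        m = fit_msr(X, np.full(30, 650.0))
        assert m.retained == []
        assert m.intercept == pytest.approx(650.0)

    def test_noiseless_three_variable_recovery(self):
        rng = np.random.default_rng(3)
        X = _frame({f"x{i}": rng.normal(0, 1, 40) for i in range(1, 6)}, n=40)
        y = 10.0 - 4.0 * X["x1"] + 2.5 * X["x3"] + 0.7 * X["x5"]
        m = fit_msr(X, y.to_numpy())
        assert sorted(m.retained) == ["x1", "x3", "x5"]
        assert m.coefficients["x1"] == pytest.approx(-4.0, abs=1e-6)
        assert m.coefficients["x3"] == pytest.approx(2.5, abs=1e-6)
        assert m.coefficients["x5"] == pytest.approx(0.7, abs=1e-6)

    def test_fixed_point(self):
        """Refitting on the retained set changes nothing."""
        rng = np.random.default_rng(4)
        X = _frame({f"x{i}": rng.normal(0, 1, 50) for i in range(6)}, n=50)
        y = 5.0 + 2.0 * X["x0"] - 1.0 * X["x2"] + rng.normal(0, 0.5, 50)
        m1 = fit_msr(X, y.to_numpy())
        m2 = fit_msr(X[m1.retained], y.to_numpy())
        assert m2.retained == m1.retained
        assert m2.intercept == pytest.approx(m1.intercept)

    def test_statsmodels_fixed_point_oracle(self):
        """The returned set is a stepwise fixed point when every entry and
        removal test is recomputed independently with statsmodels OLS."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = _frame({f"x{i}": rng.normal(0, 1, 30) for i in range(3)})
            y = 600 + 40 * X["x0"] - 30 * X["x1"] + rng.normal(0, 10, 30)
            m = fit_msr(X, y.to_numpy())
            retained = set(m.retained)
            for c in X.columns:
                cols = sorted(retained | {c})
                res = sm.OLS(y.to_numpy(), sm.add_constant(X[cols].to_numpy())).fit()
                p = res.pvalues[1 + cols.index(c)]
                if c in retained:
                    assert p <= m.p_remove + 1e-12
                else:
                    assert p >= m.p_enter - 1e-12


class TestRandomForest:
    def test_constant_target_exact(self):
        rng = np.random.default_rng(0)
        X = _frame({"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}, n=20)
        m = fit_rf(X, np.full(20, 700.0), n_trees=50, seed=1)
        assert np.all(m.predict(X) == 700.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        X = _frame({"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)})
        y = 600 + 50 * X["a"].to_numpy() + rng.normal(0, 10, 30)
        p1 = fit_rf(X, y, n_trees=100, seed=7).predict(X)
        p2 = fit_rf(X, y, n_trees=100, seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_predictions_within_training_range(self):
        rng = np.random.default_rng(2)
        X = _frame({"a": rng.normal(0, 1, 30)})
        y = rng.uniform(450, 900, 30)
        m = fit_rf(X, y, n_trees=50, seed=0)
        Xnew = _frame({"a": rng.normal(0, 3, 30)})
        p = m.predict(Xnew)
        assert p.min() >= y.min() - 1e-9 and p.max() <= y.max() + 1e-9

    def test_too_few_samples_rejected(self):
        X = _frame({"a": [1.0]}, n=1)
        with pytest.raises(ValueError):
            fit_rf(X, np.array([5.0]))


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([600, 700, 800], [600, 700, 800])
        assert (m.r_squared, m.rmse, m.mape) == (1.0, 0.0, 0.0)

    def test_mean_prediction_zero_r2(self):
        obs = np.array([600.0, 700.0, 800.0])
        m = evaluate(obs, np.full(3, obs.mean()))
        assert m.r_squared == pytest.approx(0.0)

    def test_printed_hand_example(self):
        m = evaluate([600.0, 700.0], [650.0, 650.0])
        assert m.rmse == pytest.approx(50.0)
        assert m.mape == pytest.approx((50 / 650 + 50 / 650) / 2 * 100)
        assert m.r_squared == pytest.approx(0.0)

    def test_observed_denominator_switch(self):
        m = evaluate([600.0, 700.0], [650.0, 650.0], mape_denominator="observed")
        assert m.mape == pytest.approx((50 / 600 + 50 / 700) / 2 * 100)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(500, 900, 20)
        pred = obs + rng.normal(0, 30, 20)
        a, b = evaluate(obs, pred), evaluate(3.0 * obs, 3.0 * pred)
        assert b.rmse == pytest.approx(3.0 * a.rmse)
        assert b.r_squared == pytest.approx(a.r_squared)
        assert b.mape == pytest.approx(a.mape)

    def test_zero_prediction_mape_missing(self):
        m = evaluate([600.0, 700.0], [0.0, 650.0])
        assert np.isnan(m.mape)


@pytest.fixture(scope="module")
def small_report():
    cfg = dataclasses.replace(SynthConfig(), n_plots=20)
    bench = make_three_year_benchmark(cfg, (41, 42, 43))
    return stage_combination_grid(bench, n_trees=50, rf_seed=0)


class TestGrid:
    def test_sixty_rows(self, small_report):
        assert len(small_report) == 60
        assert set(small_report.transform_set) == {"FD-VI", "CWT-FD-VI"}
        assert set(small_report.algorithm) == {"MSR", "RF"}
        assert small_report.stage_combination.nunique() == 15

    def test_validation_counts_match_disjoint_trials(self, small_report):
        assert (small_report.val1_n == 20).all() and (small_report.val2_n == 20).all()

    def test_train_r2_bounded_by_one(self, small_report):
        assert (small_report.train_r2 <= 1.0).all()
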