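"""Presence-background model: split, background, fit, prediction, AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import paleoveg as pv
from paleoveg.maxent import FeatureExpansion, auc_presence_background
from conftest import brute_force_auc


def _occ(n, vu="X", seed=0, lo=0.0, hi=8.0):
    rng = np.random.default_rng(seed)
    return pv.OccurrenceSet(vu, rng.uniform(lo, hi, n), rng.uniform(lo, hi, n))


class TestSplit:
    def test_quarter_holdout_at_n_1000(self):
        train, test = pv.split_occurrences(_occ(1000), 0.25, seed=1)
        assert len(test) == 250
        assert len(train) == 750

    def test_floor_rule_at_n_4(self):
        train, test = pv.split_occurrences(_occ(4), 0.25, seed=1)
        assert len(test) == 1
        assert len(train) == 3

    def test_partition_is_disjoint_and_exhaustive(self):
        occ = _occ(97, seed=2)
        train, test = pv.split_occurrences(occ, 0.3, seed=3)
        all_pts = set(zip(occ.x, occ.y))
        tr = set(zip(train.x, train.y))
        te = set(zip(test.x, test.y))
        assert tr | te == all_pts
        assert not (tr & te)

    def test_same_seed_same_partition(self):
        occ = _occ(60, seed=4)
        a = pv.split_occurrences(occ, 0.25, seed=9)
        b = pv.split_occurrences(occ, 0.25, seed=9)
        np.testing.assert_array_equal(a[1].x, b[1].x)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pv.split_occurrences(_occ(1), 0.25)
        with pytest.raises(ValueError):
            pv.split_occurrences(_occ(10), 1.0)


class TestBackground:
    def test_small_grid_uses_all_cells_with_warning(self, small_stack):
        geom = pv.GridGeometry(5, 10, 1.0)
        stack = pv.ClimateStack(geom, 0.0, {"v": np.arange(50.0).reshape(5, 10)})
        with pytest.warns(UserWarning, match="valid cells"):
            bg = pv.sample_background(stack, 10_000, seed=0)
        assert len(bg) == 50

    def test_sampled_cells_carry_finite_predictors(self, small_stack):
        bg = pv.sample_background(small_stack, 300, seed=1,
                                  variables=pv.NINE_PREDICTORS)
        assert np.isfinite(bg.env.to_numpy()).all()

    def test_nan_cells_excluded(self):
        geom = pv.GridGeometry(10, 10, 1.0)
        layer = np.arange(100.0).reshape(10, 10)
        layer[:5] = np.nan
        stack = pv.ClimateStack(geom, 0.0, {"v": layer})
        with pytest.warns(UserWarning):
            bg = pv.sample_background(stack, 100, seed=0)
        assert len(bg) == 50
        assert np.isfinite(bg.env["v"]).all()

    def test_selection_frequency_is_uniform_within_binomial_error(self):
        geom = pv.GridGeometry(20, 20, 1.0)
        stack = pv.ClimateStack(geom, 0.0, {"v": np.arange(400.0).reshape(20, 20)})
        reps, k = 300, 100
        hits = np.zeros(400)
        for r in range(reps):
            bg = pv.sample_background(stack, k, seed=r)
            hits[bg.rows * 20 + bg.cols] += 1
        p = k / 400
        se = np.sqrt(p * (1 - p) / reps)
        assert np.abs(hits / reps - p).max() < 5 * se


def _binary_problem(n_presence=40, seed=0):
    """20-cell grid with one binary variable; presences prefer value 1."""
    geom = pv.GridGeometry(4, 5, 1.0)
    v = np.zeros((4, 5))
    v[:, 3:] = 1.0  # 8 cells carry value 1
    stack = pv.ClimateStack(geom, 0.0, {"v": v})
    rng = np.random.default_rng(seed)
    # 75% of presences on value-1 cells
    n1 = int(0.75 * n_presence)
    xs = np.concatenate([rng.uniform(3, 5, n1), rng.uniform(0, 3, n_presence - n1)])
    ys = rng.uniform(0, 4, n_presence)
    train = pv.OccurrenceSet("X", xs, ys)
    rows, cols = np.divmod(np.arange(20), 5)
    bg = pv.BackgroundSample(rows, cols, pd.DataFrame({"v": v[rows, cols]}), geom)
    return stack, train, bg


class TestFit:
    def test_constant_feature_yields_uniform_background_distribution(self):
        stack, train, bg = _binary_problem()
        const = pv.ClimateStack(stack.geometry, 0.0, {"v": np.full((4, 5), 3.0)})
        bg_const = pv.BackgroundSample(
            bg.rows, bg.cols, pd.DataFrame({"v": np.full(20, 3.0)}), stack.geometry
        )
        with pytest.warns(UserWarning):
            model = pv.fit_maxent(train, bg_const, const,
                                  feature_classes=("linear",))
        raw = model.raw(bg_const.env)
        np.testing.assert_allclose(raw, 1 / 20, atol=1e-9)
        np.testing.assert_allclose(
            model.cloglog(bg_const.env), 1 - np.exp(-1.0), atol=1e-9
        )

    def test_huge_penalty_drives_weights_to_zero(self):
        stack, train, bg = _binary_problem()
        with pytest.warns(UserWarning):
            model = pv.fit_maxent(train, bg, stack, beta=1e6,
                                  feature_classes=("linear",))
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-8)

    def test_fitted_weight_matches_one_dimensional_objective_scan(self):
        """Independent oracle: dense scan of the penalized objective in the
        single linear-feature case must agree with the solver to 1e-3."""
        stack, train, bg = _binary_problem()
        beta = 0.1
        with pytest.warns(UserWarning):
            model = pv.fit_maxent(train, bg, stack, beta=beta,
                                  feature_classes=("linear",))
        zp = model.features.transform(
            pv.maxent.env_at_points(stack, train, ("v",))
        ).ravel()
        zb = model.features.transform(bg.env).ravel()
        s = model.penalty_scales[0]
        lams = np.arange(-20.0, 20.0, 1e-3)
        sb = np.outer(lams, zb)
        obj = (
            -zp.mean() * lams
            + np.log(np.exp(sb).sum(axis=1))
            + beta * s * np.abs(lams)
        )
        assert model.weights[0] == pytest.approx(lams[obj.argmin()], abs=1e-3)

    def test_kkt_residuals_within_penalty_bound(self, fitted_small_model):
        m = fitted_small_model["model"]
        kkt = m.diagnostics["kkt_residuals"]
        assert (kkt <= m.beta * m.penalty_scales + 1e-4).all()

    def test_objective_history_non_increasing(self, fitted_small_model):
        hist = np.array(fitted_small_model["model"].diagnostics["objective_history"])
        assert (np.diff(hist) <= 1e-9).all()

    def test_too_few_presences_rejected(self, small_stack):
        bg = pv.sample_background(small_stack, 200, seed=0,
                                  variables=pv.NINE_PREDICTORS)
        with pytest.raises(ValueError):
            pv.fit_maxent(_occ(5, lo=1, hi=40), bg, small_stack,
                          variables=pv.NINE_PREDICTORS)


class TestPredict:
    def test_raw_sums_to_one_over_training_background(self, fitted_small_model):
        m = fitted_small_model["model"]
        bg = fitted_small_model["background"]
        assert m.raw(bg.env).sum() == pytest.approx(1.0, abs=1e-9)

    def test_cloglog_is_monotone_in_raw(self, fitted_small_model):
        m = fitted_small_model["model"]
        stack = fitted_small_model["stack"]
        raw = pv.predict_suitability(m, stack, "raw").values.ravel()
        clog = pv.predict_suitability(m, stack, "cloglog").values.ravel()
        order = np.argsort(raw)
        assert (np.diff(clog[order]) >= -1e-12).all()

    def test_missing_variable_rejected(self, fitted_small_model):
        m = fitted_small_model["model"]
        geom = pv.GridGeometry(8, 8, 1.0)
        stack = pv.ClimateStack(geom, 0.0, {"other": np.ones((8, 8))})
        with pytest.raises(KeyError):
            pv.predict_suitability(m, stack)

    def test_feature_values_bounded_in_unit_interval(self, fitted_small_model):
        m = fitted_small_model["model"]
        bg = fitted_small_model["background"]
        F = m.features.transform(bg.env)
        assert F.min() >= -1e-12
        assert F.max() <= 1 + 1e-12


class TestAUC:
    def test_perfect_separation(self):
        assert auc_presence_background([3, 4], [1, 2]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_presence_background([1, 1], [1, 1, 1]) == 0.5

    def test_worked_pair_counting_example(self):
        assert auc_presence_background([0.9, 0.4], [0.5, 0.1]) == 0.75

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=20),
           st.lists(st.integers(0, 6), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exhaustive_pair_counting(self, p, b):
        assert auc_presence_background(p, b) == pytest.approx(brute_force_auc(p, b))

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(10)
        p = rng.normal(1, 1, 80)
        b = rng.normal(0, 1, 200)
        y = np.r_[np.ones(80), np.zeros(200)]
        assert auc_presence_background(p, b) == pytest.approx(
            roc_auc_score(y, np.r_[p, b])
        )

    def test_invariant_under_monotone_transform_of_scores(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 40)
        b = rng.uniform(0, 1, 90)
        a1 = auc_presence_background(p, b)
        a2 = auc_presence_background(np.exp(5 * p), np.exp(5 * b))
        assert a1 == pytest.approx(a2)

    def test_raw_and_cloglog_scores_give_identical_auc(self, fitted_small_model):
        m = fitted_small_model["model"]
        bg = fitted_small_model["background"]
        test = fitted_small_model["test"]
        stack = fitted_small_model["stack"]
        te_env = pv.maxent.env_at_points(stack, test, m.features.variables)
        a_raw = auc_presence_background(m.raw(te_env), m.raw(bg.env))
        a_clog = auc_presence_background(m.cloglog(te_env), m.cloglog(bg.env))
        assert a_raw == pytest.approx(a_clog, abs=1e-12)

    def test_evaluate_auc_result_fields(self, fitted_small_model):
        ev = pv.evaluate_auc(
            fitted_small_model["model"],
            fitted_small_model["test"],
            fitted_small_model["background"],
            fitted_small_model["stack"],
        )
        assert 0.0 <= ev.auc <= 1.0
        assert ev.n_test == len(fitted_small_model["test"])


class TestSerialization:
    def test_model_round_trips_through_json(self, fitted_small_model, tmp_path):
        m = fitted_small_model["model"]
        path = tmp_path / "model.json"
        m.save(path)
        loaded = pv.NicheModel.load(path)
        bg = fitted_small_model["background"]
        np.testing.assert_allclose(loaded.raw(bg.env), m.raw(bg.env), rtol=1e-12)
        assert loaded.vu_id == m.vu_id
        assert loaded.entropy == pytest.approx(m.entropy)


class TestNicheRecovery:
    def test_high_suitability_cells_overlap_true_extent(self, small_stack, small_truth):
        """Cells above the 90th suitability percentile must overlap the
        generating unit's true extent with Jaccard >= 0.3."""
        occ = pv.sample_presences(small_truth, "EB", 1000, seed=21)
        train, _ = pv.split_occurrences(occ, 0.25, seed=22)
        bg = pv.sample_background(small_stack, 1000, seed=23,
                                  variables=pv.NINE_PREDICTORS)
        model = pv.fit_maxent(train, bg, small_stack, variables=pv.NINE_PREDICTORS)
        surf = pv.predict_suitability(model, small_stack)
        top = surf.values >= np.percentile(surf.values, 90)
        truth_mask = small_truth.mask("EB")
        jacc = (top & truth_mask).sum() / (top | truth_mask).sum()
        assert jacc >= 0.3

    def test_smaller_extent_scores_higher_auc(self, small_stack, small_truth):
        """Narrow-belt units evaluate better than widespread ones under
        identical settings (extent-AUC anticorrelation)."""
        bg = pv.sample_background(small_stack, 1000, seed=31,
                                  variables=pv.NINE_PREDICTORS)
        counts = small_truth.counts()
        small_u = min(pv.DEFAULT_UNITS, key=lambda u: counts[u] or 10**9)
        large_u = max(pv.DEFAULT_UNITS, key=lambda u: counts[u])
        aucs = {}
        for u in (small_u, large_u):
            occ = pv.sample_presences(small_truth, u, 600, seed=32)
            train, test = pv.split_occurrences(occ, 0.25, seed=33)
            m = pv.fit_maxent(train, bg, small_stack, variables=pv.NINE_PREDICTORS)
            aucs[u] = pv.evaluate_auc(m, test, bg, small_stack).auc
        assert aucs[small_u] > aucs[large_u]
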