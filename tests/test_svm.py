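import numpy as np
import pytest

from nfcps.features import build_dataset
from nfcps.svm import (
    DEFAULT_C_GRID,
    SoftMarginLinearSVM,
    finalize,
    pick_median_state,
    run_protocol,
    select_random_state,
    tune_c,
)

from .oracles import brute_force_dual_svm


def signed(y):
    return np.where(np.asarray(y) == "VE", 1.0, -1.0)


class TestFitBasics:
    def test_symmetric_pair_boundary_at_origin(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["CE", "VE"])
        model = SoftMarginLinearSVM(C=1e6).fit(X, y)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-6)
        assert model.coef_[0] == pytest.approx(1.0, abs=1e-6)
        margins = signed(y) * model.decision_function(X)
        assert np.allclose(margins, 1.0, atol=1e-6)
        assert np.all(model.dual_multipliers_ > 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            SoftMarginLinearSVM(C=1.0).fit([[0.0], [1.0]], ["CE", "CE"])

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError, match="C"):
            SoftMarginLinearSVM(C=0.0).fit([[0.0], [1.0]], ["CE", "VE"])

    def test_dimension_mismatch_rejected(self):
        model = SoftMarginLinearSVM(C=1.0).fit([[0.0], [1.0]], ["CE", "VE"])
        with pytest.raises(ValueError, match="feature"):
            model.predict([[0.0, 1.0]])

    def test_boundary_tie_goes_to_ve(self):
        X = np.array([[-1.0], [1.0]])
        model = SoftMarginLinearSVM(C=10.0).fit(X, ["CE", "VE"])
        assert model.predict([[0.0]])[0] == "VE"

    def test_predictions_match_manual_decision_function(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, "VE", "CE")
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        model = SoftMarginLinearSVM(C=2.0).fit(X, y)
        Xq = rng.normal(size=(20, 2))
        manual = Xq @ model.coef_ + model.intercept_
        expected = np.where(manual >= 0, "VE", "CE")
        assert np.array_equal(model.predict(Xq), expected)


class TestKktInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_fitted_models_satisfy_kkt(self, seed, default_features):
        ds = build_dataset(default_features, "ab", random_state=seed + 1)
        X, y = ds.rows("train")
        model = SoftMarginLinearSVM(C=1.0).fit(X, y)
        lam = model.dual_multipliers_
        ys = signed(y)
        assert np.all(lam >= -1e-6) and np.all(lam <= model.C + 1e-6)
        assert abs(lam @ ys) < 1e-6
        assert np.allclose((lam * ys) @ X, model.coef_, atol=1e-6)
        # margin support vectors (0 < lam < C) sit exactly on the margin
        on_margin = (lam > 1e-6) & (lam < model.C - 1e-6)
        if on_margin.any():
            margins = ys[on_margin] * model.decision_function(X[on_margin])
            assert np.allclose(margins, 1.0, atol=1e-4)

    def test_strong_duality_on_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(8, 2))
            y = np.where(rng.random(8) > 0.5, "VE", "CE")
            if len(set(y)) < 2:
                continue
            model = SoftMarginLinearSVM(C=1.0).fit(X, y)
            assert model.primal_objective() == pytest.approx(
                model.dual_objective(), abs=1e-4)


class TestOracleAgreement:
    def test_four_point_line_matches_brute_force_dual(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["CE", "CE", "VE", "VE"])
        model = SoftMarginLinearSVM(C=1.0).fit(X, y)
        oracle = brute_force_dual_svm(X, signed(y), C=1.0)
        assert model.coef_[0] == pytest.approx(oracle["w"][0], abs=1e-3)
        assert model.intercept_ == pytest.approx(oracle["b"], abs=1e-3)
        assert model.dual_objective() == pytest.approx(
            oracle["dual_objective"], abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_toys_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 7))
        d = int(rng.integers(1, 3))
        X = np.round(rng.normal(size=(m, d)), 2)
        y_signed = np.ones(m)
        y_signed[: m // 2] = -1.0
        C = float(rng.choice([0.5, 1.0, 2.0]))
        y = np.where(y_signed > 0, "VE", "CE")
        model = SoftMarginLinearSVM(C=C).fit(X, y)
        oracle = brute_force_dual_svm(X, y_signed, C=C)
        assert model.dual_objective() == pytest.approx(
            oracle["dual_objective"], abs=2e-3)
        assert np.allclose(model.coef_, oracle["w"], atol=5e-3)

    def test_duplicated_rows_leave_decision_unchanged(self):
        X = np.array([[-2.0], [-0.5], [0.7], [2.0]])
        y = np.array(["CE", "CE", "VE", "VE"])
        a = SoftMarginLinearSVM(C=1.0).fit(X, y)
        b = SoftMarginLinearSVM(C=1.0).fit(np.vstack([X, X]), np.concatenate([y, y]))
        grid = np.linspace(-3, 3, 41)[:, None]
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_hard_margin_limit_recovers_max_margin_separator(self):
        # hulls end at -1 and +2 -> midpoint 0.5, margin half-width 1.5
        X = np.array([[-3.0], [-1.0], [2.0], [4.0]])
        y = np.array(["CE", "CE", "VE", "VE"])
        model = SoftMarginLinearSVM(C=1e7).fit(X, y)
        assert model.coef_[0] == pytest.approx(1 / 1.5, abs=1e-4)
        assert -model.intercept_ / model.coef_[0] == pytest.approx(0.5, abs=1e-4)

    def test_training_error_nonincreasing_in_c_on_separable_data(self):
        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(-3, 0.5, 25), rng.normal(3, 0.5, 25)])[:, None]
        y = np.array(["CE"] * 25 + ["VE"] * 25)
        errors = []
        for C in (1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0):
            model = SoftMarginLinearSVM(C=C).fit(X, y)
            errors.append(1.0 - model.score(X, y))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] == 0.0


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path, default_features):
        ds = build_dataset(default_features, "abg", random_state=1)
        model = finalize(ds, c=0.7)
        path = tmp_path / "model.json"
        model.save(path)
        back = SoftMarginLinearSVM.load(path)
        assert np.allclose(back.coef_, model.coef_, atol=1e-12, rtol=0)
        assert back.intercept_ == pytest.approx(model.intercept_, abs=1e-12)
        assert np.allclose(back.dual_multipliers_, model.dual_multipliers_,
                           atol=1e-12, rtol=0)
        assert back.meta_["combination"] == "abg"
        X, _ = ds.rows("test")
        assert np.array_equal(back.predict(X), model.predict(X))

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="format"):
            SoftMarginLinearSVM.load(p)


class TestTuneC:
    def test_grid_is_100_values_from_0p1_to_10(self):
        assert len(DEFAULT_C_GRID) == 100
        assert DEFAULT_C_GRID[0] == pytest.approx(0.1)
        assert DEFAULT_C_GRID[-1] == pytest.approx(10.0)
        assert np.allclose(np.diff(DEFAULT_C_GRID), 0.1)

    def test_separable_data_ties_resolve_to_lowest_c(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-5, 0.3, 20), rng.normal(5, 0.3, 20)])[:, None]
        y = np.array(["CE"] * 20 + ["VE"] * 20)
        assert tune_c(X, y, fold_seed=0) == pytest.approx(0.1)

    def test_matches_independent_cv_recomputation(self):
        from sklearn.model_selection import StratifiedKFold
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(-0.5, 1.0, 6), rng.normal(0.5, 1.0, 6)])[:, None]
        y = np.array(["CE"] * 6 + ["VE"] * 6)
        grid = (0.1, 0.5, 1.0, 5.0)
        c_star = tune_c(X, y, c_grid=grid, folds=3, fold_seed=1)
        # independent re-computation of the same CV loop
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=1)
        splits = list(skf.split(X, y))
        means = []
        for c in grid:
            accs = [SoftMarginLinearSVM(C=c).fit(X[tr], y[tr]).score(X[va], y[va])
                    for tr, va in splits]
            means.append(np.mean(accs))
        expected = grid[int(np.argmax(means))]  # argmax returns first = lowest C
        assert c_star == pytest.approx(expected)

    def test_folds_reduced_when_class_too_small(self, caplog):
        X = np.arange(8, dtype=float)[:, None]
        y = np.array(["CE"] * 3 + ["VE"] * 5)
        import logging
        with caplog.at_level(logging.WARNING, logger="nfcps.svm"):
            tune_c(X, y, c_grid=(1.0,), folds=10, fold_seed=0)
        assert any("reducing CV folds" in r.message for r in caplog.records)


class TestStateSelection:
    def test_median_tie_breaks_to_lowest_state(self):
        assert pick_median_state({1: 0.9, 2: 0.9, 3: 0.9, 4: 0.9, 5: 0.9}) == 1

    def test_median_of_five_accuracies(self):
        accs = {1: 0.7, 2: 0.8, 3: 0.9, 4: 0.9, 5: 1.0}
        assert pick_median_state(accs) == 3

    def test_separable_synthetic_data_selects_state_one(self):
        from .conftest import blob_features
        state, accs = select_random_state(blob_features(), "ab", c=1.0)
        assert set(accs.values()) == {1.0}
        assert state == 1


class TestProtocol:
    def test_finalize_uses_train_plus_validation_only(self, default_features):
        ds = build_dataset(default_features, "ab", random_state=2)
        model = finalize(ds, c=1.0)
        X_tv, _ = ds.rows("train", "validation")
        assert model.dual_multipliers_.shape[0] == X_tv.shape[0]
        assert X_tv.shape[0] == 184 - ds.n_rows("test")

    def test_noise_free_cohort_classified_perfectly(self, noise_free_features):
        result = run_protocol(noise_free_features, "ab", fold_seed=0)
        X_te, y_te = result.dataset.rows("test")
        assert result.model.score(X_te, y_te) == 1.0

    def test_protocol_result_records_choices(self, noise_free_features):
        result = run_protocol(noise_free_features, "αβ", fold_seed=0)
        assert result.combination == "ab"
        assert result.c_star in DEFAULT_C_GRID
        assert result.state_star in (1, 2, 3, 4, 5)
        assert len(result.validation_accuracies) == 5
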