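import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from luxsat import surrogate as sg


@pytest.fixture(scope="module")
def norm_spec():
    return sg.NormalizationSpec(np.array([10.0]), np.array([30.0]))


class TestNormalization:
    def test_endpoints_and_midpoint(self, norm_spec):
        assert sg.normalize(10.0, norm_spec) == pytest.approx(0.2)
        assert sg.normalize(30.0, norm_spec) == pytest.approx(0.9)
        assert sg.normalize(20.0, norm_spec) == pytest.approx(0.55)

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, x):
        spec = sg.NormalizationSpec(np.array([-1e4]), np.array([1e4]))
        back = float(np.asarray(sg.denormalize(sg.normalize(x, spec), spec)).ravel()[0])
        assert back == pytest.approx(x, rel=1e-12, abs=1e-9)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sg.NormalizationSpec(np.array([5.0]), np.array([5.0]))

    def test_per_variable_statistics(self):
        x = np.array([[0.0, 100.0], [10.0, 300.0]])
        spec = sg.NormalizationSpec.fit(x)
        np.testing.assert_allclose(sg.normalize(x, spec)[0], [0.2, 0.2])
        np.testing.assert_allclose(sg.normalize(x, spec)[1], [0.9, 0.9])


class TestSplit:
    def test_round_of_85_percent_of_420(self, noisy_samples):
        train, test = sg.split_train_test(noisy_samples, 0.85, seed=0)
        assert len(train) == 357 and len(test) == 63

    def test_partition_law(self, noisy_samples):
        sub = noisy_samples.head(10)
        train, test = sg.split_train_test(sub, 0.5, seed=3)
        assert len(train) == 5 and len(test) == 5
        merged = pd.concat([train, test]).sort_values(list(sub.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            merged, sub.sort_values(list(sub.columns)).reset_index(drop=True)
        )

    def test_same_seed_same_partition(self, noisy_samples):
        a = sg.split_train_test(noisy_samples, 0.85, seed=7)
        b = sg.split_train_test(noisy_samples, 0.85, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_invalid_fraction_rejected(self, noisy_samples):
        with pytest.raises(ValueError):
            sg.split_train_test(noisy_samples, 1.0, seed=0)


class TestSvm:
    def test_paper_hyperparameters_fit_noiseless_grid(self, noiseless_samples):
        """At the published (c, g) = (2.82, 0.50) the SVR reproduces the
        noiseless synthetic surface closely on the held-out split."""
        train, test = sg.split_train_test(noiseless_samples, 0.85, seed=1)
        model = sg.fit_svm(train, sg.SvmConfig(c=2.82, g=0.50))
        rep = sg.evaluate(model, test)
        assert rep.r2 > 0.98
        assert model.nsv <= len(train)

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({
            "temp_c": rng.uniform(10, 30, 50),
            "co2_umol_mol": rng.uniform(300, 2000, 50),
            "ppfd_umol_m2_s": rng.uniform(0, 1400, 50),
            "pn_umol_m2_s": 5.0,
        })
        model = sg.fit_svm(train)
        pred = model.predict(train.temp_c, train.co2_umol_mol, train.ppfd_umol_m2_s)
        # constant target: predictions constant to within the epsilon tube
        assert np.ptp(pred) <= 2 * model.config.epsilon * 1.0 + 1e-6

    def test_training_point_within_tube(self, noiseless_samples):
        train, _ = sg.split_train_test(noiseless_samples, 0.85, seed=1)
        cfg = sg.SvmConfig(c=100.0, g=1.0, epsilon=0.01)
        model = sg.fit_svm(train, cfg)
        pred = model.predict(train.temp_c, train.co2_umol_mol, train.ppfd_umol_m2_s)
        # SVR tube property in normalized units, with solver slack
        y_span = train.pn_umol_m2_s.max() - train.pn_umol_m2_s.min()
        tube_raw = cfg.epsilon * y_span / 0.7
        frac_in_tube = np.mean(np.abs(pred - train.pn_umol_m2_s) <= tube_raw * 1.5)
        assert frac_in_tube >= 0.95

    def test_predict_matches_explicit_kernel_expansion(self):
        """Term-by-term oracle on a 3-support-vector toy model."""
        x_norm = sg.NormalizationSpec(np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, 1.0]))
        y_norm = sg.NormalizationSpec(np.array([0.0]), np.array([10.0]))
        sv = np.array([[0.3, 0.4, 0.5], [0.6, 0.2, 0.8], [0.5, 0.5, 0.5]])
        dual = np.array([0.7, -0.4, 0.1])
        g, b = 0.8, 0.25
        model = sg.SvmModel(x_norm, y_norm, sv, dual, b, sg.SvmConfig(c=1.0, g=g))
        q_raw = np.array([0.45, 0.55, 0.65])
        qn = sg.normalize(q_raw, x_norm)
        expected_norm = b + sum(
            d * np.exp(-g * np.sum((s - qn) ** 2)) for d, s in zip(dual, sv)
        )
        expected = float(sg.denormalize(np.array([expected_norm]), y_norm)[0])
        got = model.predict(*q_raw)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_dual_coefficients_give_bias(self):
        x_norm = sg.NormalizationSpec(np.zeros(3), np.ones(3))
        y_norm = sg.NormalizationSpec(np.array([0.0]), np.array([1.0]))
        model = sg.SvmModel(x_norm, y_norm, np.zeros((2, 3)), np.zeros(2), 0.55,
                            sg.SvmConfig())
        expected = float(sg.denormalize(np.array([0.55]), y_norm)[0])
        assert model.predict(0.5, 0.5, 0.5) == pytest.approx(expected)


class TestTuneSvm:
    def test_singleton_grid_returned(self, noisy_samples):
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=0)
        cfg = sg.tune_svm(train.head(60), [2.82], [0.5], k_folds=3, seed=0)
        assert (cfg.c, cfg.g) == (2.82, 0.5)

    def test_matches_exhaustive_cv_oracle(self, noisy_samples):
        """Independent exhaustive CV loop over the same folds agrees."""
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=0)
        sub = train.head(120)
        c_grid, g_grid = [0.5, 2.82, 20.0], [0.1, 0.5, 2.0]
        chosen = sg.tune_svm(sub, c_grid, g_grid, k_folds=4, seed=9)

        x = sub[list(sg.FEATURES)].to_numpy()
        y = sub[sg.TARGET].to_numpy()
        x_norm = sg.NormalizationSpec.fit(x)
        y_norm = sg.NormalizationSpec(np.array([y.min()]), np.array([y.max()]))
        xn = sg.normalize(x, x_norm)
        yn = sg.normalize(y[:, None], y_norm).ravel()
        folds = list(KFold(4, shuffle=True, random_state=9).split(xn))
        scores = {}
        for c in c_grid:
            for g in g_grid:
                sq = [
                    np.mean(
                        (SVR(kernel="rbf", C=c, gamma=g, epsilon=0.01, tol=1e-6)
                         .fit(xn[tr], yn[tr]).predict(xn[te]) - yn[te]) ** 2
                    )
                    for tr, te in folds
                ]
                scores[(c, g)] = np.sqrt(np.mean(sq))
        best = min(scores, key=lambda k: (round(scores[k], 12), k))
        assert (chosen.c, chosen.g) == best

    def test_deterministic(self, noisy_samples):
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=0)
        sub = train.head(60)
        a = sg.tune_svm(sub, [1.0, 10.0], [0.5, 2.0], k_folds=3, seed=4)
        b = sg.tune_svm(sub, [1.0, 10.0], [0.5, 2.0], k_folds=3, seed=4)
        assert a == b

    def test_too_many_folds_rejected(self, noisy_samples):
        with pytest.raises(ValueError):
            sg.tune_svm(noisy_samples.head(4), [1.0], [1.0], k_folds=10, seed=0)


class TestRbfNet:
    def test_interpolation_limit(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame({
            "temp_c": rng.uniform(10, 30, 25),
            "co2_umol_mol": rng.uniform(300, 2000, 25),
            "ppfd_umol_m2_s": rng.uniform(0, 1400, 25),
            "pn_umol_m2_s": rng.uniform(0, 20, 25),
        })
        model = sg.fit_rbf_net(train, spread=0.3, goal=1e-4)
        assert model.converged

    def test_heldout_fidelity_on_noiseless_grid(self, noiseless_samples):
        train, test = sg.split_train_test(noiseless_samples, 0.85, seed=1)
        model = sg.fit_rbf_net(train)
        assert model.converged
        assert sg.evaluate(model, test).r2 >= 0.95

    def test_center_cap_flags_unconverged(self, noisy_samples):
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=1)
        model = sg.fit_rbf_net(train, goal=1e-12, max_centers=3)
        assert not model.converged
        assert len(model.centers) == 3

    def test_invalid_spread_rejected(self, noisy_samples):
        with pytest.raises(ValueError):
            sg.fit_rbf_net(noisy_samples, spread=0.0)


class TestBpNet:
    def _linear_frame(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        ppfd = rng.uniform(0, 1400, n)
        return pd.DataFrame({
            "temp_c": rng.uniform(10, 30, n),
            "co2_umol_mol": rng.uniform(300, 2000, n),
            "ppfd_umol_m2_s": ppfd,
            "pn_umol_m2_s": 2.0 * ppfd / 1400.0,
        })

    def test_easy_linear_function(self):
        df = self._linear_frame()
        train, test = sg.split_train_test(df, 0.8, seed=1)
        model = sg.fit_bp_net(train, seed=1)
        rep = sg.evaluate(model, test)
        # RMSE in normalized target units must be small for a linear target
        y_span = train.pn_umol_m2_s.max() - train.pn_umol_m2_s.min()
        assert rep.rmse * 0.7 / y_span <= 0.05

    def test_deterministic_weights(self, noisy_samples):
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=1)
        a = sg.fit_bp_net(train.head(100), seed=5, max_epochs=50)
        b = sg.fit_bp_net(train.head(100), seed=5, max_epochs=50)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)

    def test_zero_epochs_returns_initialized_unconverged(self, noisy_samples):
        model = sg.fit_bp_net(noisy_samples.iloc[::8], max_epochs=0, seed=0)
        assert not model.converged

    def test_stops_at_goal(self, noiseless_samples):
        """With the published goal (1e-4 normalized MSE) training halts once
        reached rather than running all 1000 epochs."""
        train, _ = sg.split_train_test(noiseless_samples, 0.85, seed=1)
        model = sg.fit_bp_net(train, goal=1e-4, max_epochs=1000, seed=1)
        assert model.converged
        xn = sg.normalize(train[list(sg.FEATURES)].to_numpy(), model.x_norm)
        yn = sg.normalize(train[[sg.TARGET]].to_numpy(), model.y_norm).ravel()
        mse = np.mean((model._predict_norm(xn) - yn) ** 2)
        assert mse <= 1e-4


class TestEvaluate:
    def _frame(self, obs):
        n = len(obs)
        return pd.DataFrame({
            "temp_c": np.full(n, 20.0), "co2_umol_mol": np.full(n, 1000.0),
            "ppfd_umol_m2_s": np.linspace(100, 1400, n), "pn_umol_m2_s": obs,
        })

    class _Stub(sg.SurrogateModel):
        kind = "stub"

        def __init__(self, values):
            self.values = np.asarray(values, dtype=float)

        def predict(self, temp, co2, ppfd):
            return self.values

    def test_perfect_fit(self):
        obs = np.array([1.0, 2.0, 3.0])
        rep = sg.evaluate(self._Stub(obs), self._frame(obs))
        assert (rep.mae, rep.rmse) == (0.0, 0.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_unit_error(self):
        rep = sg.evaluate(self._Stub([2.0, 3.0, 4.0]), self._frame([1.0, 2.0, 3.0]))
        assert rep.mae == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)

    def test_mre_ten_percent(self):
        rep = sg.evaluate(self._Stub([1.1, 1.8]), self._frame([1.0, 2.0]))
        assert rep.mre == pytest.approx(10.0)

    def test_mre_excludes_near_zero_observations(self):
        rep = sg.evaluate(self._Stub([0.05, 2.2]), self._frame([0.01, 2.0]))
        assert rep.mre == pytest.approx(10.0)  # only the |obs| >= 0.1 row counts

    def test_all_excluded_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="MRE"):
            rep = sg.evaluate(self._Stub([0.0, 0.0]), self._frame([0.01, -0.02]))
        assert np.isnan(rep.mre)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rmse_at_least_mae(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(5, 3, 20)
        pred = obs + rng.normal(0, 1, 20)
        rep = sg.evaluate(self._Stub(pred), self._frame(obs))
        assert rep.rmse >= rep.mae - 1e-12


class TestPersistence:
    @pytest.mark.parametrize("kind", ["svm", "rbf", "bp"])
    def test_json_round_trip_reproduces_predictions(self, kind, noisy_samples, tmp_path):
        train, test = sg.split_train_test(noisy_samples, 0.85, seed=2)
        train = train.head(80)
        if kind == "svm":
            model = sg.fit_svm(train)
        elif kind == "rbf":
            model = sg.fit_rbf_net(train, goal=1e-3, max_centers=30)
        else:
            model = sg.fit_bp_net(train, max_epochs=50, seed=3)
        path = tmp_path / "model.json"
        sg.save_model(model, path)
        back = sg.load_model(path)
        q = (test.temp_c.to_numpy(), test.co2_umol_mol.to_numpy(),
             test.ppfd_umol_m2_s.to_numpy())
        np.testing.assert_allclose(back.predict(*q), model.predict(*q), atol=1e-10)

    def test_json_is_plain_text(self, noisy_samples, tmp_path):
        train, _ = sg.split_train_test(noisy_samples, 0.85, seed=2)
        model = sg.fit_svm(train.iloc[::9])
        path = tmp_path / "model.json"
        sg.save_model(model, path)
        doc = json.loads(path.read_text())
        assert doc["kind"] == "svm"
        assert set(doc) >= {"x_norm", "y_norm", "support_vectors", "dual_coef", "bias"}
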