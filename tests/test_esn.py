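"""Reservoir mechanics: spectral scaling, state iteration, ridge readout,
sigmoid thresholding, quadrant combination and memory capacity."""

import numpy as np
import pytest

from phytoaffect.errors import ConfigError, DataError, DegenerateAnalysisError
from phytoaffect.esn import (
    ReservoirConfig,
    combine_quadrant,
    fit_readout,
    init_reservoir,
    load_reservoir_model,
    predict_binary,
    ridge_fit,
    run_reservoir,
    save_reservoir_model,
)


class TestInitReservoir:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_spectral_radius_scaled_exactly(self, seed):
        res = init_reservoir(ReservoirConfig(n_units=100, seed=seed), 3)
        radius = np.max(np.abs(np.linalg.eigvals(res.W)))
        assert abs(radius - 0.9) < 1e-6

    def test_same_seed_reproduces_weights(self):
        cfg = ReservoirConfig(n_units=50, seed=5)
        a, b = init_reservoir(cfg, 4), init_reservoir(cfg, 4)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.W_in, b.W_in)

    def test_zero_input_scaling_zeroes_input_weights(self):
        res = init_reservoir(
            ReservoirConfig(n_units=20, input_scaling=0.0, seed=1), 2
        )
        assert not res.W_in.any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ReservoirConfig(leak=0.0)
        with pytest.raises(ConfigError):
            ReservoirConfig(n_units=0)


class TestRunReservoir:
    def test_zero_input_zero_state_stays_at_fixed_point(self):
        res = init_reservoir(ReservoirConfig(n_units=10, seed=0), 1)
        X = run_reservoir(res, np.zeros((20, 1)))
        np.testing.assert_array_equal(X, 0.0)

    def test_full_leak_no_recurrence_is_memoryless(self):
        res = init_reservoir(ReservoirConfig(n_units=8, leak=1.0, seed=2), 2)
        res.W[:] = 0.0
        U = np.random.default_rng(3).standard_normal((15, 2))
        X = run_reservoir(res, U)
        np.testing.assert_allclose(X, np.tanh(U @ res.W_in.T), atol=1e-12)

    def test_matches_hand_unrolled_three_unit_iteration(self):
        res = init_reservoir(ReservoirConfig(n_units=3, leak=0.2, density=1.0, seed=7), 2)
        U = np.random.default_rng(8).standard_normal((5, 2))
        X = run_reservoir(res, U)
        x = np.zeros(3)
        for t in range(5):
            x = 0.8 * x + 0.2 * np.tanh(res.W_in @ U[t] + res.W @ x)
            np.testing.assert_allclose(X[t], x, atol=1e-12)

    def test_states_contained_in_unit_box(self):
        res = init_reservoir(ReservoirConfig(n_units=30, seed=4), 2)
        U = 10.0 * np.random.default_rng(5).standard_normal((200, 2))
        X = run_reservoir(res, U)
        assert np.abs(X).max() <= 1.0

    def test_fading_memory_forgets_initial_state(self):
        res = init_reservoir(ReservoirConfig(n_units=50, seed=6), 1)
        U = np.random.default_rng(7).standard_normal((1200, 1))
        x0 = np.random.default_rng(8).uniform(-1, 1, 50)
        X_zero = run_reservoir(res, U)
        X_rand = run_reservoir(res, U, x0)
        assert np.abs(X_zero[-1] - X_rand[-1]).max() < 1e-6

    def test_silent_input_decays_to_rest(self):
        res = init_reservoir(ReservoirConfig(n_units=30, seed=9), 1)
        x0 = np.random.default_rng(10).uniform(-1, 1, 30)
        X = run_reservoir(res, np.zeros((1500, 1)), x0)
        assert np.linalg.norm(X[-1]) < 1e-6

    def test_nan_input_identified(self):
        res = init_reservoir(ReservoirConfig(n_units=5, density=1.0, seed=0), 1)
        U = np.zeros((4, 1))
        U[2, 0] = np.nan
        with pytest.raises(DataError, match="step 2"):
            run_reservoir(res, U)


class TestReadout:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((10, 4))
        y = np.where(rng.random(10) > 0.5, 1.0, -1.0)
        lam = 0.7
        w = ridge_fit(X, y, lam)
        G = np.column_stack([X, np.ones(10)])
        D = np.eye(5)
        D[-1, -1] = 0.0
        w_oracle = np.linalg.solve(G.T @ G + lam * D, G.T @ y)
        np.testing.assert_allclose(w, w_oracle, atol=1e-8)

    def test_huge_penalty_shrinks_weights_to_bias(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((50, 3))
        y = np.r_[np.ones(30), np.zeros(20)]
        cfg = ReservoirConfig(washout=0, ridge_penalty=1e12)
        model = fit_readout(X, y, cfg)
        assert np.abs(model.W_out[:-1]).max() < 1e-6
        # bias approaches the mean of the +/-1 encoded targets
        assert abs(model.W_out[-1] - (30 - 20) / 50) < 1e-6

    def test_zero_penalty_interpolates_separable_data(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((12, 20))  # overdetermined features
        y = (rng.random(12) > 0.5).astype(int)
        y[0], y[1] = 0, 1  # both classes
        cfg = ReservoirConfig(washout=0, ridge_penalty=0.0)
        model = fit_readout(X, y, cfg)
        _, _, cls = predict_binary(model, X)
        np.testing.assert_array_equal(cls, y)

    def test_washout_rows_excluded(self):
        X = np.r_[np.full((5, 2), 1e6), np.random.default_rng(14).standard_normal((20, 2))]
        y = np.r_[np.zeros(5), np.tile([0, 1], 10)]
        cfg = ReservoirConfig(washout=5, ridge_penalty=1.0)
        model = fit_readout(X, y, cfg)
        oracle = ridge_fit(X[5:], np.where(y[5:] > 0, 1.0, -1.0), 1.0)
        np.testing.assert_allclose(model.W_out, oracle, atol=1e-10)

    def test_single_class_fold_refused(self):
        X = np.random.default_rng(15).standard_normal((30, 3))
        with pytest.raises(DegenerateAnalysisError, match="single-class"):
            fit_readout(X, np.ones(30), ReservoirConfig(washout=0))


class TestPrediction:
    def test_sigmoid_midpoint_and_saturation(self):
        from phytoaffect.esn import ReadoutModel

        model = ReadoutModel(W_out=np.array([1.0, 0.0]))  # score = x
        scores, probs, cls = predict_binary(model, np.array([[0.0], [4.0], [-4.0]]))
        np.testing.assert_allclose(probs[0], 0.5)
        assert abs(probs[1] - 0.982) < 1e-3
        np.testing.assert_array_equal(cls, [0, 1, 0])  # strict > at 0

    def test_probability_threshold_equals_score_threshold(self):
        from phytoaffect.esn import ReadoutModel

        rng = np.random.default_rng(16)
        model = ReadoutModel(W_out=rng.standard_normal(4))
        X = rng.standard_normal((100, 3))
        scores, probs, cls = predict_binary(model, X)
        np.testing.assert_array_equal(cls, (probs > 0.5).astype(np.int8))
        np.testing.assert_array_equal(cls, (scores > 0).astype(np.int8))

    def test_combine_quadrant_matches_sign_table(self):
        q = combine_quadrant([1, 0, 1, 0], [0, 1, 1, 0])
        np.testing.assert_array_equal(q, [2, 1, 3, 0])


class TestCapacity:
    def test_one_step_delay_memory_benchmark(self):
        """A 300-unit reservoir decodes a 1-step-delayed copy of random
        binary input well above 95% accuracy.

        Run at leak 0.5: the production leak of 0.2 deliberately smears
        single steps into a running average (longer-horizon memory), so
        one-step acuity is not the regime it is tuned for.
        """
        cfg = ReservoirConfig(leak=0.5, seed=20)
        res = init_reservoir(cfg, 1)
        rng = np.random.default_rng(21)
        u = (rng.random(1500) > 0.5).astype(float)
        X = run_reservoir(res, u[:, None])
        target = np.roll(u, 1)
        model = fit_readout(X[:1000], target[:1000], cfg)
        _, _, cls = predict_binary(model, X[1000:])
        assert (cls == target[1000:]).mean() > 0.95


class TestSerialisation:
    def test_round_trip_reproduces_model(self, tmp_path):
        cfg = ReservoirConfig(n_units=20, seed=3)
        res = init_reservoir(cfg, 2)
        X = run_reservoir(res, np.random.default_rng(4).standard_normal((60, 2)))
        model = fit_readout(X, np.tile([0, 1], 30), cfg, trained_on="fold-0")
        path = tmp_path / "model.json"
        save_reservoir_model(path, cfg, 2, {"v": model})
        res2, readouts = load_reservoir_model(path)
        np.testing.assert_array_equal(res.W, res2.W)
        np.testing.assert_allclose(readouts["v"].W_out, model.W_out, atol=1e-12)
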