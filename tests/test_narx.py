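import numpy as np
import pytest

from emgdecode import (NarxConfig, TrainOptions, count_parameters,
                       init_parameters, load_model, predict_series_parallel,
                       save_model, simulate_parallel, train, vaf)
from emgdecode.errors import InputError, TrainingError
from emgdecode.narx import _pack


class TestCountParameters:
    @pytest.mark.parametrize("kwargs, expected", [
        # default architecture: 6 inputs x 1 tap, 3 outputs x 2 taps, 3 hidden
        ({}, 51),
        # minimal network: every weight enumerable by hand
        (dict(n_inputs=1, n_outputs=1, n_hidden=1, input_taps=1,
              feedback_taps=1), 5),
        # literal 3-taps-per-signal reading of the published lag ranges;
        # inconsistent with the published total of 51, kept for reference
        (dict(input_taps=3, feedback_taps=3), 96),
    ])
    def test_enumeration(self, kwargs, expected):
        assert count_parameters(NarxConfig(**kwargs)) == expected

    def test_matches_initialized_tensor_sizes(self):
        config = NarxConfig()
        params = init_parameters(config, seed=0)
        assert params.n_parameters() == count_parameters(config)


class TestInitParameters:
    def test_deterministic_per_seed(self):
        a = init_parameters(NarxConfig(), seed=42)
        b = init_parameters(NarxConfig(), seed=42)
        np.testing.assert_array_equal(_pack(a), _pack(b))

    def test_different_seeds_differ(self):
        a = init_parameters(NarxConfig(), seed=1)
        b = init_parameters(NarxConfig(), seed=2)
        assert not np.array_equal(_pack(a), _pack(b))


def _rand_inputs(n, config, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 1, (n, config.n_inputs))


class TestForwardPasses:
    def test_zero_weights_output_bias(self):
        config = NarxConfig()
        params = init_parameters(config, seed=0)
        params.A[:] = 0; params.B[:] = 0; params.C[:] = 0; params.b1[:] = 0
        params.b2 = np.array([10.0, 20.0, 30.0])
        env = _rand_inputs(50, config)
        ang = np.zeros((50, 3))
        pred = predict_series_parallel(params, env, ang)
        np.testing.assert_allclose(pred[config.burn_in:],
                                   np.tile([10.0, 20.0, 30.0], (50 - config.burn_in, 1)))
        sim = simulate_parallel(params, env, ang[:config.burn_in])
        np.testing.assert_allclose(sim[config.burn_in:], pred[config.burn_in:])

    def test_teacher_self_consistency(self, teacher):
        """Feeding a teacher's own closed-loop trajectory back as 'measured'
        reproduces it exactly in both modes."""
        params, env, ang = teacher
        burn = params.config.burn_in
        pred = predict_series_parallel(params, env, ang)
        np.testing.assert_allclose(pred[burn:], ang[burn:], atol=1e-10)
        sim = simulate_parallel(params, env, ang[:burn])
        np.testing.assert_allclose(sim, ang, atol=1e-10)

    def test_zero_feedback_weights_make_modes_identical(self):
        config = NarxConfig()
        params = init_parameters(config, seed=3)
        params.A *= 5
        params.B[:] = 0.0
        env = _rand_inputs(200, config, seed=4)
        measured = np.random.default_rng(5).normal(size=(200, 3))
        open_loop = predict_series_parallel(params, env, measured)
        closed = simulate_parallel(params, env, measured[:config.burn_in])
        np.testing.assert_allclose(closed[config.burn_in:],
                                   open_loop[config.burn_in:], atol=0)

    def test_shift_equivariance(self):
        config = NarxConfig()
        params = init_parameters(config, seed=6)
        params.A *= 4; params.B *= 3; params.C *= 2
        env = _rand_inputs(150, config, seed=7)
        ang = np.random.default_rng(8).uniform(-1, 1, (150, 3))
        s = 5
        env_d = np.vstack([np.zeros((s, config.n_inputs)), env])
        ang_d = np.vstack([np.zeros((s, config.n_outputs)), ang])
        base = predict_series_parallel(params, env, ang)
        delayed = predict_series_parallel(params, env_d, ang_d)
        burn = config.burn_in
        np.testing.assert_allclose(delayed[burn + s:], base[burn:], atol=1e-12)

    def test_too_short_input_rejected(self):
        config = NarxConfig()
        params = init_parameters(config, seed=0)
        n = config.burn_in
        with pytest.raises(InputError):
            predict_series_parallel(params, np.zeros((n, 6)), np.zeros((n, 3)))
        with pytest.raises(InputError):
            simulate_parallel(params, np.zeros((n, 6)),
                              np.zeros((config.burn_in - 1, 3)))


class TestTraining:
    def test_teacher_function_recovery(self, teacher):
        """On noiseless data generated by a realizable teacher, training
        recovers the function: held-out one-step VAF >= 99.9% per joint."""
        _, env, ang = teacher
        config = NarxConfig()
        split = 3000
        opts = TrainOptions(restarts=3, max_iters=200, seed=0,
                            closed_loop_iters=0, polish_iters=0)
        params, report = train(config, env[:split], ang[:split], opts)
        pred = predict_series_parallel(params, env[split:], ang[split:])
        burn = config.burn_in
        for j in range(3):
            v = vaf(ang[split + burn:, j], pred[burn:, j])
            assert v >= 99.9, f"joint {j}: VAF {v:.3f}"

    def test_trajectories_non_increasing(self, teacher):
        _, env, ang = teacher
        opts = TrainOptions(restarts=1, max_iters=40, seed=1,
                            closed_loop_iters=20, screen_iters=20,
                            polish_iters=10)
        _, report = train(NarxConfig(), env[:1000], ang[:1000], opts)
        for traj in (report.mse_trajectory, report.closed_loop_mse_trajectory):
            assert all(b <= a for a, b in zip(traj, traj[1:]))

    def test_deterministic_given_seed(self, teacher):
        _, env, ang = teacher
        opts = TrainOptions(restarts=2, max_iters=30, seed=9,
                            closed_loop_iters=10, screen_iters=10,
                            polish_iters=5)
        p1, r1 = train(NarxConfig(), env[:800], ang[:800], opts)
        p2, r2 = train(NarxConfig(), env[:800], ang[:800], opts)
        np.testing.assert_array_equal(_pack(p1), _pack(p2))
        assert r1.final_mse == r2.final_mse

    def test_insufficient_data_rejected(self):
        config = NarxConfig()
        with pytest.raises(TrainingError):
            train(config, np.zeros((100, 6)), np.zeros((100, 3)),
                  TrainOptions(restarts=1, max_iters=1))

    def test_normalizers_fitted_from_training_data(self, teacher):
        _, env, ang = teacher
        opts = TrainOptions(restarts=1, max_iters=5, closed_loop_iters=0,
                            polish_iters=0, seed=0)
        params, _ = train(NarxConfig(), env[:800], ang[:800], opts)
        np.testing.assert_allclose(params.input_scale, env[:800].max(axis=0))
        lo, hi = ang[:800].min(axis=0), ang[:800].max(axis=0)
        np.testing.assert_allclose(params.output_offset, (lo + hi) / 2)
        np.testing.assert_allclose(params.output_scale, (hi - lo) / 2)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, teacher):
        params, env, ang = teacher
        path = save_model(params, tmp_path / "model.json")
        back = load_model(path)
        np.testing.assert_array_equal(_pack(back), _pack(params))
        np.testing.assert_array_equal(back.input_scale, params.input_scale)
        burn = params.config.burn_in
        a = simulate_parallel(params, env[:500], ang[:burn])
        b = simulate_parallel(back, env[:500], ang[:burn])
        np.testing.assert_array_equal(a, b)
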