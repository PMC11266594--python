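import numpy as np
import pytest

import biofiltervoc as bv
from biofiltervoc.enn_surrogate import _ACTIVATIONS, _forward_states, _GramLM


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def tiny_weights(n=1, w_hi=1.0, w_hc=0.0, b_h=0.0, w_oh=1.0, b_o=0.0):
    return bv.ENNWeights(
        w_hi=np.full((n, 1), w_hi),
        w_hc=np.full((n, n), w_hc),
        w_oh=np.full((1, n), w_oh),
        b_h=np.full(n, b_h),
        b_o=np.array([b_o]),
    )


def random_weights(rng, n=3):
    return bv.ENNWeights(
        w_hi=rng.normal(size=(n, 1)),
        w_hc=rng.normal(size=(n, n)) * 0.3,
        w_oh=rng.normal(size=(1, n)),
        b_h=rng.normal(size=n),
        b_o=rng.normal(size=1),
    )


class TestForward:
    def test_zero_weights_give_half(self):
        w = tiny_weights(n=4, w_hi=0.0, w_oh=0.0)
        y, _ = bv.enn_forward(w, [0.3, 0.7])
        assert np.allclose(y, 0.5)

    def test_hand_evaluated_single_neuron(self):
        # h = sigma(0) = 0.5, y = sigma(0.5) ~ 0.622459
        w = tiny_weights()
        y, ctx = bv.enn_forward(w, [0.0])
        assert y[0] == pytest.approx(0.6224593, abs=1e-6)
        assert ctx[0] == pytest.approx(0.5)

    def test_context_feeds_next_step(self):
        w = tiny_weights(w_hc=1.0)
        y, ctx = bv.enn_forward(w, [0.0, 0.0])
        h1 = sigmoid(0.0)
        h2 = sigmoid(h1)  # pre-activation at t=2 equals h(1)
        assert ctx[0] == pytest.approx(h2)
        assert y[1] == pytest.approx(sigmoid(h2))

    def test_outputs_in_logistic_range(self):
        rng = np.random.default_rng(7)
        w = random_weights(rng, n=5)
        y, _ = bv.enn_forward(w, np.linspace(0, 1, 50))
        assert np.all((y > 0) & (y < 1))

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            bv.enn_forward(tiny_weights(), [0.0, np.nan])
        with pytest.raises(ValueError):
            bv.ENNWeights(
                w_hi=[[np.inf]], w_hc=[[0.0]], w_oh=[[1.0]], b_h=[0.0], b_o=[0.0]
            )


class TestPredict:
    def test_empty_input(self):
        assert bv.predict(tiny_weights(), []).size == 0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            bv.predict(tiny_weights(), [0.5, 0.2])
        with pytest.raises(ValueError):
            bv.predict(tiny_weights(), [0.5, 1.2])

    def test_matches_forward_contract(self):
        w = random_weights(np.random.default_rng(3))
        x = np.linspace(0, 1, 17)
        y, _ = bv.enn_forward(w, x)
        assert np.array_equal(bv.predict(w, x), y)


class TestLMUpdate:
    def test_scalar_linear_model(self):
        # (J^T J + mu) dw = J^T e with J = 1, e = 1, mu = 1 -> dw = 0.5
        delta = bv.lm_update(np.array([[1.0]]), np.array([1.0]), mu=1.0)
        assert delta[0] == pytest.approx(0.5)

    def test_large_damping_freezes_step(self):
        J = np.random.default_rng(0).normal(size=(5, 3))
        e = np.ones(5)
        assert np.linalg.norm(bv.lm_update(J, e, mu=1e12)) < 1e-10

    def test_small_damping_recovers_least_squares(self):
        rng = np.random.default_rng(1)
        J = rng.normal(size=(10, 3))
        e = rng.normal(size=10)
        delta = bv.lm_update(J, e, mu=1e-12)
        ref, *_ = np.linalg.lstsq(J, e, rcond=None)
        assert np.allclose(delta, ref, atol=1e-8)

    def test_dual_and_primal_paths_agree(self):
        rng = np.random.default_rng(2)
        J = rng.normal(size=(4, 7))  # wide: dual path
        e = rng.normal(size=4)
        delta = bv.lm_update(J, e, mu=0.3)
        ref = np.linalg.solve(J.T @ J + 0.3 * np.eye(7), J.T @ e)
        assert np.allclose(delta, ref, atol=1e-10)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            bv.lm_update(np.ones((2, 2)), np.ones(2), mu=0.0)


class TestJacobian:
    def test_matches_finite_differences_with_frozen_context(self):
        """Teacher-forced analytic Jacobian vs central differences, N=3."""
        rng = np.random.default_rng(42)
        w = random_weights(rng, n=3)
        xs = np.linspace(0, 1, 7)
        J, y = bv.enn_jacobian(w, xs)
        _, H, C, X = _forward_states(w, xs, None)
        theta0 = w.to_vector()

        def frozen_outputs(theta):
            ww = w.with_vector(theta)
            a_h = X @ ww.w_hi.T + C @ ww.w_hc.T + ww.b_h
            h = sigmoid(a_h)
            return sigmoid(h @ ww.w_oh[0] + ww.b_o[0])

        step = 1e-6
        for k in range(theta0.size):
            up, dn = theta0.copy(), theta0.copy()
            up[k] += step
            dn[k] -= step
            fd = (frozen_outputs(up) - frozen_outputs(dn)) / (2 * step)
            scale = max(np.max(np.abs(fd)), 1e-8)
            assert np.max(np.abs(J[:, k] - fd)) / scale < 1e-5

    def test_gram_factorization_equals_explicit_jacobian(self):
        rng = np.random.default_rng(5)
        w = random_weights(rng, n=4)
        xs = np.linspace(0, 1, 11)
        J, y = bv.enn_jacobian(w, xs)
        _, H, C, X = _forward_states(w, xs, None)
        dg = _ACTIVATIONS["logistic"][1]
        d = dg(y)
        g = d[:, None] * w.w_oh[0][None, :] * dg(H)
        idx = np.arange(len(xs))
        engine = _GramLM(X, H, C, d, g, idx)
        assert np.allclose(engine.gram(), J @ J.T, atol=1e-12)
        z = rng.normal(size=len(xs))
        assert np.allclose(engine.jt_vec(z), J.T @ z, atol=1e-12)


class TestDataset:
    def test_canonical_split_sizes(self, mm_profile):
        ds = bv.build_dataset(mm_profile, n=1001, seed=0)
        assert ds.train_idx.size == 701
        assert ds.val_idx.size == 150
        assert ds.test_idx.size == 150

    def test_split_partitions_all_points(self, mm_profile):
        ds = bv.build_dataset(mm_profile, n=101, seed=3)
        merged = np.concatenate([ds.train_idx, ds.val_idx, ds.test_idx])
        assert np.array_equal(np.sort(merged), np.arange(101))

    def test_same_seed_same_split(self, mm_profile):
        a = bv.build_dataset(mm_profile, n=101, seed=9)
        b = bv.build_dataset(mm_profile, n=101, seed=9)
        assert np.array_equal(a.split_index, b.split_index)
        assert not np.array_equal(
            a.split_index, bv.build_dataset(mm_profile, n=101, seed=10).split_index
        )

    def test_targets_resampled_from_profile(self, mm_profile):
        ds = bv.build_dataset(mm_profile, n=501, seed=0)
        expected = np.interp(ds.x_points, mm_profile.grid, mm_profile.s_values)
        assert np.max(np.abs(ds.targets - expected)) < 1e-6  # spline vs linear

    def test_too_small_rejected(self, mm_profile):
        with pytest.raises(ValueError):
            bv.build_dataset(mm_profile, n=5)


def small_dataset(mm_profile, n=101, seed=0):
    return bv.build_dataset(mm_profile, n=n, seed=seed)


class TestTraining:
    def test_constant_target_learned_through_output_bias(self):
        x = np.linspace(0, 1, 40)
        ds = bv.TrainingDataset(
            x_points=x, targets=np.full(40, 0.5), split_index=np.zeros(40, dtype=int)
        )
        cfg = bv.ENNConfig(n_hidden=5, max_iterations=50, val_patience=0, seed=0)
        _, record = bv.train(cfg, ds)
        assert record.mse_history[-1] < 1e-10

    def test_seeded_run_is_reproducible(self, mm_profile):
        ds = small_dataset(mm_profile)
        cfg = bv.ENNConfig(n_hidden=10, max_iterations=15, seed=4)
        w1, r1 = bv.train(cfg, ds)
        w2, r2 = bv.train(cfg, ds)
        assert r1.mse_history == r2.mse_history
        assert np.array_equal(w1.to_vector(), w2.to_vector())

    def test_accepted_steps_monotone(self, mm_profile):
        ds = small_dataset(mm_profile)
        cfg = bv.ENNConfig(n_hidden=10, max_iterations=30, seed=1)
        _, record = bv.train(cfg, ds)
        h = record.mse_history
        assert all(b <= a for a, b in zip(h, h[1:]))
        assert record.stop_reason in {"max_iter", "grad_tol", "mu_max", "val_patience"}
        assert record.epochs_run <= 30

    def test_fits_reference_profile_at_small_scale(self, mm_profile):
        ds = small_dataset(mm_profile, n=201, seed=2)
        cfg = bv.ENNConfig(n_hidden=20, max_iterations=200, seed=2)
        w, record = bv.train(cfg, ds)
        y = bv.predict(w, ds.x_points)
        te = ds.test_idx
        assert bv.mad(y[te], ds.targets[te]) < 1e-3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            bv.ENNConfig(split=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            bv.ENNConfig(n_hidden=0)
        with pytest.raises(ValueError):
            bv.ENNConfig(hidden_activation="sinc")
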