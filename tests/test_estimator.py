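import numpy as np
import pytest

from aquavital._autograd import Tensor
from aquavital.errors import ConfigurationError, InsufficientDataError
from aquavital import estimator as E


def _random_gru_params(rng, d, h):
    return {
        "Wxz": rng.normal(0, 0.4, (d, h)), "Whz": rng.normal(0, 0.4, (h, h)),
        "bz": rng.normal(0, 0.2, h),
        "Wxr": rng.normal(0, 0.4, (d, h)), "Whr": rng.normal(0, 0.4, (h, h)),
        "br": rng.normal(0, 0.2, h),
        "Wxh": rng.normal(0, 0.4, (d, h)), "U": rng.normal(0, 0.4, (h, h)),
        "bh": rng.normal(0, 0.2, h),
    }


class TestBuildWindows:
    def test_sample_count_arithmetic(self):
        feats = np.random.default_rng(0).random((20, 3))
        target = np.linspace(0, 1, 20)
        wd = E.build_windows(feats, target, E.WindowSpec(window_length=15, horizon_steps=1))
        assert wd.X.shape == (5, 15, 3)
        assert wd.y.shape == (5,)

    def test_no_window_fits_raises(self):
        feats = np.zeros((16, 2))
        target = np.linspace(1, 2, 16)
        with pytest.raises(InsufficientDataError):
            E.build_windows(feats, target, E.WindowSpec(window_length=15, horizon_steps=2))

    def test_scaler_round_trip(self):
        rng = np.random.default_rng(1)
        data = rng.normal(3.0, 10.0, (50, 4))
        scaler = E.MinMaxScaler(data)
        assert np.allclose(scaler.inverse(scaler.transform(data)), data, atol=1e-12)

    def test_targets_align_with_horizon(self):
        target = np.arange(30.0)
        wd = E.build_windows(np.zeros((30, 1)) + np.arange(30)[:, None], target,
                             E.WindowSpec(window_length=5, horizon_steps=3))
        # first window covers 0..4, target is index 7
        assert wd.target_index[0] == 7
        unscaled = wd.target_scaler.inverse(wd.y[:, None])[:, 0]
        assert np.allclose(unscaled, target[wd.target_index])


class TestAttentionWeights:
    def test_equal_scores_uniform(self):
        assert np.allclose(E.attention_weights([3.0, 3.0, 3.0]), 1.0 / 3.0)

    def test_log_two_example(self):
        w = E.attention_weights([0.0, np.log(2.0)])
        assert np.allclose(w, [1.0 / 3.0, 2.0 / 3.0])

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 3, 9)
        assert np.allclose(E.attention_weights(s), E.attention_weights(s + 11.7))
        assert E.attention_weights(s).sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 2, 7)
        perm = rng.permutation(7)
        assert np.allclose(E.attention_weights(s)[perm], E.attention_weights(s[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            E.attention_weights([])


class TestGruStep:
    def test_zero_parameters_halve_state(self):
        d, h = 3, 4
        params = {k: np.zeros((d, h)) if k.startswith("Wx") else
                  np.zeros((h, h)) if k in ("Whz", "Whr", "U") else np.zeros(h)
                  for k in E.GRU_PARAM_KEYS}
        h_prev = np.array([0.4, -0.2, 1.0, 0.0])
        out = E.gru_step(np.ones(d), h_prev, params)
        assert np.allclose(out, h_prev / 2.0)

    def test_saturated_update_gate_freezes_or_replaces(self):
        rng = np.random.default_rng(0)
        d, h = 2, 3
        params = _random_gru_params(rng, d, h)
        h_prev = rng.normal(0, 0.5, h)
        x = rng.normal(0, 1, d)
        frozen = dict(params, bz=np.full(h, -50.0))  # z -> 0
        assert np.allclose(E.gru_step(x, h_prev, frozen), h_prev)
        open_gate = dict(params, bz=np.full(h, 50.0))  # z -> 1
        r = 1.0 / (1.0 + np.exp(-(x @ params["Wxr"] + h_prev @ params["Whr"] + params["br"])))
        candidate = np.tanh(x @ params["Wxh"] + (r * h_prev) @ params["U"] + params["bh"])
        assert np.allclose(E.gru_step(x, h_prev, open_gate), candidate)

    def test_convex_combination_bound(self):
        rng = np.random.default_rng(5)
        params = _random_gru_params(rng, 3, 6)
        h_prev = rng.normal(0, 0.8, 6)
        out = E.gru_step(rng.normal(0, 1, 3), h_prev, params)
        lo = np.minimum(h_prev, -1.0)
        hi = np.maximum(h_prev, 1.0)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        params = _random_gru_params(rng, 3, 4)
        with pytest.raises(ConfigurationError):
            E.gru_step(np.zeros(2), np.zeros(4), params)


class TestBigruEncode:
    def test_single_step_uses_same_input_both_ways(self):
        rng = np.random.default_rng(7)
        pf, pb = _random_gru_params(rng, 2, 3), _random_gru_params(rng, 2, 3)
        seq = rng.normal(0, 1, (1, 2))
        out = E.bigru_encode(seq, pf, pb)
        assert out.shape == (1, 6)
        assert np.allclose(out[0, :3], E.gru_step(seq[0], np.zeros(3), pf))
        assert np.allclose(out[0, 3:], E.gru_step(seq[0], np.zeros(3), pb))

    def test_palindrome_with_shared_parameters(self):
        rng = np.random.default_rng(8)
        p = _random_gru_params(rng, 2, 4)
        half = rng.normal(0, 1, (3, 2))
        seq = np.vstack([half, half[::-1]])
        out = E.bigru_encode(seq, p, p)
        fwd, bwd = out[:, :4], out[:, 4:]
        assert np.allclose(fwd, bwd[::-1])

    def test_matches_stepwise_oracle(self):
        """Hand-rolled two-pass evaluation reproduces the encoder."""
        rng = np.random.default_rng(9)
        pf, pb = _random_gru_params(rng, 3, 5), _random_gru_params(rng, 3, 5)
        seq = rng.normal(0, 1, (3, 3))

        def manual(x, h, p):
            z = 1 / (1 + np.exp(-(x @ p["Wxz"] + h @ p["Whz"] + p["bz"])))
            r = 1 / (1 + np.exp(-(x @ p["Wxr"] + h @ p["Whr"] + p["br"])))
            cand = np.tanh(x @ p["Wxh"] + (r * h) @ p["U"] + p["bh"])
            return (1 - z) * h + z * cand

        h = np.zeros(5)
        fwd = []
        for t in range(3):
            h = manual(seq[t], h, pf)
            fwd.append(h)
        h = np.zeros(5)
        bwd = [None] * 3
        for t in (2, 1, 0):
            h = manual(seq[t], h, pb)
            bwd[t] = h
        expected = np.concatenate([np.stack(fwd), np.stack(bwd)], axis=1)
        assert np.allclose(E.bigru_encode(seq, pf, pb), expected, atol=1e-12)

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(0)
        p = _random_gru_params(rng, 2, 3)
        with pytest.raises(ConfigurationError):
            E.bigru_encode(np.empty((0, 2)), p, p)


class TestAutogradConsistency:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        for net_cls, kwargs in ((E.StageOneNet, {"cell": "lstm", "use_cnn": True}),
                                (E.ResidualNet, {})):
            net = net_cls(2, E.small_config(), np.random.default_rng(1), **kwargs)
            X = rng.random((3, 6, 2))
            y = rng.random(3)
            loss = ((net(Tensor(X)) - Tensor(y[:, None])) ** 2.0).mean()
            loss.backward()
            for p in net.params()[:4]:
                flat = p.data.reshape(-1)
                i = int(rng.integers(flat.size))
                orig = flat[i]
                eps = 1e-6
                flat[i] = orig + eps
                up = float(((net(Tensor(X)) - Tensor(y[:, None])) ** 2.0).mean().data)
                flat[i] = orig - eps
                dn = float(((net(Tensor(X)) - Tensor(y[:, None])) ** 2.0).mean().data)
                flat[i] = orig
                numeric = (up - dn) / (2 * eps)
                assert p.grad.reshape(-1)[i] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_trainable_gru_cell_matches_numpy_forward(self):
        """The autograd GRU layer and the plain-numpy step agree exactly."""
        rng = np.random.default_rng(3)
        cell = E._GRUCell(rng, 3, 4)
        x = rng.normal(0, 1, (2, 3))
        h = rng.normal(0, 0.5, (2, 4))
        auto = cell.step(Tensor(x), Tensor(h)).data
        manual = E.gru_step(x, h, cell.numpy_params())
        assert np.allclose(auto, manual, atol=1e-12)


class TestTraining:
    @staticmethod
    def _windowed(T=90, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, T)
        feats = np.column_stack([t, np.cos(2 * np.pi * t)])
        target = 0.8 * t + 0.1 + noise * rng.standard_normal(T)
        return E.build_windows(feats, target, E.WindowSpec(window_length=8))

    def test_constant_target_learned(self):
        feats = np.random.default_rng(0).random((60, 2))
        target = np.full(60, 5.0)
        wd = E.build_windows(feats, target, E.WindowSpec(window_length=8))
        model = E.train_hybrid(wd, E.small_config(seed=0, epochs=30))
        # constant target: span collapses, predictions constant to 1e-3
        preds = model.predict(wd.X)
        assert np.allclose(preds, 5.0, atol=1e-3)

    def test_noiseless_linear_target_fits_tightly(self):
        wd = self._windowed(noise=0.0)
        model = E.train_hybrid(wd, E.small_config(seed=0, epochs=200))
        assert E.validation_rmse(model) <= 0.05

    def test_seeded_determinism(self):
        wd = self._windowed(noise=0.02)
        cfg = E.small_config(seed=12, epochs=15)
        a = E.train_hybrid(wd, cfg).predict(wd.X)
        b = E.train_hybrid(wd, cfg).predict(wd.X)
        assert np.array_equal(a, b)

    def test_training_loss_decreases(self):
        wd = self._windowed(noise=0.02)
        model = E.train_hybrid(wd, E.small_config(seed=1, epochs=25))
        hist = model.history[0]
        assert min(hist[-5:]) < hist[0]

    def test_unknown_baseline_kind_rejected(self):
        wd = self._windowed()
        with pytest.raises(ConfigurationError):
            E.train_baseline(wd, E.small_config(), "transformer")


class TestForecast:
    def test_horizon_unit_conversion(self):
        assert E.horizon_steps(5.0, 5.0) == 1
        assert E.horizon_steps(20.0, 5.0) == 4
        with pytest.raises(ConfigurationError):
            E.horizon_steps(2.0, 5.0)

    def test_degenerate_band_when_no_residual_variance(self):
        wd = TestTraining._windowed(noise=0.0)
        model = E.train_hybrid(wd, E.small_config(seed=0, epochs=20))
        model.val_residual_sd = 0.0
        fc = E.forecast(model, "lactate", 5.0)
        assert np.array_equal(fc.lower, fc.point)
        assert np.array_equal(fc.upper, fc.point)

    def test_band_orders_and_alignment(self):
        wd = TestTraining._windowed(noise=0.05, seed=4)
        model = E.train_hybrid(wd, E.small_config(seed=4, epochs=20))
        fc = E.forecast(model, "glucose", 5.0)
        assert np.all(fc.lower <= fc.point) and np.all(fc.point <= fc.upper)
        assert fc.target_index.size == wd.X.shape[0] - model.n_train
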