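import numpy as np
import pytest

from ecgforecast import (
    EmbeddingConfig,
    NestedLSTM,
    PlainLSTM,
    TrainingConfig,
    compute_loss,
    embed,
    forward_sequence,
    gradients,
    predict_series,
    split_train_eval,
    train,
)
from ecgforecast.model import (
    ForecastResult,
    TrainingDiverged,
    load_checkpoint,
    save_checkpoint,
)

# ---------------------------------------------------------------------------
# Naive transliteration oracles: straight-line, per-equation, loop-based.
# ---------------------------------------------------------------------------


def _sig(z):
    return 1.0 / (1.0 + np.exp(-z))


def naive_plain_forward(p, window):
    H = p["b_f"].size
    h = np.zeros(H)
    c = np.zeros(H)
    for x in window:
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        f = _sig(p["W_fx"] @ xv + p["W_fh"] @ h + p["b_f"])
        i = _sig(p["W_ix"] @ xv + p["W_ih"] @ h + p["b_i"])
        g = np.tanh(p["W_cx"] @ xv + p["W_ch"] @ h + p["b_c"])
        o = _sig(p["W_ox"] @ xv + p["W_oh"] @ h + p["b_o"])
        c = f * c + i * g
        h = o * np.tanh(c)
    return float((p["W_yh"] @ h)[0]), h, c


def naive_nested_forward(p, window, c0=None, cbar0=None):
    H = p["b_f"].size
    h = np.zeros(H)
    c = np.zeros(H) if c0 is None else np.asarray(c0, dtype=float)
    cbar = np.zeros(H) if cbar0 is None else np.asarray(cbar0, dtype=float)
    for x in window:
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        f = _sig(p["W_fx"] @ xv + p["W_fh"] @ h + p["b_f"])
        i = _sig(p["W_ix"] @ xv + p["W_ih"] @ h + p["b_i"])
        g = np.tanh(p["W_cx"] @ xv + p["W_ch"] @ h + p["b_c"])
        hbar_prev = f * c
        xbar = i * g
        fb = _sig(p["Wi_fx"] @ xbar + p["Wi_fh"] @ hbar_prev + p["bi_f"])
        ib = _sig(p["Wi_ix"] @ xbar + p["Wi_ih"] @ hbar_prev + p["bi_i"])
        gb = np.tanh(p["Wi_cx"] @ xbar + p["Wi_ch"] @ hbar_prev + p["bi_c"])
        ob = _sig(p["Wi_ox"] @ xbar + p["Wi_oh"] @ hbar_prev + p["bi_o"])
        cbar = fb * cbar + ib * gb
        hbar = ob * np.tanh(cbar)
        c = hbar
        o = _sig(p["W_ox"] @ xv + p["W_oh"] @ h + p["b_o"])
        h = o * np.tanh(c)
    return float((p["W_yh"] @ h)[0]), h, c, cbar


def grad_check(model, params, X, targets, tol=1e-4, step=1e-5):
    """Per-tensor norm comparison of analytic vs central-difference grads."""
    _, analytic = gradients(model, params, X, targets)
    for name, arr in params.items():
        fd = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + step
            lp, _ = compute_loss(model.predict(params, X), targets)
            arr[ix] = orig - step
            lm, _ = compute_loss(model.predict(params, X), targets)
            arr[ix] = orig
            fd[ix] = (lp - lm) / (2 * step)
        denom = max(np.linalg.norm(analytic[name]), np.linalg.norm(fd), 1e-8)
        rel = np.linalg.norm(analytic[name] - fd) / denom
        assert rel < tol, f"{name}: rel err {rel:.2e}"


class TestZeroParameterCases:
    @pytest.mark.parametrize("cls", [NestedLSTM, PlainLSTM])
    def test_zero_params_zero_output(self, cls):
        model = cls(hidden_size=4)
        params = {k: np.zeros(s) for k, s in model.param_shapes().items()}
        y = model.predict(params, np.random.default_rng(0).normal(size=(3, 6)))
        np.testing.assert_array_equal(y, np.zeros(3))

    def test_zero_params_sigmoid_gives_half(self):
        model = NestedLSTM(hidden_size=2, output_activation="sigmoid")
        params = {k: np.zeros(s) for k, s in model.param_shapes().items()}
        y = forward_sequence(model, params, np.array([1.0, -2.0, 3.0]))
        assert y == pytest.approx(0.5)

    def test_plain_step_zero(self):
        model = PlainLSTM(hidden_size=3)
        params = {k: np.zeros(s) for k, s in model.param_shapes().items()}
        h, c = model.step(params, (np.zeros(3), np.zeros(3)), np.array([5.0]))
        np.testing.assert_array_equal(h, np.zeros(3))


class TestScalarHandTrace:
    def test_inner_cell_seeded_memory(self):
        # hidden 1, every weight zero, large-negative inner input-gate bias,
        # inner memory seeded at 1: outer gates are 0.5, candidates 0, so the
        # inner cell sees zero input/hidden state; its forget gate halves the
        # seeded memory: cbar_1 = 0.5, hbar_1 = 0.5 * tanh(0.5) = c_1.
        model = NestedLSTM(hidden_size=1)
        params = {k: np.zeros(s) for k, s in model.param_shapes().items()}
        params["bi_i"] = np.array([-50.0])
        h1, c1, cbar1 = model.step(
            params,
            (np.zeros(1), np.zeros(1), np.ones(1)),
            np.array([0.3]),
        )
        assert cbar1[0] == pytest.approx(0.5, abs=1e-12)
        assert c1[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-12)
        assert h1[0] == pytest.approx(0.5 * np.tanh(c1[0]), abs=1e-12)
        # independent straight-line trace agrees
        _, h_ref, c_ref, cbar_ref = naive_nested_forward(
            params, [0.3], c0=[0.0], cbar0=[1.0]
        )
        np.testing.assert_allclose(h1, h_ref, atol=1e-14)
        np.testing.assert_allclose(cbar1, cbar_ref, atol=1e-14)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_nested_matches_transliteration(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(1, 5))
        T = int(rng.integers(1, 8))
        model = NestedLSTM(hidden_size=H)
        params = model.init_params(rng, 0.6)
        window = rng.normal(size=T)
        y = forward_sequence(model, params, window)
        y_ref, _, _, _ = naive_nested_forward(params, window)
        assert abs(y - y_ref) <= 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_plain_matches_transliteration(self, seed):
        rng = np.random.default_rng(100 + seed)
        H = int(rng.integers(1, 5))
        T = int(rng.integers(1, 8))
        model = PlainLSTM(hidden_size=H)
        params = model.init_params(rng, 0.6)
        window = rng.normal(size=T)
        y = forward_sequence(model, params, window)
        y_ref, _, _ = naive_plain_forward(params, window)
        assert abs(y - y_ref) <= 1e-12

    def test_structural_reduction_50_steps(self):
        rng = np.random.default_rng(7)
        H = 3
        nested = NestedLSTM(hidden_size=H, bypass_inner=True)
        plain = PlainLSTM(hidden_size=H)
        params = nested.init_params(rng, 0.5)
        plain_params = {
            k: v for k, v in params.items() if not k.startswith(("Wi_", "bi_"))
        }
        window = rng.normal(size=50)
        yn, cache_n = nested.forward_batch(params, window[None, :])
        yp, cache_p = plain.forward_batch(plain_params, window[None, :])
        assert yn[0] == yp[0]  # exact, same float operations
        np.testing.assert_array_equal(cache_n["h_last"], cache_p["h_last"])


class TestLoss:
    def test_zero_when_equal(self):
        E, per = compute_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert E == 0.0
        np.testing.assert_array_equal(per, [0.0, 0.0])

    def test_half_factor(self):
        E, _ = compute_loss(np.array([1.0]), np.array([0.0]))
        assert E == 0.5

    def test_sum_over_steps(self):
        E, per = compute_loss(np.array([1.0, 3.0]), np.array([0.0, 1.0]))
        assert E == 2.5
        np.testing.assert_array_equal(per, [0.5, 2.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_loss(np.zeros(2), np.zeros(3))


class TestGradients:
    @pytest.mark.parametrize("cls", [NestedLSTM, PlainLSTM])
    def test_finite_difference_small_instance(self, cls):
        rng = np.random.default_rng(0)
        model = cls(hidden_size=3)
        params = model.init_params(rng, 0.4)
        X = rng.normal(size=(4, 5))
        targets = rng.normal(size=4)
        grad_check(model, params, X, targets)

    def test_sigmoid_readout_gradient(self):
        rng = np.random.default_rng(5)
        model = NestedLSTM(hidden_size=2, output_activation="sigmoid")
        params = model.init_params(rng, 0.5)
        X = rng.normal(size=(3, 4))
        targets = rng.uniform(0.2, 0.8, size=3)
        grad_check(model, params, X, targets)

    def test_zero_residual_zero_gradient(self):
        model = PlainLSTM(hidden_size=2)
        params = {k: np.zeros(s) for k, s in model.param_shapes().items()}
        X = np.random.default_rng(1).normal(size=(3, 4))
        _, grads = gradients(model, params, X, np.zeros(3))  # predictions are 0
        for g in grads.values():
            np.testing.assert_array_equal(g, np.zeros_like(g))

    def test_batch_duplication_doubles_gradient(self):
        rng = np.random.default_rng(2)
        model = NestedLSTM(hidden_size=2)
        params = model.init_params(rng, 0.4)
        X = rng.normal(size=(3, 5))
        t = rng.normal(size=3)
        loss1, g1 = gradients(model, params, X, t)
        loss2, g2 = gradients(
            model, params, np.vstack([X, X]), np.concatenate([t, t])
        )
        assert loss2 == pytest.approx(2 * loss1)
        for name in g1:
            np.testing.assert_allclose(g2[name], 2 * g1[name], rtol=1e-12)


class TestTraining:
    def _sine_sets(self, m=20, n=600):
        x = np.sin(2 * np.pi * np.arange(n) / 50)
        dataset = embed(x / np.std(x, ddof=1), EmbeddingConfig(m=m))
        return split_train_eval(dataset, train_fraction=0.8, strict=True)

    def test_zero_epochs_noop(self):
        train_set, _ = self._sine_sets()
        model = NestedLSTM(hidden_size=4)
        params = model.init_params(np.random.default_rng(0), 0.1)
        before = {k: v.copy() for k, v in params.items()}
        after, history = train(
            model, params, train_set, TrainingConfig(epochs=0, hidden_size=4)
        )
        assert history == []
        for k in before:
            np.testing.assert_array_equal(after[k], before[k])

    def test_determinism(self):
        train_set, _ = self._sine_sets()
        config = TrainingConfig(epochs=3, hidden_size=4, seed=11, learning_rate=3e-3)
        histories = []
        for _ in range(2):
            model = PlainLSTM(hidden_size=4)
            params = model.init_params(np.random.default_rng(11), 0.1)
            _, history = train(model, params, train_set, config)
            histories.append(history)
        assert histories[0] == histories[1]

    @pytest.mark.parametrize("cls", [NestedLSTM, PlainLSTM])
    def test_sine_loss_decreases(self, cls):
        train_set, eval_set = self._sine_sets()
        model = cls(hidden_size=8)
        config = TrainingConfig(
            epochs=20, hidden_size=8, seed=1, learning_rate=5e-3, batch_size=128
        )
        params = model.init_params(np.random.default_rng(1), 0.1)
        params, history = train(model, params, train_set, config)
        assert history[-1] < 0.5 * history[0]
        assert all(np.isfinite(h) for h in history)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_detected(self):
        # A readout weight at float-max overflows the squared loss to inf.
        train_set, _ = self._sine_sets()
        model = PlainLSTM(hidden_size=4)
        params = model.init_params(np.random.default_rng(0), 0.1)
        params["W_yh"][:] = 1e200
        params["b_o"][:] = 50.0  # saturate the output gate so |h| ~ 1
        config = TrainingConfig(epochs=2, hidden_size=4, gradient_clip=None)
        with pytest.raises((TrainingDiverged, FloatingPointError)):
            train(model, params, train_set, config)

    def test_nan_gradient_names_parameter(self):
        train_set, _ = self._sine_sets()
        model = PlainLSTM(hidden_size=2)
        params = model.init_params(np.random.default_rng(0), 0.1)
        params["W_fh"][0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="W_"):
            gradients(model, params, train_set.inputs[:4], train_set.targets[:4])

    def test_error_threshold_stops_early(self):
        train_set, _ = self._sine_sets()
        model = PlainLSTM(hidden_size=4)
        params = model.init_params(np.random.default_rng(0), 0.1)
        config = TrainingConfig(epochs=50, hidden_size=4, error_threshold=1e9)
        _, history = train(model, params, train_set, config)
        assert len(history) == 1  # first epoch already under the huge threshold

    def test_empty_dataset(self):
        train_set, _ = self._sine_sets()
        empty = train_set.subset(slice(0, 0))
        model = PlainLSTM(hidden_size=2)
        params = model.init_params(np.random.default_rng(0), 0.1)
        with pytest.raises(ValueError, match="empty"):
            train(model, params, empty, TrainingConfig(hidden_size=2))


class TestForecastResult:
    def test_perfect_constant_predictor(self):
        res = ForecastResult(np.full(5, 2.0), np.full(5, 2.0))
        assert res.rmse == 0.0
        assert res.mae == 0.0

    def test_hand_arithmetic(self):
        res = ForecastResult(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert res.rmse == pytest.approx(1.0)
        assert res.mae == pytest.approx(1.0)

    def test_rmse_ge_mae_on_random_residuals(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            res = ForecastResult(rng.normal(size=n), rng.normal(size=n))
            assert res.rmse >= res.mae
            assert res.rmse >= abs(res.residuals.mean())

    def test_rescaled(self):
        res = ForecastResult(np.array([0.0, 1.0]), np.array([1.0, 3.0]))
        scaled = res.rescaled(2.0, 5.0)
        assert scaled.rmse == pytest.approx(2 * res.rmse)
        assert scaled.mae == pytest.approx(2 * res.mae)


class TestPredictSeries:
    def test_runs_over_every_position(self, rng):
        model = PlainLSTM(hidden_size=3)
        params = model.init_params(rng, 0.2)
        series = rng.normal(size=120)
        result = predict_series(model, params, series, EmbeddingConfig(m=10))
        assert result.predictions.size == 120 - 10
        assert np.all(np.isfinite(result.predictions))

    def test_forward_sequence_determinism(self, rng):
        model = NestedLSTM(hidden_size=3)
        params = model.init_params(rng, 0.2)
        window = rng.normal(size=12)
        assert forward_sequence(model, params, window) == forward_sequence(
            model, params, window
        )

    def test_empty_window_rejected(self):
        model = NestedLSTM(hidden_size=2)
        params = model.init_params(np.random.default_rng(0), 0.1)
        with pytest.raises(ValueError, match="empty"):
            forward_sequence(model, params, np.array([]))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        model = NestedLSTM(hidden_size=3)
        params = model.init_params(rng, 0.3)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, model, params, TrainingConfig(hidden_size=3))
        model2, params2 = load_checkpoint(path)
        assert isinstance(model2, NestedLSTM)
        assert model2.hidden_size == 3
        window = rng.normal(size=8)
        assert forward_sequence(model, params, window) == forward_sequence(
            model2, params2, window
        )

    def test_version_guard(self, tmp_path):
        path = tmp_path / "bad.ckpt"
        path.write_text('{"version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_checkpoint(path)
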