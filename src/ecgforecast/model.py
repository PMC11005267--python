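"""Nested LSTM and plain LSTM cells, exact backpropagation, and training.

The nested cell replaces the additive memory update of a standard LSTM with
a full inner LSTM: the outer forget-gated memory ``f_t * c_{t-1}`` becomes
the inner hidden state, the gated candidate ``i_t * c~_t`` becomes the
inner input, and the outer memory is set to the inner hidden output. With
the inner unit bypassed (``c_t = f_t * c_{t-1} + i_t * c~_t``) the cell
reduces exactly to the plain LSTM, which doubles as the comparison
baseline.

Everything is plain NumPy: parameters are flat ``{name: ndarray}`` dicts,
gradients share the same keys, and the analytic backward pass is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .embedding import EmbeddedDataset, EmbeddingConfig, embed

__all__ = [
    "NestedLSTM",
    "PlainLSTM",
    "TrainingConfig",
    "ForecastResult",
    "TrainingDiverged",
    "compute_loss",
    "gradients",
    "train",
    "forward_sequence",
    "predict_series",
    "save_checkpoint",
    "load_checkpoint",
]

GATES = ("f", "i", "c", "o")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainingConfig:
    epochs: int = 60
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    error_threshold: float = 1e-4
    seed: int = 0
    hidden_size: int = 32
    gradient_clip: Optional[float] = 5.0
    batch_size: int = 256
    init_scale: float = 0.1
    log_every: int = 10

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class ForecastResult:
    predictions: np.ndarray
    targets: np.ndarray
    model_tag: str = "model"
    record_id: str = "record"
    residuals: np.ndarray = field(init=False)
    rmse: float = field(init=False)
    mae: float = field(init=False)

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.predictions.shape != self.targets.shape:
            raise ValueError("predictions and targets must have equal length")
        self.residuals = self.targets - self.predictions
        self.rmse = float(np.sqrt(np.mean(self.residuals**2)))
        self.mae = float(np.mean(np.abs(self.residuals)))

    def rescaled(self, scale: float, offset: float = 0.0) -> "ForecastResult":
        """Result in de-normalized units (residuals scale linearly)."""
        return ForecastResult(
            predictions=self.predictions * scale + offset,
            targets=self.targets * scale + offset,
            model_tag=self.model_tag,
            record_id=self.record_id,
        )

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "record_id": self.record_id,
            "rmse": self.rmse,
            "mae": self.mae,
            "predictions": self.predictions.tolist(),
            "targets": self.targets.tolist(),
            "residuals": self.residuals.tolist(),
        }


class _RecurrentForecaster:
    """Shared plumbing: parameter init, readout, batched driver loops."""

    tag = "base"

    def __init__(
        self,
        input_size: int = 1,
        hidden_size: int = 32,
        output_activation: str = "identity",
    ):
        if output_activation not in ("identity", "sigmoid"):
            raise ValueError("output_activation must be 'identity' or 'sigmoid'")
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.output_activation = output_activation

    # -- parameters --------------------------------------------------------
    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        H, I = self.hidden_size, self.input_size
        shapes: dict[str, tuple[int, ...]] = {}
        for g in GATES:
            shapes[f"W_{g}x"] = (H, I)
            shapes[f"W_{g}h"] = (H, H)
            shapes[f"b_{g}"] = (H,)
        shapes["W_yh"] = (1, H)
        return shapes

    def init_params(
        self, rng: np.random.Generator, scale: float = 0.1
    ) -> dict[str, np.ndarray]:
        params = {}
        for name, shape in self.param_shapes().items():
            if name.startswith("b"):
                params[name] = np.zeros(shape)
            else:
                params[name] = scale * rng.standard_normal(shape)
        return params

    def _readout(self, params, h):
        y = h @ params["W_yh"].T  # (B, 1)
        y = y[:, 0]
        if self.output_activation == "sigmoid":
            y = _sigmoid(y)
        return y

    def _readout_backward(self, params, cache, dy):
        y, h_last = cache["y"], cache["h_last"]
        if self.output_activation == "sigmoid":
            dy = dy * y * (1.0 - y)
        dW_yh = dy[:, None].T @ h_last  # (1, H)
        dh = dy[:, None] * params["W_yh"]  # (B, H) via broadcasting (1,H)
        return dW_yh, dh

    # -- public driver -----------------------------------------------------
    def forward_batch(self, params, windows: np.ndarray):
        """Predict one step ahead for each window row; returns (y, cache)."""
        X = np.asarray(windows, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, :, None]  # (B, T, I) with scalar inputs
        if X.shape[1] == 0:
            raise ValueError("empty input window")
        if X.shape[2] != self.input_size:
            raise ValueError(
                f"window feature size {X.shape[2]} != input_size {self.input_size}"
            )
        y, cache = self._forward(params, X)
        return y, cache

    def predict(self, params, windows: np.ndarray) -> np.ndarray:
        y, _ = self.forward_batch(params, windows)
        return y


class PlainLSTM(_RecurrentForecaster):
    """Standard LSTM: ``c_t = f_t c_{t-1} + i_t c~_t``, ``h_t = o_t tanh c_t``."""

    tag = "lstm"

    def step(self, params, state, x_t):
        """Single-sample single-step update; state is (h, c)."""
        h, c = state
        y = self._gates(params, x_t[None, :], h[None, :])
        f, i, g, o = (y[k] for k in ("f", "i", "c", "o"))
        c_new = f * c[None, :] + i * g
        h_new = o * np.tanh(c_new)
        return h_new[0], c_new[0]

    def _gates(self, params, x_t, h_prev):
        out = {}
        for g in GATES:
            a = x_t @ params[f"W_{g}x"].T + h_prev @ params[f"W_{g}h"].T + params[f"b_{g}"]
            out[g] = np.tanh(a) if g == "c" else _sigmoid(a)
        return out

    def _forward(self, params, X):
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            gt = self._gates(params, x_t, h)
            c_new = gt["f"] * c + gt["i"] * gt["c"]
            tanh_c = np.tanh(c_new)
            h_new = gt["o"] * tanh_c
            steps.append(
                {"x": x_t, "h_prev": h, "c_prev": c, "tanh_c": tanh_c, **gt}
            )
            h, c = h_new, c_new
        y = self._readout(params, h)
        return y, {"steps": steps, "h_last": h, "y": y}

    def _backward(self, params, cache, dy):
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dW_yh, dh = self._readout_backward(params, cache, dy)
        grads["W_yh"] += dW_yh
        dc = np.zeros_like(dh)
        for st in reversed(cache["steps"]):
            f, i, g, o = st["f"], st["i"], st["c"], st["o"]
            tanh_c = st["tanh_c"]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            df = dc * st["c_prev"]
            di = dc * g
            dg = dc * i
            dc = dc * f  # flows to c_{t-1}
            da = {
                "f": df * f * (1.0 - f),
                "i": di * i * (1.0 - i),
                "c": dg * (1.0 - g**2),
                "o": do * o * (1.0 - o),
            }
            dh = np.zeros_like(dh)
            for gname in GATES:
                a = da[gname]
                grads[f"W_{gname}x"] += a.T @ st["x"]
                grads[f"W_{gname}h"] += a.T @ st["h_prev"]
                grads[f"b_{gname}"] += a.sum(axis=0)
                dh += a @ params[f"W_{gname}h"]
        return grads


class NestedLSTM(_RecurrentForecaster):
    """LSTM whose memory update is delegated to an inner LSTM.

    Outer gates feed the inner cell with hidden state ``f_t * c_{t-1}`` and
    input ``i_t * c~_t``; the outer memory becomes the inner hidden output.
    ``bypass_inner=True`` replaces the inner cell by plain addition, which
    reproduces :class:`PlainLSTM` exactly (structural sanity check).
    """

    tag = "nested_lstm"

    def __init__(
        self,
        input_size: int = 1,
        hidden_size: int = 32,
        output_activation: str = "identity",
        bypass_inner: bool = False,
    ):
        super().__init__(input_size, hidden_size, output_activation)
        self.bypass_inner = bypass_inner

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        H = self.hidden_size
        shapes = super().param_shapes()
        for g in GATES:
            shapes[f"Wi_{g}x"] = (H, H)  # inner input is hidden-sized
            shapes[f"Wi_{g}h"] = (H, H)
            shapes[f"bi_{g}"] = (H,)
        return shapes

    def step(self, params, state, x_t):
        """Single-sample single-step update; state is (h, c, c_inner)."""
        h, c, c_inner = state
        X = np.asarray(x_t, dtype=np.float64)[None, None, :]
        # Run one step of the batched path with injected initial state.
        y, cache = self._forward(
            params, X, h0=h[None, :], c0=c[None, :], cbar0=c_inner[None, :]
        )
        st = cache["steps"][-1]
        return cache["h_last"][0], st["c_new"][0], st["cbar_new"][0]

    def _outer_gates(self, params, x_t, h_prev):
        out = {}
        for g in GATES:
            a = x_t @ params[f"W_{g}x"].T + h_prev @ params[f"W_{g}h"].T + params[f"b_{g}"]
            out[g] = np.tanh(a) if g == "c" else _sigmoid(a)
        return out

    def _inner_gates(self, params, xbar, hbar_prev):
        out = {}
        for g in GATES:
            a = (
                xbar @ params[f"Wi_{g}x"].T
                + hbar_prev @ params[f"Wi_{g}h"].T
                + params[f"bi_{g}"]
            )
            out[g] = np.tanh(a) if g == "c" else _sigmoid(a)
        return out

    def _forward(self, params, X, h0=None, c0=None, cbar0=None):
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        cbar = np.zeros((B, H)) if cbar0 is None else cbar0
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            og = self._outer_gates(params, x_t, h)
            hbar_in = og["f"] * c  # inner hidden state
            xbar = og["i"] * og["c"]  # inner input
            st = {
                "x": x_t,
                "h_prev": h,
                "c_prev": c,
                "cbar_prev": cbar,
                "hbar_in": hbar_in,
                "xbar": xbar,
                **{f"o_{k}": v for k, v in og.items()},
            }
            if self.bypass_inner:
                c_new = hbar_in + xbar
                cbar_new = cbar
            else:
                ig = self._inner_gates(params, xbar, hbar_in)
                cbar_new = ig["f"] * cbar + ig["i"] * ig["c"]
                tanh_cbar = np.tanh(cbar_new)
                c_new = ig["o"] * tanh_cbar  # inner hidden == outer memory
                st.update({f"i_{k}": v for k, v in ig.items()})
                st["tanh_cbar"] = tanh_cbar
            tanh_c = np.tanh(c_new)
            h_new = og["o"] * tanh_c
            st["c_new"] = c_new
            st["cbar_new"] = cbar_new
            st["tanh_c"] = tanh_c
            steps.append(st)
            h, c, cbar = h_new, c_new, cbar_new
        y = self._readout(params, h)
        return y, {"steps": steps, "h_last": h, "y": y}

    def _backward(self, params, cache, dy):
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dW_yh, dh = self._readout_backward(params, cache, dy)
        grads["W_yh"] += dW_yh
        B, H = dh.shape
        dc = np.zeros((B, H))
        dcbar = np.zeros((B, H))
        for st in reversed(cache["steps"]):
            of, oi, oc, oo = st["o_f"], st["o_i"], st["o_c"], st["o_o"]
            tanh_c = st["tanh_c"]
            doo = dh * tanh_c
            dc = dc + dh * oo * (1.0 - tanh_c**2)
            if self.bypass_inner:
                dhbar_in = dc
                dxbar = dc
                dcbar_prev = dcbar
            else:
                # c_new = i_o * tanh(cbar_new); cbar_new = i_f*cbar_prev + i_i*i_c
                inf, ini, inc, ino = st["i_f"], st["i_i"], st["i_c"], st["i_o"]
                tanh_cbar = st["tanh_cbar"]
                dino = dc * tanh_cbar
                dcbar = dcbar + dc * ino * (1.0 - tanh_cbar**2)
                dinf = dcbar * st["cbar_prev"]
                dini = dcbar * inc
                dinc = dcbar * ini
                dcbar_prev = dcbar * inf
                dia = {
                    "f": dinf * inf * (1.0 - inf),
                    "i": dini * ini * (1.0 - ini),
                    "c": dinc * (1.0 - inc**2),
                    "o": dino * ino * (1.0 - ino),
                }
                dxbar = np.zeros((B, H))
                dhbar_in = np.zeros((B, H))
                for g in GATES:
                    a = dia[g]
                    grads[f"Wi_{g}x"] += a.T @ st["xbar"]
                    grads[f"Wi_{g}h"] += a.T @ st["hbar_in"]
                    grads[f"bi_{g}"] += a.sum(axis=0)
                    dxbar += a @ params[f"Wi_{g}x"]
                    dhbar_in += a @ params[f"Wi_{g}h"]
            # hbar_in = f*c_prev ; xbar = i*c~
            dof = dhbar_in * st["c_prev"]
            dc_prev = dhbar_in * of
            doi = dxbar * oc
            doc = dxbar * oi
            da = {
                "f": dof * of * (1.0 - of),
                "i": doi * oi * (1.0 - oi),
                "c": doc * (1.0 - oc**2),
                "o": doo * oo * (1.0 - oo),
            }
            dh = np.zeros((B, H))
            for g in GATES:
                a = da[g]
                grads[f"W_{g}x"] += a.T @ st["x"]
                grads[f"W_{g}h"] += a.T @ st["h_prev"]
                grads[f"b_{g}"] += a.sum(axis=0)
                dh += a @ params[f"W_{g}h"]
            dc = dc_prev
            dcbar = dcbar_prev
        return grads


def compute_loss(
    predictions: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Squared-error loss: per-step ``E_t = (y_t - target_t)^2 / 2``, total
    ``E = sum_t E_t``."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    per_step = 0.5 * (predictions - targets) ** 2
    return float(per_step.sum()), per_step


def gradients(
    model: _RecurrentForecaster,
    params: dict[str, np.ndarray],
    inputs: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and exact parameter gradients for one batch of windows."""
    y, cache = model.forward_batch(params, inputs)
    loss, _ = compute_loss(y, targets)
    grads = model._backward(params, cache, y - np.asarray(targets, dtype=np.float64))
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in parameter {name!r}")
    return loss, grads


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def train(
    model: _RecurrentForecaster,
    params: dict[str, np.ndarray],
    dataset: EmbeddedDataset,
    config: TrainingConfig,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Mini-batch gradient training with the E < threshold stopping rule.

    Deterministic for a given seed: shuffling, batching and the optimizer
    state all derive from one generator. Returns the trained parameters and
    the per-epoch total loss history.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    params = {k: v.copy() for k, v in params.items()}
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(dataset.n)
        epoch_loss = 0.0
        for lo in range(0, dataset.n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            loss, grads = gradients(
                model, params, dataset.inputs[idx], dataset.targets[idx]
            )
            epoch_loss += loss
            if config.gradient_clip:
                _clip_global_norm(grads, config.gradient_clip)
            step += 1
            for name in params:
                g = grads[name]
                if config.optimizer == "adam":
                    adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * g
                    adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * g**2
                    m_hat = adam_m[name] / (1 - beta1**step)
                    v_hat = adam_v[name] / (1 - beta2**step)
                    params[name] -= (
                        config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    )
                else:
                    params[name] -= config.learning_rate * g
        if not np.isfinite(epoch_loss):
            raise TrainingDiverged(
                f"loss became non-finite at epoch {_epoch + 1}"
            )
        history.append(epoch_loss)
        if epoch_loss < config.error_threshold:
            break
    return params, history


def forward_sequence(
    model: _RecurrentForecaster, params: dict[str, np.ndarray], window: np.ndarray
) -> float:
    """One-step-ahead prediction from a single input window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("empty window")
    return float(model.predict(params, window[None, :])[0])


def predict_series(
    model: _RecurrentForecaster,
    params: dict[str, np.ndarray],
    series: np.ndarray,
    embedding_config: EmbeddingConfig,
    model_tag: Optional[str] = None,
    record_id: str = "record",
    batch_size: int = 1024,
) -> ForecastResult:
    """One-step-ahead predictions over every embeddable position."""
    dataset = embed(series, embedding_config)
    preds = np.empty(dataset.n)
    for lo in range(0, dataset.n, batch_size):
        preds[lo : lo + batch_size] = model.predict(
            params, dataset.inputs[lo : lo + batch_size]
        )
    return ForecastResult(
        predictions=preds,
        targets=dataset.targets,
        model_tag=model_tag or model.tag,
        record_id=record_id,
    )


# -- checkpoints (JSON: text-portable, versioned) ---------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path,
    model: _RecurrentForecaster,
    params: dict[str, np.ndarray],
    config: Optional[TrainingConfig] = None,
) -> None:
    blob = {
        "version": _CHECKPOINT_VERSION,
        "model": model.tag,
        "input_size": model.input_size,
        "hidden_size": model.hidden_size,
        "output_activation": model.output_activation,
        "params": {k: v.tolist() for k, v in params.items()},
        "training_config": vars(config) if config else None,
    }
    Path(path).write_text(json.dumps(blob))


def load_checkpoint(path: str | Path):
    blob = json.loads(Path(path).read_text())
    if blob.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {blob.get('version')}")
    cls = {"nested_lstm": NestedLSTM, "lstm": PlainLSTM}[blob["model"]]
    model = cls(
        input_size=blob["input_size"],
        hidden_size=blob["hidden_size"],
        output_activation=blob["output_activation"],
    )
    params = {k: np.asarray(v, dtype=np.float64) for k, v in blob["params"].items()}
    return model, params
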