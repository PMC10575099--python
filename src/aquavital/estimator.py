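"""Sliding-window stress forecasting with a residual-correcting hybrid model.

The estimator maps a window of screened WBIA features (plus temperature) to a
stress-factor value ``horizon`` steps past the window end.  The hybrid model
runs in two stages: a 1-D CNN extracts window features which an LSTM with
additive (tanh-scored softmax) attention turns into a point estimate; the
training-set residuals of that stage are then regressed by a bidirectional
GRU with its own attention head, and the final prediction is the sum of both
stages, inverse-scaled to the original units.  LSTM/GRU/CNN-LSTM/CNN-GRU
single-stage baselines share the training protocol.  One model is trained per
stress factor and horizon; 95% bands are Gaussian, from the validation
residual standard deviation.

All training is full-precision numpy via the package's reverse-mode autodiff
core; a fixed seed makes initialization, batching and hence the trained
weights reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor, concat, softmax, stack_time
from .errors import ConfigurationError, InsufficientDataError, TrainingError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    window_length: int = 15
    horizon_steps: int = 1
    feature_labels: tuple[str, ...] = ()
    target: str = "lactate"

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ConfigurationError(f"window_length must be >= 1, got {self.window_length}")
        if self.horizon_steps < 1:
            raise ConfigurationError(f"horizon_steps must be >= 1, got {self.horizon_steps}")


@dataclass(frozen=True)
class CnnConfig:
    layers: int = 1
    kernel_size: int = 3
    channels: int = 16


@dataclass(frozen=True)
class RecurrentConfig:
    layers: int = 2
    hidden: int = 32  # reference study states 30-40 neurons
    dense: int = 10


@dataclass(frozen=True)
class BiGruConfig:
    layers: int = 2
    hidden: int = 32
    dense: int = 32
    fully_connected: int = 3


@dataclass(frozen=True)
class HybridModelConfig:
    cnn: CnnConfig = CnnConfig()
    lstm: RecurrentConfig = RecurrentConfig()
    bigru: BiGruConfig = BiGruConfig()
    batch_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 200
    patience: int = 20
    seed: int = 0
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "patience"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(f"train_fraction must be in (0,1), got {self.train_fraction}")


#: compact configuration for CI-scale experiments (same architecture family,
#: smaller widths and budget)
def small_config(seed: int = 0, epochs: int = 60) -> HybridModelConfig:
    return HybridModelConfig(
        cnn=CnnConfig(layers=1, kernel_size=3, channels=6),
        lstm=RecurrentConfig(layers=1, hidden=10, dense=8),
        bigru=BiGruConfig(layers=1, hidden=8, dense=8, fully_connected=2),
        batch_size=32,
        learning_rate=0.02,
        epochs=epochs,
        patience=15,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scaling and windowing
# ---------------------------------------------------------------------------


class MinMaxScaler:
    """Columnwise min-max scaling to [0, 1] with exact inversion."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        self.lo = data.min(axis=0)
        self.hi = data.max(axis=0)
        span = self.hi - self.lo
        self.span = np.where(span == 0.0, 1.0, span)

    def transform(self, data) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.lo) / self.span

    def inverse(self, data) -> np.ndarray:
        return np.asarray(data, dtype=float) * self.span + self.lo


@dataclass
class WindowedData:
    X: np.ndarray  # (N, window_length, n_features), scaled to [0, 1]
    y: np.ndarray  # (N,), scaled
    target_index: np.ndarray  # position of each target in the source series
    feature_scaler: MinMaxScaler
    target_scaler: MinMaxScaler
    spec: WindowSpec


def build_windows(features, target, spec: WindowSpec) -> WindowedData:
    """Supervised (window, future value) pairs from aligned series.

    Sample count is ``T - window_length - horizon_steps + 1``; the target of a
    window ending at index ``e`` is the value at ``e + horizon_steps``.  All
    features and the target are min-max scaled with the scalers retained.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    t = np.asarray(target, dtype=float)
    T = t.size
    if F.shape[0] != T:
        raise ConfigurationError(f"features ({F.shape[0]}) and target ({T}) must be time-aligned")
    n = T - spec.window_length - spec.horizon_steps + 1
    if n < 1:
        raise InsufficientDataError(
            f"series of length {T} yields no windows (window {spec.window_length}, "
            f"horizon {spec.horizon_steps})"
        )
    fs = MinMaxScaler(F)
    ts = MinMaxScaler(t[:, None])
    Fs = fs.transform(F)
    tscaled = ts.transform(t[:, None])[:, 0]
    idx = np.arange(n)
    X = np.stack([Fs[i : i + spec.window_length] for i in idx])
    tgt_idx = idx + spec.window_length + spec.horizon_steps - 1
    return WindowedData(X=X, y=tscaled[tgt_idx], target_index=tgt_idx,
                        feature_scaler=fs, target_scaler=ts, spec=spec)


# ---------------------------------------------------------------------------
# plain-numpy recurrent primitives (forward only)
# ---------------------------------------------------------------------------

GRU_PARAM_KEYS = ("Wxz", "Whz", "bz", "Wxr", "Whr", "br", "Wxh", "U", "bh")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_step(x_t, h_prev, params: dict) -> np.ndarray:
    """One gated-recurrent-unit update.

    ``z`` (update) and ``r`` (reset) are sigmoid gates; the candidate state is
    a tanh of the input plus the reset-gated recurrent term; the new hidden
    state is the convex combination ``(1-z)*h_prev + z*candidate``.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    missing = [k for k in GRU_PARAM_KEYS if k not in params]
    if missing:
        raise ConfigurationError(f"gru_step params missing {missing}")
    d, h = x_t.shape[-1], h_prev.shape[-1]
    if params["Wxz"].shape != (d, h) or params["Whz"].shape != (h, h):
        raise ConfigurationError(
            f"gru_step dimension mismatch: x dim {d}, h dim {h}, "
            f"Wxz {params['Wxz'].shape}, Whz {params['Whz'].shape}"
        )
    z = _sigmoid(x_t @ params["Wxz"] + h_prev @ params["Whz"] + params["bz"])
    r = _sigmoid(x_t @ params["Wxr"] + h_prev @ params["Whr"] + params["br"])
    candidate = np.tanh(x_t @ params["Wxh"] + (r * h_prev) @ params["U"] + params["bh"])
    return (1.0 - z) * h_prev + z * candidate


def bigru_encode(sequence, params_forward: dict, params_backward: dict) -> np.ndarray:
    """Bidirectional GRU encoding of a (T, d) sequence -> (T, 2*hidden).

    The forward pass runs t = 1..T, the backward pass t = T..1; outputs are
    the per-step concatenation [forward_state_t, backward_state_t].
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ConfigurationError("bigru_encode requires a nonempty (T, d) sequence")
    h = params_forward["Whz"].shape[0]
    fwd, bwd = [], []
    state = np.zeros(h)
    for t in range(seq.shape[0]):
        state = gru_step(seq[t], state, params_forward)
        fwd.append(state)
    state = np.zeros(params_backward["Whz"].shape[0])
    for t in range(seq.shape[0] - 1, -1, -1):
        state = gru_step(seq[t], state, params_backward)
        bwd.append(state)
    bwd.reverse()
    return np.concatenate([np.stack(fwd), np.stack(bwd)], axis=1)


def attention_weights(scores) -> np.ndarray:
    """Softmax alignment weights from attention scores (positive, sum to 1)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ConfigurationError("attention_weights requires nonempty scores")
    e = np.exp(s - s.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = math.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, shape)


class _Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Tensor(_glorot(rng, (d_in, d_out)))
        self.b = Tensor(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _Conv1D:
    """Valid-mode 1-D convolution over the time axis of (B, L, F)."""

    def __init__(self, rng, d_in: int, channels: int, kernel_size: int):
        self.kernel_size = kernel_size
        self.taps = [Tensor(_glorot(rng, (d_in, channels))) for _ in range(kernel_size)]
        self.b = Tensor(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        L_out = L - self.kernel_size + 1
        if L_out < 1:
            raise ConfigurationError(
                f"window of length {L} shorter than CNN kernel {self.kernel_size}"
            )
        out = None
        for k, W in enumerate(self.taps):
            term = x[:, k : k + L_out, :] @ W
            out = term if out is None else out + term
        return (out + self.b).relu()

    def params(self):
        return [*self.taps, self.b]


class _LSTMCell:
    def __init__(self, rng, d_in: int, hidden: int):
        self.hidden = hidden
        self.p = {}
        for gate in ("i", "f", "o", "c"):
            self.p[f"W{gate}"] = Tensor(_glorot(rng, (d_in, hidden)))
            self.p[f"U{gate}"] = Tensor(_glorot(rng, (hidden, hidden)))
            self.p[f"b{gate}"] = Tensor(np.zeros(hidden))

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        p = self.p
        i = (x @ p["Wi"] + h @ p["Ui"] + p["bi"]).sigmoid()
        f = (x @ p["Wf"] + h @ p["Uf"] + p["bf"]).sigmoid()
        o = (x @ p["Wo"] + h @ p["Uo"] + p["bo"]).sigmoid()
        g = (x @ p["Wc"] + h @ p["Uc"] + p["bc"]).tanh()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new

    def run(self, seq: list[Tensor], batch: int) -> list[Tensor]:
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        out = []
        for x in seq:
            h, c = self.step(x, h, c)
            out.append(h)
        return out

    def params(self):
        return list(self.p.values())


class _GRUCell:
    def __init__(self, rng, d_in: int, hidden: int):
        self.hidden = hidden
        self.p = {
            "Wxz": Tensor(_glorot(rng, (d_in, hidden))),
            "Whz": Tensor(_glorot(rng, (hidden, hidden))),
            "bz": Tensor(np.zeros(hidden)),
            "Wxr": Tensor(_glorot(rng, (d_in, hidden))),
            "Whr": Tensor(_glorot(rng, (hidden, hidden))),
            "br": Tensor(np.zeros(hidden)),
            "Wxh": Tensor(_glorot(rng, (d_in, hidden))),
            "U": Tensor(_glorot(rng, (hidden, hidden))),
            "bh": Tensor(np.zeros(hidden)),
        }

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        p = self.p
        z = (x @ p["Wxz"] + h @ p["Whz"] + p["bz"]).sigmoid()
        r = (x @ p["Wxr"] + h @ p["Whr"] + p["br"]).sigmoid()
        candidate = (x @ p["Wxh"] + (r * h) @ p["U"] + p["bh"]).tanh()
        return (1.0 - z) * h + z * candidate

    def run(self, seq: list[Tensor], batch: int, reverse: bool = False) -> list[Tensor]:
        h = Tensor(np.zeros((batch, self.hidden)))
        out = []
        for x in reversed(seq) if reverse else seq:
            h = self.step(x, h)
            out.append(h)
        if reverse:
            out.reverse()
        return out

    def numpy_params(self) -> dict:
        return {k: v.data for k, v in self.p.items()}

    def params(self):
        return list(self.p.values())


class _Attention:
    """Additive attention: e_j = v . tanh(W h_j + U q + b), softmax over j."""

    def __init__(self, rng, d_state: int, d_query: int, d_align: int = 16):
        self.W = Tensor(_glorot(rng, (d_state, d_align)))
        self.U = Tensor(_glorot(rng, (d_query, d_align)))
        self.b = Tensor(np.zeros(d_align))
        self.v = Tensor(_glorot(rng, (d_align, 1)))

    def __call__(self, states: list[Tensor], query: Tensor) -> Tensor:
        scores = [((h @ self.W + query @ self.U + self.b).tanh() @ self.v) for h in states]
        e = concat(scores, axis=1)  # (B, T)
        a = softmax(e, axis=1)
        stacked = stack_time(states, axis=1)  # (B, T, H)
        weighted = stacked * a.reshape(a.shape[0], a.shape[1], 1)
        return weighted.sum(axis=1)

    def params(self):
        return [self.W, self.U, self.b, self.v]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class StageOneNet:
    """CNN feature extractor + (stacked) LSTM/GRU with attention + dense head."""

    def __init__(self, n_features: int, config: HybridModelConfig, rng,
                 cell: str = "lstm", use_cnn: bool = True):
        self.use_cnn = use_cnn
        d = n_features
        self._parts = []
        if use_cnn:
            self.conv = _Conv1D(rng, d, config.cnn.channels, config.cnn.kernel_size)
            self._parts.append(self.conv)
            d = config.cnn.channels
        self.cells = []
        for _ in range(config.lstm.layers):
            made = _LSTMCell(rng, d, config.lstm.hidden) if cell == "lstm" else _GRUCell(
                rng, d, config.lstm.hidden)
            self.cells.append(made)
            self._parts.append(made)
            d = config.lstm.hidden
        self.attn = _Attention(rng, d, d)
        self.head1 = _Dense(rng, d, config.lstm.dense)
        self.head2 = _Dense(rng, config.lstm.dense, 1)
        self._parts += [self.attn, self.head1, self.head2]

    def __call__(self, X: Tensor) -> Tensor:
        batch, L, _ = X.shape
        h = self.conv(X) if self.use_cnn else X
        seq = [h[:, t, :] for t in range(h.shape[1])]
        for cell_obj in self.cells:
            if isinstance(cell_obj, _LSTMCell):
                seq = cell_obj.run(seq, batch)
            else:
                seq = cell_obj.run(seq, batch)
        context = self.attn(seq, seq[-1])
        return self.head2(self.head1(context).relu())

    def params(self):
        out = []
        for part in self._parts:
            out += part.params()
        return out


class ResidualNet:
    """Bidirectional GRU with attention regressing stage-one residuals."""

    def __init__(self, n_features: int, config: HybridModelConfig, rng):
        cfg = config.bigru
        self.fwd, self.bwd = [], []
        d = n_features
        for _ in range(cfg.layers):
            self.fwd.append(_GRUCell(rng, d, cfg.hidden))
            self.bwd.append(_GRUCell(rng, d, cfg.hidden))
            d = 2 * cfg.hidden
        self.attn = _Attention(rng, d, d)
        dims = [d]
        width = cfg.dense
        for _ in range(max(cfg.fully_connected - 1, 1)):
            dims.append(width)
            width = max(width // 2, 4)
        dims.append(1)
        rng_heads = rng
        self.heads = [_Dense(rng_heads, a, b) for a, b in zip(dims, dims[1:])]

    def __call__(self, X: Tensor) -> Tensor:
        batch = X.shape[0]
        seq = [X[:, t, :] for t in range(X.shape[1])]
        for f_cell, b_cell in zip(self.fwd, self.bwd):
            fw = f_cell.run(seq, batch)
            bw = b_cell.run(seq, batch, reverse=True)
            seq = [concat([a, b], axis=1) for a, b in zip(fw, bw)]
        context = self.attn(seq, seq[-1])
        h = context
        for head in self.heads[:-1]:
            h = head(h).tanh()
        return self.heads[-1](h)

    def params(self):
        out = []
        for cell in self.fwd + self.bwd:
            out += cell.params()
        out += self.attn.params()
        for head in self.heads:
            out += head.params()
        return out


def _train_net(net, X: np.ndarray, y: np.ndarray, config: HybridModelConfig,
               rng: np.random.Generator) -> list[float]:
    """Minibatch Adam / MSE with early stopping on the training loss."""
    opt = Adam(net.params(), lr=config.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    best, since_best = np.inf, 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Tensor(X[idx])
            yb = Tensor(y[idx][:, None])
            pred = net(xb)
            loss = ((pred - yb) ** 2.0).mean()
            if not np.isfinite(loss.data):
                raise TrainingError(f"training diverged (NaN/inf loss); config: {config}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        history.append(epoch_loss / n)
        if history[-1] < best - 1e-12:
            best, since_best = history[-1], 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return history


# ---------------------------------------------------------------------------
# hybrid training and forecasting
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    nets: list
    windowed: WindowedData
    config: HybridModelConfig
    history: list[list[float]]
    n_train: int
    val_residual_sd: float = 0.0
    constant_scaled: float | None = None  # degenerate zero-span target

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        if self.constant_scaled is not None:
            return np.full(X.shape[0], self.constant_scaled)
        total = np.zeros(X.shape[0])
        for net in self.nets:
            total += net(Tensor(X)).data[:, 0]
        return total

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.windowed.target_scaler.inverse(self.predict_scaled(X)[:, None])[:, 0]

    def stage_predictions(self, X: np.ndarray) -> list[np.ndarray]:
        if self.constant_scaled is not None:
            return [np.full(X.shape[0], self.constant_scaled)]
        return [net(Tensor(X)).data[:, 0] for net in self.nets]


def _split(n: int, fraction: float) -> int:
    return max(1, min(n - 1, int(math.floor(n * fraction)))) if n >= 2 else n


def train_hybrid(windowed: WindowedData, config: HybridModelConfig) -> TrainedModel:
    """Two-stage CNN-LSTM(+attention) -> BiGRU(+attention) residual model.

    Stage one fits the target; stage two fits the *training-set* residuals of
    stage one on the same windows (validation data never leak into residual
    targets); the model's prediction is the sum of the stages.
    """
    X, y = windowed.X, windowed.y
    if X.shape[0] < 2:
        raise InsufficientDataError("train_hybrid requires >= 2 samples")
    rng = np.random.default_rng(config.seed)
    n_train = _split(X.shape[0], config.train_fraction)
    if np.ptp(y) == 0.0:
        # degenerate zero-span target: the exact constant is the optimum
        return TrainedModel(nets=[], windowed=windowed, config=config,
                            history=[[0.0]], n_train=n_train,
                            constant_scaled=float(y[0]))
    Xtr, ytr = X[:n_train], y[:n_train]
    stage1 = StageOneNet(X.shape[2], config, rng, cell="lstm", use_cnn=True)
    hist1 = _train_net(stage1, Xtr, ytr, config, rng)
    residual = ytr - stage1(Tensor(Xtr)).data[:, 0]
    stage2 = ResidualNet(X.shape[2], config, rng)
    hist2 = _train_net(stage2, Xtr, residual, config, rng)
    model = TrainedModel(nets=[stage1, stage2], windowed=windowed, config=config,
                         history=[hist1, hist2], n_train=n_train)
    val_X, val_y = X[n_train:], y[n_train:]
    if val_X.shape[0]:
        resid = windowed.target_scaler.inverse(val_y[:, None])[:, 0] - model.predict(val_X)
        model.val_residual_sd = float(np.sqrt(np.mean(resid**2)))
    return model


BASELINE_KINDS = ("lstm", "gru", "cnn_lstm", "cnn_gru")


def train_baseline(windowed: WindowedData, config: HybridModelConfig, kind: str) -> TrainedModel:
    """Single-stage baseline sharing the hybrid's training protocol."""
    if kind not in BASELINE_KINDS:
        raise ConfigurationError(f"kind must be one of {BASELINE_KINDS}, got {kind!r}")
    X, y = windowed.X, windowed.y
    if X.shape[0] < 2:
        raise InsufficientDataError("train_baseline requires >= 2 samples")
    rng = np.random.default_rng(config.seed)
    n_train = _split(X.shape[0], config.train_fraction)
    if np.ptp(y) == 0.0:
        return TrainedModel(nets=[], windowed=windowed, config=config,
                            history=[[0.0]], n_train=n_train,
                            constant_scaled=float(y[0]))
    cell = "lstm" if "lstm" in kind else "gru"
    net = StageOneNet(X.shape[2], config, rng, cell=cell, use_cnn=kind.startswith("cnn"))
    hist = _train_net(net, X[:n_train], y[:n_train], config, rng)
    model = TrainedModel(nets=[net], windowed=windowed, config=config,
                         history=[hist], n_train=n_train)
    val_X, val_y = X[n_train:], y[n_train:]
    if val_X.shape[0]:
        resid = windowed.target_scaler.inverse(val_y[:, None])[:, 0] - model.predict(val_X)
        model.val_residual_sd = float(np.sqrt(np.mean(resid**2)))
    return model


def validation_rmse(model: TrainedModel) -> float:
    """Held-out RMSE on the [0, 1] target scale."""
    w = model.windowed
    val_X, val_y = w.X[model.n_train :], w.y[model.n_train :]
    if not val_X.shape[0]:
        raise InsufficientDataError("model has no validation split")
    return float(np.sqrt(np.mean((model.predict_scaled(val_X) - val_y) ** 2)))


@dataclass
class StressForecast:
    """Validation-period point forecasts with 95% Gaussian bands."""

    factor: str
    horizon_min: float
    target_index: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    residual_correction: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if np.any(self.lower > self.point + 1e-12) or np.any(self.point > self.upper + 1e-12):
            raise ConfigurationError("forecast bands must satisfy lower <= point <= upper")


def horizon_steps(horizon_min: float, sample_interval_min: float) -> int:
    steps = int(round(horizon_min / sample_interval_min))
    if steps < 1:
        raise ConfigurationError(
            f"horizon {horizon_min} min is below the sampling interval {sample_interval_min} min"
        )
    return steps


def forecast(model: TrainedModel, factor: str, horizon_min: float) -> StressForecast:
    """Validation-period forecast of one trained per-horizon model.

    The 95% band is ``point +/- 1.96 * sd`` with ``sd`` the validation
    residual standard deviation about zero (RMS residual, so systematic
    validation bias widens the band); bounds are degenerate and equal when
    the validation residuals vanish.
    """
    w = model.windowed
    val_X = w.X[model.n_train :]
    if not val_X.shape[0]:
        raise InsufficientDataError("model has no validation split to forecast")
    point = model.predict(val_X)
    half = 1.96 * model.val_residual_sd
    stages = model.stage_predictions(val_X)
    correction = (
        w.target_scaler.inverse(stages[1][:, None])[:, 0] - w.target_scaler.lo[0]
        if len(stages) > 1
        else np.zeros_like(point)
    )
    return StressForecast(
        factor=factor,
        horizon_min=horizon_min,
        target_index=w.target_index[model.n_train :],
        point=point,
        lower=point - half,
        upper=point + half,
        residual_correction=correction,
    )
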