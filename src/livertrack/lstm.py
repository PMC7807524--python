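"""Peephole LSTM cell and a numpy sequence-regression network built on it.

The memory block follows the classic peephole formulation.  With input
``x_t``, previous hidden outputs ``b_h^{t-1}`` and previous cell values
``s_c^{t-1}``:

* input gate      ``b_l = f(W_il x_t + w_cl s^{t-1} + W_hl b^{t-1})``
* forget gate     ``b_phi = f(W_iphi x_t + w_cphi s^{t-1} + W_hphi b^{t-1})``
* cell update     ``s^t = b_phi s^{t-1} + b_l g(W_ic x_t + W_hc b^{t-1})``
* output gate     ``b_w = f(W_iw x_t + w_cw s^t + W_hw b^{t-1})``  (note:
  the output-gate peephole reads the *current* cell value)
* block output    ``b^t = b_w h(s^t)``

with f the logistic sigmoid and g = h = tanh; peephole weights are diagonal
(one scalar per cell).  Biases are optional and default to zero, so the bare
cell reproduces the equations above exactly; training enables them.

Training is full backpropagation through time with Adam on mean squared
error, implemented directly in numpy (gradients include the peephole terms;
verified against finite differences in the test suite).  Dropout is applied
between stacked layers during training only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["LSTMCellWeights", "LSTMState", "NetworkConfig", "TrainConfig",
           "lstm_cell_step", "lstm_forward", "LSTMRegressor", "train_lstm"]


@dataclass
class LSTMCellWeights:
    """Weights of one peephole memory-block layer.

    ``w_x`` (I, 4H) and ``w_h`` (H, 4H) stack the four gate blocks in the
    order (input gate, forget gate, cell input, output gate); ``p_in``,
    ``p_forget``, ``p_out`` are the diagonal peephole weights from the cell
    values to the three gates; ``bias`` (4H,) defaults to zero.
    """

    w_x: np.ndarray
    w_h: np.ndarray
    p_in: np.ndarray
    p_forget: np.ndarray
    p_out: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.w_x = np.asarray(self.w_x, dtype=float)
        self.w_h = np.asarray(self.w_h, dtype=float)
        self.p_in = np.asarray(self.p_in, dtype=float)
        self.p_forget = np.asarray(self.p_forget, dtype=float)
        self.p_out = np.asarray(self.p_out, dtype=float)
        H = self.hidden_size
        if self.w_x.ndim != 2 or self.w_x.shape[1] != 4 * H:
            raise ValueError("w_x must have shape (I, 4H)")
        if self.w_h.shape != (H, 4 * H):
            raise ValueError("w_h must have shape (H, 4H)")
        for p in (self.p_in, self.p_forget, self.p_out):
            if p.shape != (H,):
                raise ValueError("peephole weights must have shape (H,)")
        if self.bias is None:
            self.bias = np.zeros(4 * H)
        else:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (4 * H,):
                raise ValueError("bias must have shape (4H,)")
        arrays = (self.w_x, self.w_h, self.p_in, self.p_forget, self.p_out,
                  self.bias)
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("weights must be finite")

    @property
    def input_size(self) -> int:
        return self.w_x.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w_h.shape[0]

    @classmethod
    def constant(cls, input_size: int, hidden_size: int,
                 value: float) -> "LSTMCellWeights":
        """All gate, recurrent and peephole weights set to ``value``
        (biases zero) — handy for worked-example checks."""
        return cls(
            w_x=np.full((input_size, 4 * hidden_size), value),
            w_h=np.full((hidden_size, 4 * hidden_size), value),
            p_in=np.full(hidden_size, value),
            p_forget=np.full(hidden_size, value),
            p_out=np.full(hidden_size, value),
        )


@dataclass
class LSTMState:
    """Cell values ``s_c`` and hidden outputs ``b_h`` after step ``t``."""

    c: np.ndarray
    h: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, hidden_size: int, batch: int | None = None) -> "LSTMState":
        shape = (hidden_size,) if batch is None else (batch, hidden_size)
        return cls(c=np.zeros(shape), h=np.zeros(shape), t=0)


def lstm_cell_step(weights: LSTMCellWeights, state: LSTMState,
                   x_t: np.ndarray) -> tuple[LSTMState, np.ndarray]:
    """Advance one memory-block layer by one time step.

    ``x_t`` may be a single input vector (I,) or a batch (B, I).  Returns
    the new state and the block output ``b_w * tanh(s^t)``.  Gate order of
    evaluation matters: input and forget peepholes read the previous cell
    value, the output-gate peephole reads the freshly updated one.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != weights.input_size:
        raise ValueError(
            f"input size {x_t.shape[-1]} != expected {weights.input_size}")
    if not np.all(np.isfinite(x_t)):
        raise ValueError("non-finite input")
    H = weights.hidden_size
    a = x_t @ weights.w_x + state.h @ weights.w_h + weights.bias
    a_in, a_forget, a_cell, a_out = (a[..., :H], a[..., H:2 * H],
                                     a[..., 2 * H:3 * H], a[..., 3 * H:])
    gate_in = _sigmoid(a_in + weights.p_in * state.c)
    gate_forget = _sigmoid(a_forget + weights.p_forget * state.c)
    c_new = gate_forget * state.c + gate_in * np.tanh(a_cell)
    gate_out = _sigmoid(a_out + weights.p_out * c_new)
    output = gate_out * np.tanh(c_new)
    return LSTMState(c=c_new, h=output, t=state.t + 1), output


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the stacked recurrent regressor.

    Two stacked layers of 32 memory blocks with a linear readout are the
    default: small enough to train quickly on a single CPU, deep enough
    that inter-layer dropout is meaningful.  ``window`` is the number of
    time steps fed to the network (20 samples = 1 s at 20 Hz).
    """

    num_layers: int = 2
    hidden_size: int = 32
    dropout: float = 0.20
    window: int = 20
    use_biases: bool = True

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.window < 1 or self.num_layers < 1 or self.hidden_size < 1:
            raise ValueError("window, layers and hidden size must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Adam/MSE training settings (learning rate 0.001, batch 64)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0, batch size >= 1")


def _init_layer(rng: np.random.Generator, input_size: int, hidden_size: int,
                use_biases: bool) -> LSTMCellWeights:
    k = 1.0 / np.sqrt(hidden_size)
    w = LSTMCellWeights(
        w_x=rng.uniform(-k, k, (input_size, 4 * hidden_size)),
        w_h=rng.uniform(-k, k, (hidden_size, 4 * hidden_size)),
        p_in=np.zeros(hidden_size),
        p_forget=np.zeros(hidden_size),
        p_out=np.zeros(hidden_size),
    )
    if use_biases:
        # forget-gate bias starts at 1 so early training does not forget
        w.bias[hidden_size:2 * hidden_size] = 1.0
    return w


class LSTMRegressor:
    """Stacked peephole-LSTM network with a linear readout to one scalar.

    Consumes a window of W scalar samples (fed one per time step) and emits
    the regression target; used both for latency-compensating prediction of
    the external signal and for the external->internal correlation map.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[LSTMCellWeights] = []
        in_size = 1
        for _ in range(config.num_layers):
            self.layers.append(_init_layer(rng, in_size, config.hidden_size,
                                           config.use_biases))
            in_size = config.hidden_size
        k = 1.0 / np.sqrt(config.hidden_size)
        self.w_out = rng.uniform(-k, k, config.hidden_size)
        self.b_out = 0.0
        self.loss_history: list[float] = []

    # ---------------------------------------------------------------- forward

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference: (M, W) windows -> (M,) predictions.

        Dropout is disabled; a single window (W,) is also accepted.
        """
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.config.window:
            raise ValueError(
                f"window length {X.shape[1]} != config {self.config.window}")
        B, T = X.shape
        seq = X.T[:, :, None]  # (T, B, 1)
        for weights in self.layers:
            state = LSTMState.zeros(self.config.hidden_size, B)
            outs = np.empty((T, B, self.config.hidden_size))
            for t in range(T):
                state, outs[t] = lstm_cell_step(weights, state, seq[t])
            seq = outs
        pred = seq[-1] @ self.w_out + self.b_out
        return pred[0] if single else pred

    # ------------------------------------------------------------ parameters

    def _params(self) -> list[np.ndarray]:
        ps = []
        for w in self.layers:
            ps += [w.w_x, w.w_h, w.p_in, w.p_forget, w.p_out, w.bias]
        ps.append(self.w_out)
        return ps

    # ------------------------------------------------------- fwd/bwd training

    def _forward_cached(self, X: np.ndarray, dropout_rng=None):
        """Forward pass storing per-layer, per-step intermediates."""
        cfg = self.config
        B, T = X.shape
        H = cfg.hidden_size
        seq = X.T[:, :, None]
        caches, masks = [], []
        for li, w in enumerate(self.layers):
            if li > 0 and dropout_rng is not None and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (dropout_rng.random(seq.shape) < keep) / keep
                seq = seq * mask
            else:
                mask = None
            masks.append(mask)
            gi = np.empty((T, B, H)); gf = np.empty((T, B, H))
            gc = np.empty((T, B, H)); go = np.empty((T, B, H))
            cs = np.empty((T, B, H)); hs = np.empty((T, B, H))
            c_prev = np.zeros((B, H)); h_prev = np.zeros((B, H))
            x_seq = seq
            for t in range(T):
                a = x_seq[t] @ w.w_x + h_prev @ w.w_h + w.bias
                i_g = _sigmoid(a[:, :H] + w.p_in * c_prev)
                f_g = _sigmoid(a[:, H:2 * H] + w.p_forget * c_prev)
                g = np.tanh(a[:, 2 * H:3 * H])
                c = f_g * c_prev + i_g * g
                o_g = _sigmoid(a[:, 3 * H:] + w.p_out * c)
                h = o_g * np.tanh(c)
                gi[t], gf[t], gc[t], go[t], cs[t], hs[t] = i_g, f_g, g, o_g, c, h
                c_prev, h_prev = c, h
            caches.append({"x": x_seq, "i": gi, "f": gf, "g": gc, "o": go,
                           "c": cs, "h": hs})
            seq = hs
        pred = seq[-1] @ self.w_out + self.b_out
        return pred, caches, masks

    def _backward(self, X, pred, y, caches, masks):
        cfg = self.config
        B, T = X.shape
        H = cfg.hidden_size
        dpred = 2.0 * (pred - y) / B  # d(MSE)/d(pred)
        grads = {"w_out": caches[-1]["h"][-1].T @ dpred,
                 "b_out": float(dpred.sum())}
        dh_seq = np.zeros((T, B, H))
        dh_seq[-1] = dpred[:, None] * self.w_out

        layer_grads = []
        for li in range(len(self.layers) - 1, -1, -1):
            w = self.layers[li]
            cache = caches[li]
            I = w.input_size
            dWx = np.zeros_like(w.w_x); dWh = np.zeros_like(w.w_h)
            dpi = np.zeros(H); dpf = np.zeros(H); dpo = np.zeros(H)
            db = np.zeros(4 * H)
            dx_seq = np.zeros((T, B, I))
            dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i_g = cache["i"][t]; f_g = cache["f"][t]; g = cache["g"][t]
                o_g = cache["o"][t]; c = cache["c"][t]
                c_prev = cache["c"][t - 1] if t > 0 else np.zeros((B, H))
                h_prev = cache["h"][t - 1] if t > 0 else np.zeros((B, H))
                tanh_c = np.tanh(c)

                dh = dh_seq[t] + dh_next
                dc = dc_next + dh * o_g * (1.0 - tanh_c ** 2)
                da_o = dh * tanh_c * o_g * (1.0 - o_g)
                dc = dc + da_o * w.p_out
                da_i = dc * g * i_g * (1.0 - i_g)
                da_f = dc * c_prev * f_g * (1.0 - f_g)
                da_c = dc * i_g * (1.0 - g ** 2)
                dc_next = dc * f_g + da_i * w.p_in + da_f * w.p_forget

                dpo += (da_o * c).sum(axis=0)
                dpi += (da_i * c_prev).sum(axis=0)
                dpf += (da_f * c_prev).sum(axis=0)

                da = np.concatenate([da_i, da_f, da_c, da_o], axis=1)
                x_t = cache["x"][t]
                dWx += x_t.T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dx_seq[t] = da @ w.w_x.T
                dh_next = da @ w.w_h.T
            layer_grads.append([dWx, dWh, dpi, dpf, dpo, db])
            if li > 0:
                mask = masks[li]
                dh_seq = dx_seq if mask is None else dx_seq * mask
        flat = []
        for g6 in reversed(layer_grads):
            flat += g6
        flat.append(grads["w_out"])
        return flat, grads["b_out"]

    def gradients(self, X: np.ndarray, y: np.ndarray):
        """Analytic MSE gradients (no dropout) — used by the finite-
        difference sanity check."""
        X = np.asarray(X, dtype=float); y = np.asarray(y, dtype=float)
        pred, caches, masks = self._forward_cached(X, dropout_rng=None)
        return self._backward(X, pred, y, caches, masks)

    def fit(self, X: np.ndarray, y: np.ndarray,
            train_config: TrainConfig | None = None) -> list[float]:
        """Minibatch Adam on MSE; returns the per-epoch loss history.

        Seeded runs are bit-reproducible: the training seed drives batch
        shuffling and dropout masks (weight init is fixed at construction).
        """
        tc = train_config or TrainConfig()
        X = np.asarray(X, dtype=float); y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y) or len(X) == 0:
            raise ValueError("X must be (M, W) with matching non-empty y")
        rng = np.random.default_rng(tc.seed)
        params = self._params()
        m = [np.zeros_like(p) for p in params] + [0.0]
        v = [np.zeros_like(p) for p in params] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history = []
        for _epoch in range(tc.epochs):
            order = rng.permutation(len(X))
            sq_sum = 0.0
            for start in range(0, len(X), tc.batch_size):
                idx = order[start:start + tc.batch_size]
                Xb, yb = X[idx], y[idx]
                drop_rng = rng if self.config.dropout > 0 else None
                pred, caches, masks = self._forward_cached(Xb, drop_rng)
                gflat, g_bout = self._backward(Xb, pred, yb, caches, masks)
                sq_sum += float(np.sum((pred - yb) ** 2))
                step += 1
                for j, (p, g) in enumerate(zip(params, gflat)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1 ** step)
                    vhat = v[j] / (1 - beta2 ** step)
                    p -= tc.learning_rate * mhat / (np.sqrt(vhat) + eps)
                j = len(params)
                m[j] = beta1 * m[j] + (1 - beta1) * g_bout
                v[j] = beta2 * v[j] + (1 - beta2) * g_bout * g_bout
                self.b_out -= tc.learning_rate * (
                    m[j] / (1 - beta1 ** step)) / (
                    np.sqrt(v[j] / (1 - beta2 ** step)) + eps)
            self.loss_history.append(sq_sum / len(X))
        return self.loss_history

    # -------------------------------------------------------- serialization

    def state_dict(self) -> dict:
        from dataclasses import asdict
        layers = [{k: np.asarray(a).tolist()
                   for k, a in (("w_x", w.w_x), ("w_h", w.w_h),
                                ("p_in", w.p_in), ("p_forget", w.p_forget),
                                ("p_out", w.p_out), ("bias", w.bias))}
                  for w in self.layers]
        return {"config": asdict(self.config), "layers": layers,
                "w_out": self.w_out.tolist(), "b_out": float(self.b_out)}

    @classmethod
    def from_state_dict(cls, state: dict) -> "LSTMRegressor":
        cfg = NetworkConfig(**state["config"])
        model = cls(cfg, seed=0)
        model.layers = [LSTMCellWeights(**{k: np.array(v)
                                           for k, v in layer.items()})
                        for layer in state["layers"]]
        model.w_out = np.array(state["w_out"])
        model.b_out = float(state["b_out"])
        return model


def lstm_forward(model: LSTMRegressor, sequence: np.ndarray) -> float:
    """Run one window through the network (inference, no dropout)."""
    return float(model.forward(np.asarray(sequence, dtype=float)))


def train_lstm(config: NetworkConfig, train_config: TrainConfig,
               X: np.ndarray, y: np.ndarray
               ) -> tuple[LSTMRegressor, list[float]]:
    """Construct and train a regressor; returns (model, loss history)."""
    model = LSTMRegressor(config, seed=train_config.seed)
    history = model.fit(X, y, train_config)
    return model, history
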