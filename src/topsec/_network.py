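"""Compact numpy neural network used as the emission provider.

Architecture (matching the hybrid model's deep-learning module at desk
scale): stacked 1-D convolutions over the residue window, a bidirectional
LSTM, additive attention pooling over window positions, two fully connected
layers, and a softmax-over-states or sigmoid-per-state head.  Forward and
backward passes are written out explicitly and verified against finite
differences in the test suite; parameters are trained with Adam.

Everything is float64 and driven by a single ``numpy.random.Generator`` so
training is bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EmissionNetwork"]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class _Layer:
    """Parameterised layer: ``params``/``grads`` are dicts of arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Conv1D(_Layer):
    """Same-padded 1-D convolution over the window axis. (B,T,Cin)->(B,T,Cout)."""

    def __init__(self, rng, c_in, c_out, kernel):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        self.params = {"W": _glorot(rng, (kernel * c_in, c_out)), "b": np.zeros(c_out)}

    def forward(self, x):
        B, T, C = x.shape
        half = self.k // 2
        xp = np.zeros((B, T + 2 * half, C))
        xp[:, half : half + T] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)  # (B,T,C,k)
        cols = cols.transpose(0, 1, 3, 2).reshape(B, T, self.k * C)
        self._cols, self._shape = cols, (B, T, C)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        B, T, C = self._shape
        half = self.k // 2
        self.grads["W"] = np.einsum("btk,btc->kc", self._cols, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = dout @ self.params["W"].T  # (B,T,k*C)
        dcols = dcols.reshape(B, T, self.k, C)
        dxp = np.zeros((B, T + 2 * half, C))
        for j in range(self.k):
            dxp[:, j : j + T] += dcols[:, :, j]
        return dxp[:, half : half + T]


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LSTM(_Layer):
    """Single-direction LSTM, full-sequence output. (B,T,C)->(B,T,U)."""

    def __init__(self, rng, c_in, units):
        super().__init__()
        self.u = units
        self.params = {
            "Wx": _glorot(rng, (c_in, 4 * units)),
            "Wh": _glorot(rng, (units, 4 * units)),
            "b": np.zeros(4 * units),
        }
        # forget-gate bias starts at 1 (common initialisation for gradient flow)
        self.params["b"][units : 2 * units] = 1.0

    def forward(self, x):
        B, T, C = x.shape
        U = self.u
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, U))
        for t in range(T):
            z = x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return hs

    def backward(self, dhs):
        x = self._x
        B, T, C = x.shape
        U = self.u
        dWx = np.zeros_like(self.params["Wx"])
        dWh = np.zeros_like(self.params["Wh"])
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class BiLSTM(_Layer):
    """Concatenated forward/backward LSTM outputs. (B,T,C)->(B,T,2U)."""

    def __init__(self, rng, c_in, units):
        super().__init__()
        self.fwd = LSTM(rng, c_in, units)
        self.bwd = LSTM(rng, c_in, units)

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        u = self.fwd.u
        dxf = self.fwd.backward(dout[:, :, :u])
        dxb = self.bwd.backward(dout[:, ::-1, u:])[:, ::-1]
        return dxf + dxb


class AttentionPool(_Layer):
    """Additive attention over window positions: (B,T,D)->(B,D).

    score_t = v . tanh(W h_t + b); weights = softmax over t; output is the
    weighted sum of position vectors.
    """

    def __init__(self, rng, d_in, d_att):
        super().__init__()
        self.params = {"W": _glorot(rng, (d_in, d_att)), "b": np.zeros(d_att), "v": _glorot(rng, (d_att, 1))[:, 0]}

    def forward(self, h):
        s = np.tanh(h @ self.params["W"] + self.params["b"])  # (B,T,Da)
        u = s @ self.params["v"]  # (B,T)
        u = u - u.max(axis=1, keepdims=True)
        e = np.exp(u)
        a = e / e.sum(axis=1, keepdims=True)
        self._h, self._s, self._a = h, s, a
        return np.einsum("bt,btd->bd", a, h)

    def backward(self, dout):
        h, s, a = self._h, self._s, self._a
        dh = a[:, :, None] * dout[:, None, :]
        da = np.einsum("btd,bd->bt", h, dout)
        du = a * (da - (a * da).sum(axis=1, keepdims=True))
        self.grads["v"] = np.einsum("btd,bt->d", s, du)
        ds = du[:, :, None] * self.params["v"]
        dpre = ds * (1 - s * s)
        self.grads["W"] = np.einsum("btd,bte->de", h, dpre)
        self.grads["b"] = dpre.sum(axis=(0, 1))
        dh += dpre @ self.params["W"].T
        return dh


class CenterPick(_Layer):
    """No-attention alternative: take the central window position."""

    def forward(self, h):
        self._T = h.shape[1]
        return h[:, self._T // 2]

    def backward(self, dout):
        dh = np.zeros((dout.shape[0], self._T, dout.shape[1]))
        dh[:, self._T // 2] = dout
        return dh


class Dense(_Layer):
    def __init__(self, rng, d_in, d_out):
        super().__init__()
        self.params = {"W": _glorot(rng, (d_in, d_out)), "b": np.zeros(d_out)}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class DenseReLU(Dense):
    def forward(self, x):
        z = super().forward(x)
        self._mask = z > 0
        return z * self._mask

    def backward(self, dout):
        return super().backward(dout * self._mask)


class Adam:
    def __init__(self, params: list[np.ndarray], lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EmissionNetwork:
    """Window classifier/regressor: (B, window, features) -> (B, n_outputs).

    ``head='softmax_states'`` produces a probability vector (rows sum to 1)
    trained by cross-entropy against (possibly soft) targets;
    ``head='sigmoid_per_state'`` produces independent values in (0, 1), one
    regressor head per emitting state, trained by a squared-error loss that
    accepts an additive residual term per output.
    """

    def __init__(self, cfg, n_features: int, n_outputs: int):
        self.cfg = cfg
        self.n_outputs = n_outputs
        rng = np.random.default_rng(cfg.seed)
        layers: list[_Layer] = []
        c = n_features
        for filters, kernel in cfg.conv_layers:
            layers.append(Conv1D(rng, c, filters, kernel))
            layers.append(ReLU())
            c = filters
        if cfg.lstm_units > 0:
            layers.append(BiLSTM(rng, c, cfg.lstm_units))
            c = 2 * cfg.lstm_units
        if cfg.attention:
            layers.append(AttentionPool(rng, c, max(8, c // 2)))
        else:
            layers.append(CenterPick())
        f1, f2 = cfg.fc_units
        layers.append(DenseReLU(rng, c, f1))
        layers.append(DenseReLU(rng, f1, f2))
        layers.append(Dense(rng, f2, n_outputs))
        self.layers = layers
        self.opt = Adam(self._params(), lr=cfg.learning_rate)

    # -- parameter plumbing ------------------------------------------------
    def _param_layers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.sublayers if isinstance(layer, BiLSTM) else [layer])
        return out

    def _params(self) -> list[np.ndarray]:
        return [p for l in self._param_layers() for p in l.params.values()]

    def _grads(self) -> list[np.ndarray]:
        return [l.grads[k] for l in self._param_layers() for k in l.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self._params(), weights, strict=True):
            p[...] = w

    # -- forward / loss ----------------------------------------------------
    def _logits(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            return np.zeros((0, self.n_outputs))
        z = self._logits(X)
        if self.cfg.head == "softmax_states":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return _sigmoid(z)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def loss_and_backward(self, X, targets, residual=None) -> float:
        """Compute the head loss, run backprop, leave grads in the layers.

        softmax head: mean cross-entropy, -sum_k t_k log p_k.
        sigmoid head: mean over entries of ((residual + t - e))^2 with e the
        sigmoid output; residual defaults to 0 (plain MSE toward t).
        """
        z = self._logits(X)
        B = X.shape[0]
        if self.cfg.head == "softmax_states":
            z = z - z.max(axis=1, keepdims=True)
            logZ = np.log(np.exp(z).sum(axis=1, keepdims=True))
            logp = z - logZ
            loss = float(-(targets * logp).sum() / B)
            p = np.exp(logp)
            self._backward((p - targets) / B)
        else:
            e = _sigmoid(z)
            r = 0.0 if residual is None else residual
            err = r + targets - e
            n = err.size
            loss = float((err**2).sum() / n)
            dE = -2.0 * err / n
            self._backward(dE * e * (1 - e))
        return loss

    def train_step(self, X, targets, residual=None) -> float:
        loss = self.loss_and_backward(X, targets, residual)
        self.opt.step(self._params(), self._grads())
        return loss
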