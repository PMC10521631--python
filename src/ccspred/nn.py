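"""Minimal NumPy neural-network primitives with hand-written gradients.

Implements exactly the layers the residual CCS predictor needs: a token
embedding, gated recurrent units (double-bias variant, so each direction has
3·(in·u + u² + 2u) weights), a bidirectional wrapper with padding masks, and
dense layers with inverted dropout. Gradients are accumulated into ``.grads``
by the ``backward`` methods and validated against finite differences in the
test suite. An :class:`Adam` optimizer updates any list of parameter arrays.

All arithmetic is float64; forward passes cache what backward needs.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Layer:
    """Base: named parameter arrays plus matching gradient accumulators."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray):
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self._register("E", rng.normal(0.0, 0.05, size=(vocab_size, dim)))

    def forward(self, ids: np.ndarray) -> np.ndarray:
        return self.params["E"][ids]

    def backward(self, ids: np.ndarray, dout: np.ndarray):
        np.add.at(self.grads["E"], ids, dout)


class GRUDirection(Layer):
    """One direction of a GRU layer, double-bias ("reset after") gating.

        z_t = σ(x W_z + b_xz + h U_z + b_hz)
        r_t = σ(x W_r + b_xr + h U_r + b_hr)
        ĥ_t = tanh(x W_h + b_xh + r_t ∘ (h U_h + b_hh))
        h_t = z_t ∘ h_{t−1} + (1 − z_t) ∘ ĥ_t

    Padded steps (mask 0) carry the previous state through unchanged, so
    outputs are invariant to the amount of padding.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.units = units
        self._register("W", glorot(rng, in_dim, 3 * units))
        self._register("U", glorot(rng, units, 3 * units))
        self._register("bx", np.zeros(3 * units))
        self._register("bh", np.zeros(3 * units))

    def forward(self, x: np.ndarray, mask: np.ndarray):
        B, T, _ = x.shape
        u = self.units
        W, U, bx, bh = (self.params[k] for k in ("W", "U", "bx", "bh"))
        h = np.zeros((B, u))
        H = np.empty((B, T, u))
        cache = []
        gx_all = x @ W + bx  # (B, T, 3u), precomputed input gates
        for t in range(T):
            gh = h @ U + bh
            gx = gx_all[:, t]
            z = sigmoid(gx[:, :u] + gh[:, :u])
            r = sigmoid(gx[:, u : 2 * u] + gh[:, u : 2 * u])
            hh = gh[:, 2 * u :]
            hcand = np.tanh(gx[:, 2 * u :] + r * hh)
            h_new = z * h + (1.0 - z) * hcand
            m = mask[:, t : t + 1]
            cache.append((h, z, r, hh, hcand))
            h = m * h_new + (1.0 - m) * h
            H[:, t] = h
        self._cache = (x, mask, cache)
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        x, mask, cache = self._cache
        B, T, in_dim = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW, dU, dbx, dbh = (self.grads[k] for k in ("W", "U", "bx", "bh"))
        dx = np.zeros_like(x)
        dh = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, hh, hcand = cache[t]
            dh = dh + dH[:, t]
            m = mask[:, t : t + 1]
            dh_new = m * dh
            dh_prev = (1.0 - m) * dh
            dz = dh_new * (h_prev - hcand)
            dhc = dh_new * (1.0 - z)
            dh_prev = dh_prev + dh_new * z
            dtanh = dhc * (1.0 - hcand * hcand)
            dr = dtanh * hh
            d_hh = dtanh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            Gx = np.concatenate([dz_pre, dr_pre, dtanh], axis=1)
            Gh = np.concatenate([dz_pre, dr_pre, d_hh], axis=1)
            dW += x[:, t].T @ Gx
            dbx += Gx.sum(axis=0)
            dU += h_prev.T @ Gh
            dbh += Gh.sum(axis=0)
            dx[:, t] = Gx @ W.T
            dh = dh_prev + Gh @ U.T
        return dx


class BiGRU(Layer):
    """Bidirectional GRU layer; concatenates the two directions' features."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = GRUDirection(in_dim, units, rng)
        self.bwd = GRUDirection(in_dim, units, rng)
        for name, sub in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in sub.params.items():
                self.params[f"{name}_{k}"] = v
                self.grads[f"{name}_{k}"] = sub.grads[k]

    def forward(self, x: np.ndarray, mask: np.ndarray, return_sequences: bool):
        Hf = self.fwd.forward(x, mask)
        Hb = self.bwd.forward(x[:, ::-1], mask[:, ::-1])
        self._return_sequences = return_sequences
        if return_sequences:
            return np.concatenate([Hf, Hb[:, ::-1]], axis=2)
        # final states: last step of each direction (masking carries the
        # state of the last real token through the padding)
        return np.concatenate([Hf[:, -1], Hb[:, -1]], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        u = self.fwd.units
        B = dout.shape[0]
        if self._return_sequences:
            dHf = dout[:, :, :u]
            dHb = dout[:, ::-1, u:]
        else:
            T = self.fwd._cache[0].shape[1]
            dHf = np.zeros((B, T, u))
            dHb = np.zeros((B, T, u))
            dHf[:, -1] = dout[:, :u]
            dHb[:, -1] = dout[:, u:]
        dx = self.fwd.backward(dHf)
        dx = dx + self.bwd.backward(dHb)[:, ::-1]
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, activation: str = "linear"):
        super().__init__()
        self.activation = activation
        self._register("W", glorot(rng, in_dim, out_dim))
        self._register("b", np.zeros(out_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        a = np.maximum(z, 0.0) if self.activation == "relu" else z
        self._cache = (x, a)
        return a

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._cache
        dz = dout * (a > 0) if self.activation == "relu" else dout
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, pairs, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(pairs)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
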