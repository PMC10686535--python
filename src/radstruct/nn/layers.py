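"""Layers with explicit forward/backward passes.

Conventions: batches are (B, T, ...) float32 arrays with a (B, T) mask
(1.0 on real positions, 0.0 on padding).  Each layer owns its parameter
arrays in ``params`` and accumulates gradients of the same shapes in
``grads``; callers zero the gradients between steps.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _uniform(rng: np.random.Generator, shape, scale) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape).astype(DTYPE)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(3.0 / dim)
        self.params["W"] = _uniform(rng, (vocab_size, dim), scale)
        self.params["W"][0] = 0.0  # padding row
        self.zero_grad()

    def forward(self, ids: np.ndarray):
        self._ids = ids
        return self.params["W"][ids]

    def backward(self, d_out: np.ndarray) -> None:
        flat_ids = self._ids.reshape(-1)
        np.add.at(
            self.grads["W"], flat_ids, d_out.reshape(-1, d_out.shape[-1])
        )
        self.grads["W"][0] = 0.0


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(6.0 / (d_in + d_out))
        self.params["W"] = _uniform(rng, (d_in, d_out), scale)
        self.params["b"] = np.zeros(d_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d_out.reshape(-1, d_out.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return d_out @ self.params["W"].T


class _LSTMDirection(Layer):
    """One direction of an LSTM over a padded batch (B, T, D) -> (B, T, H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        sx = np.sqrt(6.0 / (d_in + 4 * hidden))
        self.params["Wx"] = _uniform(rng, (d_in, 4 * hidden), sx)
        # Orthogonal recurrent blocks (one per gate) speed up convergence.
        blocks = []
        for _ in range(4):
            a = rng.standard_normal((hidden, hidden))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        self.params["Wh"] = np.concatenate(blocks, axis=1).astype(DTYPE)
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        dt = x.dtype
        Wh = self.params["Wh"]
        pre = x @ self.params["Wx"] + self.params["b"]  # (B,T,4H)
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        cache_g = np.empty((B, T, 4 * H), dtype=dt)  # i,f,g~,o post-activation
        cache_tc = np.empty((B, T, H), dtype=dt)  # tanh(c_candidate)
        hs = np.empty((B, T, H), dtype=dt)
        cs = np.empty((B, T, H), dtype=dt)
        for t in range(T):
            g = pre[:, t] + h @ Wh
            i = _sigmoid(g[:, :H])
            f = _sigmoid(g[:, H : 2 * H])
            gg = np.tanh(g[:, 2 * H : 3 * H])
            o = _sigmoid(g[:, 3 * H :])
            c_new = f * c + i * gg
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t : t + 1]
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            cache_g[:, t, :H] = i
            cache_g[:, t, H : 2 * H] = f
            cache_g[:, t, 2 * H : 3 * H] = gg
            cache_g[:, t, 3 * H :] = o
            cache_tc[:, t] = tc
            hs[:, t] = h
            cs[:, t] = c
        self._cache = (x, mask, cache_g, cache_tc, hs, cs)
        return hs

    def backward(self, d_hs: np.ndarray) -> np.ndarray:
        x, mask, cache_g, cache_tc, hs, cs = self._cache
        B, T, _ = x.shape
        H = self.hidden
        dt = x.dtype
        Wh = self.params["Wh"]
        d_pre = np.zeros((B, T, 4 * H), dtype=dt)
        dh = np.zeros((B, H), dtype=dt)
        dc = np.zeros((B, H), dtype=dt)
        dWh = np.zeros_like(Wh)
        for t in range(T - 1, -1, -1):
            m = mask[:, t : t + 1]
            dh_total = dh + d_hs[:, t]
            dh_cand = m * dh_total
            dh_pass = (1.0 - m) * dh_total
            dc_cand = m * dc
            dc_pass = (1.0 - m) * dc
            i = cache_g[:, t, :H]
            f = cache_g[:, t, H : 2 * H]
            gg = cache_g[:, t, 2 * H : 3 * H]
            o = cache_g[:, t, 3 * H :]
            tc = cache_tc[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dt)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dt)
            do = dh_cand * tc
            dc_new = dc_cand + dh_cand * o * (1.0 - tc * tc)
            di = dc_new * gg
            dgg = dc_new * i
            df = dc_new * c_prev
            dc_prev_from_cell = dc_new * f
            dg = np.empty((B, 4 * H), dtype=dt)
            dg[:, :H] = di * i * (1.0 - i)
            dg[:, H : 2 * H] = df * f * (1.0 - f)
            dg[:, 2 * H : 3 * H] = dgg * (1.0 - gg * gg)
            dg[:, 3 * H :] = do * o * (1.0 - o)
            d_pre[:, t] = dg
            dWh += h_prev.T @ dg
            dh = dg @ Wh.T + dh_pass
            dc = dc_prev_from_cell + dc_pass
        self.grads["Wh"] += dWh
        x2 = x.reshape(-1, x.shape[-1])
        d2 = d_pre.reshape(-1, 4 * H)
        self.grads["Wx"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return d_pre @ self.params["Wx"].T


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its valid length; padding stays put."""
    out = np.array(x)
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
    return out


class BiLSTM(Layer):
    """Bidirectional LSTM; output concatenates both directions (B,T,2H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.fwd = _LSTMDirection(d_in, hidden, rng)
        self.bwd = _LSTMDirection(d_in, hidden, rng)

    # Parameter/grad views are delegated so the optimizer sees flat dicts.
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, layer in (("f", self.fwd), ("b", self.bwd)):
            for k, v in layer.params.items():
                out[f"{tag}_{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, layer in (("f", self.fwd), ("b", self.bwd)):
            for k, v in layer.grads.items():
                out[f"{tag}_{k}"] = v
        return out

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        lengths = mask.sum(axis=1).astype(int)
        self._lengths = lengths
        hf = self.fwd.forward(x, mask)
        xr = reverse_padded(x, lengths)
        hb_r = self.bwd.forward(xr, mask)
        hb = reverse_padded(hb_r, lengths)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        H = self.hidden
        d_hf = d_out[:, :, :H]
        d_hb = d_out[:, :, H:]
        dx_f = self.fwd.backward(np.ascontiguousarray(d_hf))
        d_hb_r = reverse_padded(np.ascontiguousarray(d_hb), self._lengths)
        dx_b_r = self.bwd.backward(d_hb_r)
        dx_b = reverse_padded(dx_b_r, self._lengths)
        return dx_f + dx_b


class AttentionPooling(Layer):
    """Additive attention pooling: r = sum_t softmax_t(h_t . v) h_t."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["v"] = _uniform(rng, (dim,), np.sqrt(3.0 / dim))
        self.zero_grad()

    def forward(self, h: np.ndarray, mask: np.ndarray):
        v = self.params["v"]
        e = h @ v  # (B,T)
        e = np.where(mask > 0, e, -np.inf)
        e_max = e.max(axis=1, keepdims=True)
        ex = np.exp(e - e_max)
        ex = np.where(mask > 0, ex, 0.0)
        alpha = ex / ex.sum(axis=1, keepdims=True)
        r = np.einsum("bt,btd->bd", alpha, h)
        self._cache = (h, alpha)
        return r.astype(h.dtype), alpha

    def backward(self, d_r: np.ndarray) -> np.ndarray:
        h, alpha = self._cache
        v = self.params["v"]
        # r = sum_t alpha_t h_t ; alpha = softmax(e), e_t = h_t . v
        d_alpha = np.einsum("bd,btd->bt", d_r, h)
        dot = (alpha * d_alpha).sum(axis=1, keepdims=True)
        d_e = alpha * (d_alpha - dot)
        d_h = alpha[:, :, None] * d_r[:, None, :] + d_e[:, :, None] * v[None, None, :]
        self.grads["v"] += np.einsum("bt,btd->d", d_e, h)
        return d_h.astype(h.dtype)


class Dropout:
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None):
        if rng is None or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        return d_out * self._mask
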