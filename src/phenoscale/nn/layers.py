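"""Minimal dependency-free neural-network layers with explicit backprop.

Layout conventions: images are channels-last (N, H, W, C); sequences are
(N, T, C). Every layer exposes ``forward(x, train)`` and ``backward(dout)``
plus flat ``params`` / ``grads`` lists consumed by the optimizer. Weight
initialisation is He-scaled and driven by a caller-supplied generator, so a
network built from a seed is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        b = np.zeros(d_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=True):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.reshape(-1, w.shape[0]).T @ dout.reshape(
            -1, w.shape[1]
        )
        self.grads[1][...] = dout.reshape(-1, w.shape[1]).sum(axis=0)
        return dout @ w.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _im2col(xp, kh, kw, s):
    """View of all kh x kw patches of padded NHWC input, stride s."""
    n, h, w, c = xp.shape
    ho = (h - kh) // s + 1
    wo = (w - kw) // s + 1
    sn, sh, sw, sc = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, ho, wo, kh, kw, c),
        strides=(sn, sh * s, sw * s, sh, sw, sc),
        writeable=False,
    )
    return view, ho, wo


class Conv2D(Layer):
    """3x3-style convolution, NHWC, implemented by patch extraction."""

    def __init__(self, c_in, c_out, kernel, stride, rng, pad=None):
        super().__init__()
        self.k = kernel
        self.s = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp_shape = xp.shape
        view, ho, wo = _im2col(xp, self.k, self.k, self.s)
        w, b = self.params
        cols = view.reshape(-1, self.k * self.k * x.shape[-1])
        self._cols = cols
        out = cols @ w.reshape(-1, w.shape[-1]) + b
        return out.reshape(x.shape[0], ho, wo, -1)

    def backward(self, dout):
        w, _ = self.params
        n, ho, wo, co = dout.shape
        dflat = dout.reshape(-1, co)
        self.grads[0][...] = (self._cols.T @ dflat).reshape(w.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ w.reshape(-1, co).T).reshape(
            n, ho, wo, self.k, self.k, w.shape[2]
        )
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        s = self.s
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        p = self.pad
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class Conv1D(Layer):
    """Temporal convolution over (N, T, C)."""

    def __init__(self, c_in, c_out, kernel, stride, rng, pad=None):
        super().__init__()
        self.k = kernel
        self.s = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        w = rng.normal(0.0, np.sqrt(2.0 / (kernel * c_in)), size=(kernel, c_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (0, 0))) if p else x
        self._xp_shape = xp.shape
        n, t, c = xp.shape
        to = (t - self.k) // self.s + 1
        sn, st, sc = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, to, self.k, c),
            strides=(sn, st * self.s, st, sc),
            writeable=False,
        )
        cols = view.reshape(-1, self.k * c)
        self._cols = cols
        w, b = self.params
        out = cols @ w.reshape(-1, w.shape[-1]) + b
        return out.reshape(n, to, -1)

    def backward(self, dout):
        w, _ = self.params
        n, to, co = dout.shape
        dflat = dout.reshape(-1, co)
        self.grads[0][...] = (self._cols.T @ dflat).reshape(w.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ w.reshape(-1, co).T).reshape(n, to, self.k, w.shape[1])
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for i in range(self.k):
            dxp[:, i : i + to * self.s : self.s, :] += dcols[:, :, i, :]
        p = self.pad
        if p:
            return dxp[:, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Normalisation per channel (last axis) over batch and space/time."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        gamma, beta = self.params
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return gamma * self._xhat + beta

    def backward(self, dout):
        gamma, _ = self.params
        xhat, std, axes, m = self._xhat, self._std, self._axes, self._m
        self.grads[0][...] = (dout * xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * gamma
        if not self._train:
            return dxhat / std
        return (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) / std


class LayerNorm(Layer):
    """Normalisation over the last axis, per position."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]

    def forward(self, x, train=True):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, dout):
        gamma, _ = self.params
        xhat, std = self._xhat, self._std
        red = tuple(range(dout.ndim - 1))
        self.grads[0][...] = (dout * xhat).sum(axis=red)
        self.grads[1][...] = dout.sum(axis=red)
        dxhat = dout * gamma
        return (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) / std


class GlobalAvgPool(Layer):
    """Mean over all non-batch, non-channel axes: NHWC -> NC or NTC -> NC."""

    def forward(self, x, train=True):
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        self._n = int(np.prod([x.shape[a] for a in axes])) if axes else 1
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = self._shape
        expand = (shape[0],) + (1,) * (len(shape) - 2) + (shape[-1],)
        return np.broadcast_to(dout.reshape(expand), shape) / self._n


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class PositionalEncoding(Layer):
    """Adds fixed sinusoidal position features; parameter-free."""

    def __init__(self, t_max, channels):
        super().__init__()
        pos = np.arange(t_max)[:, None]
        i = np.arange(channels)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / channels)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.pe = pe

    def forward(self, x, train=True):
        return x + self.pe[: x.shape[1]]

    def backward(self, dout):
        return dout


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention with a residual
    connection: out = x + softmax(QK^T / sqrt(d)) V Wo."""

    def __init__(self, d, rng):
        super().__init__()
        scale = np.sqrt(1.0 / d)
        ws = [rng.normal(0.0, scale, size=(d, d)) for _ in range(4)]
        bs = [np.zeros(d) for _ in range(4)]
        self.params = ws + bs
        self.grads = [np.zeros_like(p) for p in self.params]
        self.d = d

    def forward(self, x, train=True):
        wq, wk, wv, wo = self.params[:4]
        bq, bk, bv, bo = self.params[4:]
        self._x = x
        q = x @ wq + bq
        k = x @ wk + bk
        v = x @ wv + bv
        s = np.einsum("ntd,nsd->nts", q, k) / np.sqrt(self.d)
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        o = np.einsum("nts,nsd->ntd", a, v)
        self._q, self._k, self._v, self._a, self._o = q, k, v, a, o
        return x + o @ wo + bo

    def backward(self, dout):
        wq, wk, wv, wo = self.params[:4]
        x, q, k, v, a, o = self._x, self._q, self._k, self._v, self._a, self._o
        d2 = dout.reshape(-1, self.d)
        self.grads[3][...] = o.reshape(-1, self.d).T @ d2  # dWo
        self.grads[7][...] = d2.sum(axis=0)  # dbo
        do = dout @ wo.T
        da = np.einsum("ntd,nsd->nts", do, v)
        dv = np.einsum("nts,ntd->nsd", a, do)
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.d)
        dq = np.einsum("nts,nsd->ntd", ds, k)
        dk = np.einsum("nts,ntd->nsd", ds, q)
        xf = x.reshape(-1, self.d)
        for idx, (dm, bidx) in enumerate(zip((dq, dk, dv), (4, 5, 6))):
            self.grads[idx][...] = xf.T @ dm.reshape(-1, self.d)
            self.grads[bidx][...] = dm.reshape(-1, self.d).sum(axis=0)
        dx = dout + dq @ wq.T + dk @ wk.T + dv @ wv.T
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, value):  # Layer.__init__ compatibility
        pass

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def astype(self, dtype):
        """Cast every parameter, gradient buffer and running statistic to
        ``dtype`` in place (e.g. float32 to halve CPU matmul time)."""
        for layer in self.layers:
            for i, p in enumerate(layer.params):
                layer.params[i] = p.astype(dtype)
            for i, g in enumerate(layer.grads):
                layer.grads[i] = g.astype(dtype)
            if isinstance(layer, BatchNorm):
                layer.running_mean = layer.running_mean.astype(dtype)
                layer.running_var = layer.running_var.astype(dtype)
        return self

    def get_state(self):
        """All weights and normalisation running statistics as a flat dict
        of arrays, suitable for ``np.savez``."""
        state = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                state[f"l{li}_p{pi}"] = p
            if isinstance(layer, BatchNorm):
                state[f"l{li}_rmean"] = layer.running_mean
                state[f"l{li}_rvar"] = layer.running_var
        return state

    def set_state(self, state):
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                p[...] = state[f"l{li}_p{pi}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"l{li}_rmean"])
                layer.running_var = np.asarray(state[f"l{li}_rvar"])
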