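"""Minimal neural-network engine on numpy arrays.

The models used here are small (a light-attention pooling block and an MLP
of a few thousand parameters), so the package ships its own compact layer
stack with hand-written reverse-mode gradients instead of depending on a
full deep-learning framework. Parameters live in flat ``dict[str, ndarray]``
containers so a single :class:`AdamW` instance can update a whole model;
every block exposes ``forward`` returning ``(output, cache)`` and
``backward`` consuming that cache plus the upstream gradient. All gradients
are checked against central finite differences in the test suite.

Conventions
-----------
* Batched per-residue inputs have shape ``(B, L, d)`` with a boolean padding
  mask of shape ``(B, L)``; ``True`` marks real residues.
* Dropout uses inverted scaling and is only applied when ``train=True`` and
  an ``rng`` is supplied, so inference is deterministic.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]
Grads = dict[str, np.ndarray]

__all__ = [
    "AdamW",
    "Dense",
    "DepthwiseConv1d",
    "LightAttentionRegressor",
    "PositionwiseEncoder",
    "clone_params",
]


def clone_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}


def _accum(grads: Grads, key: str, value: np.ndarray) -> None:
    if key in grads:
        grads[key] += value
    else:
        grads[key] = value


class Dense:
    """Affine map ``y = x @ W + b`` over the last axis."""

    def __init__(self, name: str, n_in: int, n_out: int):
        self.name = name
        self.n_in = n_in
        self.n_out = n_out

    def init(self, params: Params, rng: np.random.Generator) -> None:
        # He initialization; appropriate for the ReLU stacks used here.
        scale = np.sqrt(2.0 / self.n_in)
        params[self.name + ".w"] = rng.normal(0.0, scale, (self.n_in, self.n_out))
        params[self.name + ".b"] = np.zeros(self.n_out)

    def forward(self, params: Params, x: np.ndarray):
        y = x @ params[self.name + ".w"] + params[self.name + ".b"]
        return y, x

    def backward(self, params: Params, grads: Grads, cache, dout: np.ndarray):
        x = cache
        x2 = x.reshape(-1, self.n_in)
        d2 = dout.reshape(-1, self.n_out)
        _accum(grads, self.name + ".w", x2.T @ d2)
        _accum(grads, self.name + ".b", d2.sum(axis=0))
        return dout @ params[self.name + ".w"].T


class DepthwiseConv1d:
    """Per-feature 1-D convolution over the length axis, same padding.

    Each of the ``dim`` features is convolved with its own length-``kernel``
    filter; padded/masked positions contribute zeros.
    """

    def __init__(self, name: str, dim: int, kernel: int):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
        self.name = name
        self.dim = dim
        self.kernel = kernel
        self.pad = kernel // 2

    def init(self, params: Params, rng: np.random.Generator) -> None:
        scale = np.sqrt(1.0 / self.kernel)
        params[self.name + ".w"] = rng.normal(0.0, scale, (self.kernel, self.dim))
        params[self.name + ".b"] = np.zeros(self.dim)

    def forward(self, params: Params, x: np.ndarray, mask: np.ndarray):
        w = params[self.name + ".w"]
        b = params[self.name + ".b"]
        B, L, d = x.shape
        xm = np.where(mask[..., None], x, 0.0)
        xp = np.zeros((B, L + 2 * self.pad, d))
        xp[:, self.pad : self.pad + L, :] = xm
        out = np.empty((B, L, d))
        out[:] = b
        for t in range(self.kernel):
            out += xp[:, t : t + L, :] * w[t]
        return out, (xp, mask)

    def backward(self, params: Params, grads: Grads, cache, dout: np.ndarray):
        xp, mask = cache
        w = params[self.name + ".w"]
        B, L, d = dout.shape
        dw = np.empty((self.kernel, self.dim))
        for t in range(self.kernel):
            dw[t] = np.einsum("bld,bld->d", xp[:, t : t + L, :], dout)
        _accum(grads, self.name + ".w", dw)
        _accum(grads, self.name + ".b", dout.sum(axis=(0, 1)))
        dxp = np.zeros_like(xp)
        for t in range(self.kernel):
            dxp[:, t : t + L, :] += dout * w[t]
        dx = dxp[:, self.pad : self.pad + L, :]
        return np.where(mask[..., None], dx, 0.0)


def _masked_softmax_over_length(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of ``(B, L, d)`` logits, zero weight off-mask."""
    neg = np.where(mask[..., None], a, -np.inf)
    m = neg.max(axis=1, keepdims=True)
    e = np.exp(neg - m)
    e = np.where(mask[..., None], e, 0.0)
    return e / e.sum(axis=1, keepdims=True)


class LightAttentionRegressor:
    """Light-attention pooling over residues followed by an MLP head.

    Two depthwise 1-D convolutions produce attention logits ``A`` and values
    ``V``; per feature, a softmax of ``A`` over sequence length weights the
    values, and the weighted sum is concatenated with a max-pool of ``V``,
    giving a fixed-size ``2 d`` representation regardless of length. The MLP
    head then maps this to ``n_out`` outputs through ReLU hidden layers
    (sizes ``hidden``) and a linear output. ``pooling='mean'`` replaces the
    attention block with a plain masked average (size ``d``), the variant
    used by fine-tuning protocols.
    """

    def __init__(
        self,
        d_in: int,
        n_out: int,
        hidden: tuple[int, ...] = (128, 64),
        kernel_size: int = 9,
        dropout: float = 0.25,
        pooling: str = "light_attention",
    ):
        if pooling not in ("light_attention", "mean"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.d_in = d_in
        self.n_out = n_out
        self.hidden = tuple(hidden)
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.pooling = pooling
        if pooling == "light_attention":
            self.conv_a = DepthwiseConv1d("conv_a", d_in, kernel_size)
            self.conv_v = DepthwiseConv1d("conv_v", d_in, kernel_size)
            pooled_dim = 2 * d_in
        else:
            pooled_dim = d_in
        self.pooled_dim = pooled_dim
        self.mlp: list[Dense] = []
        prev = pooled_dim
        for i, h in enumerate(self.hidden):
            self.mlp.append(Dense(f"mlp{i}", prev, h))
            prev = h
        self.mlp.append(Dense("out", prev, n_out))

    def init_params(self, rng: np.random.Generator) -> Params:
        params: Params = {}
        if self.pooling == "light_attention":
            self.conv_a.init(params, rng)
            self.conv_v.init(params, rng)
        for layer in self.mlp:
            layer.init(params, rng)
        return params

    def config(self) -> dict:
        return {
            "d_in": self.d_in,
            "n_out": self.n_out,
            "hidden": list(self.hidden),
            "kernel_size": self.kernel_size,
            "dropout": self.dropout,
            "pooling": self.pooling,
        }

    # -- pooling ---------------------------------------------------------
    def pool(self, params: Params, x: np.ndarray, mask: np.ndarray):
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in embedding input")
        if x.shape[1] == 0 or not mask.any(axis=1).all():
            raise ValueError("every sequence must have at least one residue")
        if self.pooling == "mean":
            n = mask.sum(axis=1, keepdims=True)
            pooled = np.where(mask[..., None], x, 0.0).sum(axis=1) / n
            return pooled, ("mean", mask, n)
        a, cache_a = self.conv_a.forward(params, x, mask)
        v, cache_v = self.conv_v.forward(params, x, mask)
        att = _masked_softmax_over_length(a, mask)
        ws = (att * v).sum(axis=1)
        vneg = np.where(mask[..., None], v, -np.inf)
        argmx = vneg.argmax(axis=1)
        mx = np.take_along_axis(vneg, argmx[:, None, :], axis=1)[:, 0, :]
        pooled = np.concatenate([ws, mx], axis=1)
        return pooled, ("la", cache_a, cache_v, att, v, argmx, mask)

    def pool_backward(self, params: Params, grads: Grads, cache, dpooled: np.ndarray):
        if cache[0] == "mean":
            _, mask, n = cache
            dx = (dpooled[:, None, :] / n[..., None]) * mask[..., None]
            return dx
        _, cache_a, cache_v, att, v, argmx, mask = cache
        d = self.d_in
        dws = dpooled[:, :d]
        dmx = dpooled[:, d:]
        dv = att * dws[:, None, :]
        np.put_along_axis(
            dv, argmx[:, None, :], np.take_along_axis(dv, argmx[:, None, :], axis=1) + dmx[:, None, :], axis=1
        )
        datt = v * dws[:, None, :]
        # softmax backward over the length axis, independently per feature
        da = att * (datt - (att * datt).sum(axis=1, keepdims=True))
        dx_a = self.conv_a.backward(params, grads, cache_a, da)
        dx_v = self.conv_v.backward(params, grads, cache_v, dv)
        return dx_a + dx_v

    # -- full model ------------------------------------------------------
    def forward(
        self,
        params: Params,
        x: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        pooled, pool_cache = self.pool(params, x, mask)
        h = pooled
        drop_mask = None
        if train and self.dropout > 0.0 and rng is not None:
            drop_mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * drop_mask
        caches = []
        for layer in self.mlp[:-1]:
            z, c = layer.forward(params, h)
            h = np.maximum(z, 0.0)
            caches.append((c, z))
        y, c_out = self.mlp[-1].forward(params, h)
        return y, (pool_cache, drop_mask, caches, c_out)

    def backward(self, params: Params, cache, dy: np.ndarray) -> Grads:
        pool_cache, drop_mask, caches, c_out = cache
        grads: Grads = {}
        dh = self.mlp[-1].backward(params, grads, c_out, dy)
        for layer, (c, z) in zip(reversed(self.mlp[:-1]), reversed(caches)):
            dh = layer.backward(params, grads, c, dh * (z > 0.0))
        if drop_mask is not None:
            dh = dh * drop_mask
        self.pool_backward(params, grads, pool_cache, dh)
        return grads


class PositionwiseEncoder:
    """Residue-wise MLP ``d -> hidden -> e`` shared across positions.

    Used as the contrastive encoder: it transforms per-residue embeddings
    without mixing positions, and its masked length-mean provides the
    fixed-size vector the contrastive similarity is computed on.
    """

    def __init__(self, d_in: int, hidden: int = 64, d_out: int = 32):
        self.d_in = d_in
        self.hidden = hidden
        self.d_out = d_out
        self.fc1 = Dense("enc1", d_in, hidden)
        self.fc2 = Dense("enc2", hidden, d_out)

    def init_params(self, rng: np.random.Generator) -> Params:
        params: Params = {}
        self.fc1.init(params, rng)
        self.fc2.init(params, rng)
        return params

    def config(self) -> dict:
        return {"d_in": self.d_in, "hidden": self.hidden, "d_out": self.d_out}

    def forward(self, params: Params, x: np.ndarray):
        z, c1 = self.fc1.forward(params, x)
        h = np.maximum(z, 0.0)
        y, c2 = self.fc2.forward(params, h)
        return y, (c1, z, c2)

    def backward(self, params: Params, cache, dy: np.ndarray) -> Grads:
        c1, z, c2 = cache
        grads: Grads = {}
        dh = self.fc2.backward(params, grads, c2, dy)
        self.fc1.backward(params, grads, c1, dh * (z > 0.0))
        return grads

    def mean_representation(self, params: Params, x: np.ndarray, mask: np.ndarray):
        y, cache = self.forward(params, x)
        n = mask.sum(axis=1, keepdims=True)
        rep = np.where(mask[..., None], y, 0.0).sum(axis=1) / n
        return rep, (cache, mask, n)

    def mean_representation_backward(self, params: Params, cache, drep: np.ndarray) -> Grads:
        enc_cache, mask, n = cache
        dy = (drep[:, None, :] / n[..., None]) * mask[..., None]
        return self.backward(params, enc_cache, dy)


class AdamW:
    """Adam with decoupled weight decay.

    Biases (parameter names ending in ``.b``) are exempt from decay, the
    usual convention.
    """

    def __init__(
        self,
        params: Params,
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            if self.weight_decay and not k.endswith(".b"):
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
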