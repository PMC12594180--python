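"""Prediction architecture: light-attention pooling, MLP head, dual output.

The regression model consumes a frozen per-residue embedding matrix
``L × d``, pools it to a fixed-size vector with light attention (two
depthwise 1-D convolutions producing attention logits and values; softmax
over length per feature; weighted sum concatenated with a max-pool), and
maps the pooled vector through an MLP with hidden layers (128, 64) to ``n``
outputs: ``n = 1`` for plain Tm regression, ``n = 2`` for the dual head
whose outputs are a species-level estimate and a per-protein offset with
``phi_tm = y_ogt + y_bias``.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass

import numpy as np

from .nn import LightAttentionRegressor, Params, PositionwiseEncoder

__all__ = [
    "DualPrediction",
    "light_attention_pool",
    "mlp_predict",
    "combine_dual",
    "concat_embeddings",
    "build_regressor",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DualPrediction:
    """Two-component prediction: species-level estimate plus protein offset."""

    y_ogt: float
    y_bias: float

    @property
    def phi_tm(self) -> float:
        return self.y_ogt + self.y_bias


def combine_dual(outputs: np.ndarray) -> DualPrediction:
    """Combine the dual head's two outputs; the predicted Tm is their sum."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (2,):
        raise ValueError(f"dual head must produce exactly 2 outputs, got shape {outputs.shape}")
    return DualPrediction(y_ogt=float(outputs[0]), y_bias=float(outputs[1]))


def concat_embeddings(seq_emb: np.ndarray, struct_emb: np.ndarray) -> np.ndarray:
    """Residue-wise concatenation, sequence features first."""
    seq_emb = np.asarray(seq_emb)
    struct_emb = np.asarray(struct_emb)
    if seq_emb.shape[0] != struct_emb.shape[0]:
        raise ValueError(
            f"length mismatch: sequence embedding has {seq_emb.shape[0]} residues, "
            f"structure embedding has {struct_emb.shape[0]}"
        )
    return np.concatenate([seq_emb, struct_emb], axis=1)


def build_regressor(
    d_in: int,
    n_out: int = 1,
    hidden: tuple[int, ...] = (128, 64),
    kernel_size: int = 9,
    dropout: float = 0.25,
    pooling: str = "light_attention",
) -> LightAttentionRegressor:
    return LightAttentionRegressor(
        d_in, n_out, hidden=hidden, kernel_size=kernel_size, dropout=dropout, pooling=pooling
    )


def light_attention_pool(embedding: np.ndarray, params: Params, kernel_size: int = 9) -> np.ndarray:
    """Pool one ``L × d`` embedding to the fixed-size ``2 d`` vector.

    ``params`` holds the two convolution kernels (``conv_a.*`` for attention
    logits, ``conv_v.*`` for values). Output is the softmax-weighted sum of
    values concatenated with their max over length; its size never depends
    on ``L``.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[0] < 1:
        raise ValueError("embedding must be a non-empty L x d matrix")
    d = embedding.shape[1]
    model = build_regressor(d, 1, kernel_size=kernel_size, dropout=0.0)
    x = embedding[None, :, :]
    mask = np.ones((1, embedding.shape[0]), dtype=bool)
    pooled, _ = model.pool(params, x, mask)
    return pooled[0]


def mlp_predict(rep: np.ndarray, params: Params, hidden: tuple[int, ...] = (128, 64), n_out: int = 1) -> np.ndarray:
    """Forward the pooled representation through the (128, 64, n) MLP head."""
    rep = np.asarray(rep, dtype=float)
    squeeze = rep.ndim == 1
    h = rep[None, :] if squeeze else rep
    model = LightAttentionRegressor(1, n_out, hidden=hidden, dropout=0.0)
    # reuse the head layers only; pooled width is taken from the input
    model.mlp[0].n_in = h.shape[1]
    first_w = params[model.mlp[0].name + ".w"]
    if first_w.shape[0] != h.shape[1]:
        raise ValueError(
            f"representation width {h.shape[1]} does not match head input {first_w.shape[0]}"
        )
    for layer in model.mlp[:-1]:
        z, _ = layer.forward(params, h)
        h = np.maximum(z, 0.0)
    y, _ = model.mlp[-1].forward(params, h)
    return y[0] if squeeze else y


def save_checkpoint(path: str | os.PathLike, model, params: Params, kind: str = "regressor") -> None:
    """Serialize parameters together with the model config so a loaded
    checkpoint can verify compatibility with the data it is applied to."""
    meta = json.dumps({"kind": kind, "config": model.config()})
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **params)
    tmp = str(path) + ".tmp"
    with open(tmp, "wb") as fh:
        fh.write(buf.getvalue())
    os.replace(tmp, path)


def load_checkpoint(path: str | os.PathLike):
    """Load a checkpoint; returns ``(model, params)``."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = meta["config"]
    if meta["kind"] == "regressor":
        model = LightAttentionRegressor(
            cfg["d_in"],
            cfg["n_out"],
            hidden=tuple(cfg["hidden"]),
            kernel_size=cfg["kernel_size"],
            dropout=cfg["dropout"],
            pooling=cfg["pooling"],
        )
    elif meta["kind"] == "encoder":
        model = PositionwiseEncoder(cfg["d_in"], cfg["hidden"], cfg["d_out"])
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    return model, params
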