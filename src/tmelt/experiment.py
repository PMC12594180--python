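"""Scenario orchestration: approaches x training regimes.

Approaches
    baseline  light-attention pooling + MLP on the given embeddings, MSE.
    concat    same model on residue-wise concatenated sequence+structure
              embeddings.
    rnc       two-stage: a contrastive (Rank-N-Contrast) residue-wise
              encoder is learned first and frozen; the standard pooling+MLP
              predictor is then trained on its outputs.
    dual      two-output head (species-level estimate + protein offset)
              trained with the OGT-anchored dual loss.

Regimes
    G   one model trained on all species pooled (cross-species),
    S   one independent model per species,
    GB  as G but with species-balanced sampling (inverse-frequency weights,
        resampling with replacement each epoch).

Optimization uses AdamW with the regime-dependent default learning rates
(G/GB 1e-4, S 1e-3; contrastive encoder 1e-5 with predictor 1e-4 for G and
1e-3 for S) and early stopping on validation RMSE. Species means used as
anchors are always computed on the training split only; test and validation
labels never influence parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MeltomeDataset, concat_datasets, species_partition
from .model import build_regressor
from .nn import AdamW, clone_params
from .objectives import SpeciesAnchor, train_rnc_representation

logger = logging.getLogger(__name__)

APPROACHES = ("baseline", "concat", "rnc", "dual")
REGIMES = ("G", "S", "GB")

__all__ = [
    "APPROACHES",
    "REGIMES",
    "ScenarioSpec",
    "PredictionRecord",
    "train_scenario",
    "balanced_batch_weights",
    "mean_predictor",
    "records_to_frame",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the approach x regime grid, with its training protocol."""

    approach: str = "baseline"
    regime: str = "G"
    lr: float | None = None  # default: 1e-4 for G/GB, 1e-3 for S
    lr_encoder: float = 1e-5
    lr_predictor: float | None = None  # rnc predictor: 1e-4 for G/GB, 1e-3 for S
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    encoder_epochs: int | None = None
    hidden: tuple[int, ...] = (128, 64)
    encoder_dims: tuple[int, int] = (64, 32)
    kernel_size: int = 9
    dropout: float = 0.25
    tau: float = 2.0
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        for name in ("lr", "lr_predictor"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr_encoder <= 0:
            raise ValueError("lr_encoder must be positive")

    def resolved_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        return 1e-3 if self.regime == "S" else 1e-4

    def resolved_lr_predictor(self) -> float:
        if self.lr_predictor is not None:
            return self.lr_predictor
        return 1e-3 if self.regime == "S" else 1e-4


@dataclass(frozen=True)
class PredictionRecord:
    protein_id: str
    species: str
    split: str
    y_true: float
    y_pred: float
    approach: str
    regime: str
    model_tag: str = ""


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.protein_id, r.species, r.split, r.y_true, r.y_pred, r.approach, r.regime, r.model_tag)
            for r in records
        ],
        columns=["protein_id", "species", "split", "y_true", "y_pred", "approach", "regime", "model_tag"],
    )


def balanced_batch_weights(ds: MeltomeDataset) -> np.ndarray:
    """Per-train-sample sampling weights proportional to 1/n_species."""
    train = ds.split_proteins("train")
    if not train:
        raise ValueError("train split is empty")
    counts: dict[str, int] = {}
    for p in train:
        counts[p.species] = counts.get(p.species, 0) + 1
    w = np.array([1.0 / counts[p.species] for p in train])
    return w / w.sum()


def mean_predictor(ds: MeltomeDataset, scope: str) -> list[PredictionRecord]:
    """The mean-Tm reference: predict the train-set mean (per species or
    overall) for every test protein."""
    train = ds.split_proteins("train")
    test = ds.split_proteins("test")
    if not train:
        raise ValueError("train split is empty")
    if scope == "global":
        mu = float(np.mean([p.tm for p in train]))
        preds = {p.protein_id: mu for p in test}
        regime = "G"
    elif scope == "per_species":
        anchor = SpeciesAnchor.from_training(ds)
        preds = {}
        for p in test:
            if p.species not in anchor.mu_tm:
                raise ValueError(f"species {p.species!r} has no training data for the mean predictor")
            preds[p.protein_id] = anchor[p.species]
        regime = "S"
    else:
        raise ValueError(f"scope must be 'global' or 'per_species', got {scope!r}")
    return [
        PredictionRecord(
            protein_id=p.protein_id,
            species=p.species,
            split=p.split,
            y_true=p.tm,
            y_pred=preds[p.protein_id],
            approach="mean",
            regime=regime,
            model_tag=f"mean_{scope}",
        )
        for p in test
    ]


def _pad(proteins, embeddings):
    d = embeddings[0].shape[1]
    lmax = max(e.shape[0] for e in embeddings)
    x = np.zeros((len(proteins), lmax, d))
    mask = np.zeros((len(proteins), lmax), dtype=bool)
    for a, e in enumerate(embeddings):
        x[a, : e.shape[0]] = e
        mask[a, : e.shape[0]] = True
    return x, mask


def _predict(model, params, proteins, embeddings, batch_size=128) -> np.ndarray:
    out = []
    for lo in range(0, len(proteins), batch_size):
        chunk = proteins[lo : lo + batch_size]
        x, mask = _pad(chunk, embeddings[lo : lo + batch_size])
        y, _ = model.forward(params, x, mask, train=False)
        out.append(y)
    y = np.concatenate(out, axis=0)
    return y.sum(axis=1) if y.shape[1] == 2 else y[:, 0]


def _train_supervised(
    proteins: list,
    embeddings: list[np.ndarray],
    val_proteins: list,
    val_embeddings: list[np.ndarray],
    spec: ScenarioSpec,
    lr: float,
    dual: bool,
    anchor: SpeciesAnchor | None,
    sample_weights: np.ndarray | None,
    seed_seq: np.random.SeedSequence,
):
    """Shared AdamW loop with early stopping on validation RMSE (training
    RMSE when the validation set is too small to be trusted, n < 5).

    Targets are z-scored on the training split (the model regresses
    standardized Tm and predictions are mapped back to °C), so the stated
    learning rates behave the same across pooled and per-species target
    scales. Anchors are transformed with the same affine map, which leaves
    the dual decomposition intact."""
    d = embeddings[0].shape[1]
    n_out = 2 if dual else 1
    model = build_regressor(d, n_out, hidden=spec.hidden, kernel_size=spec.kernel_size, dropout=spec.dropout)
    rng_init, rng_batch, rng_drop = (np.random.default_rng(s) for s in seed_seq.spawn(3))
    params = model.init_params(rng_init)
    opt = AdamW(params, lr=lr, weight_decay=spec.weight_decay)
    y_raw = np.array([p.tm for p in proteins])
    y_loc = float(y_raw.mean())
    y_scale = float(y_raw.std()) or 1.0
    y_train = (y_raw - y_loc) / y_scale
    mu_train = (
        (np.array([anchor[p.species] for p in proteins]) - y_loc) / y_scale if dual else None
    )

    use_val = len(val_proteins) >= 5
    if not use_val:
        logger.warning(
            "validation split has %d samples (< 5); early stopping falls back to training RMSE",
            len(val_proteins),
        )

    def monitor_rmse() -> float:
        if use_val:
            yhat = _predict(model, params, val_proteins, val_embeddings)
            yv = np.array([p.tm for p in val_proteins])
        else:
            yhat = _predict(model, params, proteins, embeddings)
            yv = y_raw
        return float(np.sqrt(np.mean((y_loc + y_scale * yhat - yv) ** 2)))

    n = len(proteins)
    bs = max(2, min(spec.batch_size, n))
    best = np.inf
    best_params = clone_params(params)
    bad = 0
    history: list[float] = []
    for _epoch in range(spec.max_epochs):
        if sample_weights is not None:
            order = rng_batch.choice(n, size=n, replace=True, p=sample_weights)
        else:
            order = rng_batch.permutation(n)
        for lo in range(0, n, bs):
            sel = order[lo : lo + bs]
            if len(sel) < 2:
                continue
            chunk = [proteins[k] for k in sel]
            x, mask = _pad(chunk, [embeddings[k] for k in sel])
            pred, cache = model.forward(params, x, mask, train=True, rng=rng_drop)
            b = len(sel)
            if dual:
                phi = pred[:, 0] + pred[:, 1]
                resid = phi - y_train[sel]
                resid_s = pred[:, 0] - mu_train[sel]
                dy = np.empty_like(pred)
                dy[:, 0] = 2.0 * (resid + resid_s) / b
                dy[:, 1] = 2.0 * resid / b
            else:
                dy = 2.0 * (pred[:, 0] - y_train[sel])[:, None] / b
            grads = model.backward(params, cache, dy)
            opt.step(grads)
        m = monitor_rmse()
        history.append(m)
        if m < best - 1e-9:
            best, best_params, bad = m, clone_params(params), 0
        else:
            bad += 1
            if bad >= spec.patience:
                break
    return model, best_params, history, (y_loc, y_scale)


def _encode_all(encoder, enc_params, proteins) -> list[np.ndarray]:
    out = []
    for p in proteins:
        y, _ = encoder.forward(enc_params, p.embedding[None, :, :].astype(float))
        out.append(y[0])
    return out


def _run_one_model(ds: MeltomeDataset, spec: ScenarioSpec, seed_seq, tag: str) -> list[PredictionRecord]:
    train = ds.split_proteins("train")
    val = ds.split_proteins("val")
    test = ds.split_proteins("test")
    anchor = SpeciesAnchor.from_training(ds) if spec.approach == "dual" else None
    weights = balanced_batch_weights(ds) if spec.regime == "GB" else None

    if spec.approach == "rnc":
        enc_seed = np.random.default_rng(seed_seq.spawn(1)[0]).integers(0, 2**31 - 1)
        encoder, enc_params, _ = train_rnc_representation(
            ds,
            encoder_dims=spec.encoder_dims,
            lr=spec.lr_encoder,
            batch_size=min(32, max(2, len(train))),
            max_epochs=spec.encoder_epochs if spec.encoder_epochs is not None else spec.max_epochs,
            patience=spec.patience,
            tau=spec.tau,
            weight_decay=spec.weight_decay,
            seed=int(enc_seed),
        )
        emb_train = _encode_all(encoder, enc_params, train)
        emb_val = _encode_all(encoder, enc_params, val)
        emb_test = _encode_all(encoder, enc_params, test)
        lr = spec.resolved_lr_predictor()
    else:
        emb_train = [p.embedding.astype(float) for p in train]
        emb_val = [p.embedding.astype(float) for p in val]
        emb_test = [p.embedding.astype(float) for p in test]
        lr = spec.resolved_lr()

    model, params, _, (y_loc, y_scale) = _train_supervised(
        train, emb_train, val, emb_val, spec, lr, spec.approach == "dual", anchor, weights, seed_seq.spawn(1)[0]
    )
    if not test:
        return []
    yhat = y_loc + y_scale * _predict(model, params, test, emb_test)
    return [
        PredictionRecord(
            protein_id=p.protein_id,
            species=p.species,
            split=p.split,
            y_true=p.tm,
            y_pred=float(yhat[a]),
            approach=spec.approach,
            regime=spec.regime,
            model_tag=tag,
        )
        for a, p in enumerate(test)
    ]


def train_scenario(
    ds: MeltomeDataset, spec: ScenarioSpec, struct_ds: MeltomeDataset | None = None
) -> list[PredictionRecord]:
    """Train one (approach, regime) scenario and return test-split predictions.

    Regime S trains one independent model per species and concatenates the
    records; species without any validation data are skipped with a logged
    warning (tiny species exist in real meltome splits).
    """
    if spec.approach == "concat":
        if struct_ds is None:
            raise ValueError("approach 'concat' needs a structure-embedding dataset")
        ds = concat_datasets(ds, struct_ds)
    if not ds.split_proteins("train"):
        raise ValueError("train split is empty")

    root = np.random.SeedSequence(spec.seed)
    if spec.regime in ("G", "GB"):
        return _run_one_model(ds, spec, root, tag=f"{spec.approach}_{spec.regime}")

    records: list[PredictionRecord] = []
    parts = species_partition(ds)
    # a single-species dataset degenerates to the global regime (same seeds)
    children = [root] if len(parts) == 1 else root.spawn(len(parts))
    for child, (sp, sub) in zip(children, parts.items()):
        n_train = len(sub.split_proteins("train"))
        n_val = len(sub.split_proteins("val"))
        if n_train < 2:
            logger.warning("species %s skipped: only %d training samples", sp, n_train)
            continue
        if n_val == 0:
            logger.warning("species %s skipped: no validation data", sp)
            continue
        records.extend(_run_one_model(sub, spec, child, tag=f"{spec.approach}_S_{sp}"))
    return records
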