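"""Training objectives: MSE, the OGT-anchored dual loss, and Rank-N-Contrast.

Dual loss. The dual head predicts a species-level component ``y_ogt``
(anchored to the species' mean train-set Tm ``mu_tm``, the proxy for its
optimal growth temperature) and a per-protein offset ``y_bias``; the
predicted melting temperature is ``phi_tm = y_ogt + y_bias`` and

    loss = MSE(phi_tm, y_tm) + MSE(y_ogt, mu_tm).

Rank-N-Contrast. Given a two-view batch of ``2N`` fixed-size
representations ``v_i`` with labels ``y_i`` (each augmented view keeps its
source's label), the per-sample loss contrasts every other sample ``j``
against the set ``S_ij = {k != i : |y_i - y_k| >= |y_i - y_j|}`` of samples
ranked at least as far from the anchor in label space:

    l_i = 1/(2N-1) * sum_{j != i} -log[ exp(sim(v_i, v_j)/tau)
                                        / sum_{k in S_ij} exp(sim(v_i, v_k)/tau) ],

averaged over the batch. Since ``j`` belongs to its own ``S_ij``, every term
is the negative log of a probability and the loss is finite and
non-negative. Similarity defaults to negative Euclidean distance with
``tau = 2``.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import MeltomeDataset
from .model import DualPrediction
from .nn import AdamW, PositionwiseEncoder, clone_params

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastiveBatch",
    "SpeciesAnchor",
    "mse_loss",
    "dual_loss",
    "gaussian_augment",
    "rank_set",
    "rnc_loss",
    "rnc_loss_and_grad",
    "train_rnc_representation",
]


@dataclass(frozen=True)
class ContrastiveBatch:
    """A two-view batch: 2N representations, labels, and temperature tau.

    The first N entries are the original views and the last N their
    augmented counterparts, so ``labels[:N] == labels[N:]``.
    """

    representations: np.ndarray  # (2N, e)
    labels: np.ndarray  # (2N,)
    tau: float = 2.0

    def __post_init__(self):
        reps = np.asarray(self.representations, dtype=float)
        labels = np.asarray(self.labels, dtype=float)
        if reps.ndim != 2 or reps.shape[0] != labels.shape[0]:
            raise ValueError("representations must be (2N, e) matching labels")
        if reps.shape[0] % 2 or reps.shape[0] < 2:
            raise ValueError("a two-view batch has an even number >= 2 of entries")
        n = reps.shape[0] // 2
        if not np.array_equal(labels[:n], labels[n:]):
            raise ValueError("augmented views must carry their source's label")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "representations", reps)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.representations.shape[0] // 2


@dataclass(frozen=True)
class SpeciesAnchor:
    """Per-species mean train-set Tm, the OGT proxy of the dual loss."""

    mu_tm: dict[str, float]

    @classmethod
    def from_training(cls, ds: MeltomeDataset) -> "SpeciesAnchor":
        sums: dict[str, list[float]] = {}
        for p in ds.proteins:
            if p.split == "train":
                sums.setdefault(p.species, []).append(p.tm)
        return cls(mu_tm={sp: float(np.mean(v)) for sp, v in sums.items()})

    def __getitem__(self, species: str) -> float:
        if species not in self.mu_tm:
            raise KeyError(f"no training-set Tm anchor for species {species!r}")
        return self.mu_tm[species]


def mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be non-empty and of equal length")
    return float(np.mean((pred - truth) ** 2))


def dual_loss(
    preds: Sequence[DualPrediction],
    y_tm: np.ndarray,
    species: Sequence[str],
    anchor: SpeciesAnchor,
) -> float:
    """Batch dual loss: MSE(phi_tm, y_tm) + MSE(y_ogt, mu_tm)."""
    y_tm = np.asarray(y_tm, dtype=float)
    if not (len(preds) == len(y_tm) == len(species)) or len(preds) == 0:
        raise ValueError("preds, y_tm and species must be non-empty and of equal length")
    mu = np.array([anchor[sp] for sp in species])
    phi = np.array([p.phi_tm for p in preds])
    ogt = np.array([p.y_ogt for p in preds])
    return mse_loss(phi, y_tm) + mse_loss(ogt, mu)


def gaussian_augment(
    embedding: np.ndarray, sigma_aug: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. Gaussian noise per entry in embedding space (label unchanged).

    ``sigma_aug`` may be a scalar or a per-feature vector.
    """
    sigma = np.asarray(sigma_aug, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma_aug must be >= 0")
    return embedding + sigma * rng.standard_normal(embedding.shape)


def rank_set(i: int, j: int, labels: np.ndarray) -> np.ndarray:
    """Indices ``k != i`` whose label distance to the anchor ``i`` is at least
    that of ``j`` (ties included); always contains ``j``."""
    if i == j:
        raise ValueError("anchor and candidate must differ")
    labels = np.asarray(labels, dtype=float)
    d = np.abs(labels - labels[i])
    keep = (d >= d[j]) & (np.arange(len(labels)) != i)
    return np.flatnonzero(keep)


def _pairwise_sim(reps: np.ndarray, sim: Callable[[np.ndarray, np.ndarray], float] | None) -> np.ndarray:
    if sim is None:
        d = squareform(pdist(reps))
        return -d
    m = len(reps)
    s = np.empty((m, m))
    for a in range(m):
        for b in range(m):
            s[a, b] = sim(reps[a], reps[b])
    return s


def rnc_loss(batch: ContrastiveBatch, sim: Callable[[np.ndarray, np.ndarray], float] | None = None) -> float:
    """The Rank-N-Contrast loss of a two-view batch (mean over samples)."""
    reps = batch.representations
    if not np.all(np.isfinite(reps)):
        raise ValueError("non-finite representations")
    s_mat = _pairwise_sim(reps, sim) / batch.tau
    loss, _ = _rnc_from_sim(s_mat, batch.labels)
    return loss


def _rnc_from_sim(s: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the (already tau-scaled) similarity matrix."""
    m = len(labels)
    d_lab = np.abs(labels[None, :] - labels[:, None])
    loss = 0.0
    grad = np.zeros((m, m))
    idx = np.arange(m)
    for i in range(m):
        rows = idx != i
        # mask[j, k]: k belongs to S_ij
        mask = (d_lab[i][None, :] >= d_lab[i][:, None]) & (idx != i)[None, :]
        sm = np.where(mask, s[i][None, :], -np.inf)
        mmax = sm.max(axis=1)
        e = np.exp(sm - mmax[:, None])
        z = e.sum(axis=1)
        lse = mmax + np.log(z)
        terms = -s[i] + lse
        loss += terms[rows].sum() / (m - 1)
        w = e / z[:, None]  # softmax over k in S_ij, per j
        g = w[rows].sum(axis=0)
        g[rows] -= 1.0
        grad[i] = g / (m - 1)
    loss /= m
    grad /= m
    return float(loss), grad


def rnc_loss_and_grad(
    reps: np.ndarray, labels: np.ndarray, tau: float = 2.0
) -> tuple[float, np.ndarray]:
    """Loss plus gradient w.r.t. the representations, for the default
    negative-Euclidean similarity (used by the encoder training loop)."""
    reps = np.asarray(reps, dtype=float)
    if not np.all(np.isfinite(reps)):
        raise ValueError("non-finite representations")
    diff = reps[:, None, :] - reps[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    loss, g_s = _rnc_from_sim(-dist / tau, np.asarray(labels, dtype=float))
    g_s = (g_s + g_s.T) / tau  # each unordered pair appears at (i,j) and (j,i)
    safe = np.where(dist > 1e-12, dist, 1.0)
    unit = diff / safe[:, :, None]
    # d s_ij / d v_i = -(v_i - v_j) / (tau * dist), hence the minus sign
    dv = -(g_s[:, :, None] * unit).sum(axis=1)
    return loss, dv


def train_rnc_representation(
    ds: MeltomeDataset,
    encoder_dims: tuple[int, int] = (64, 32),
    lr: float = 1e-5,
    batch_size: int = 32,
    max_epochs: int = 200,
    patience: int = 20,
    tau: float = 2.0,
    sigma_aug: np.ndarray | float | None = None,
    weight_decay: float = 0.01,
    seed: int = 0,
) -> tuple[PositionwiseEncoder, dict, list[float]]:
    """Learn a frozen contrastive encoder on the train split.

    The encoder is a residue-wise MLP; the contrastive similarity is
    computed on the masked length-mean of its outputs. Each batch pairs N
    proteins with Gaussian-perturbed views of themselves (default
    perturbation: 0.1 x per-feature train SD). Early stopping monitors the
    single-view contrastive objective on the validation split (train split
    when no validation data exists). Returns the encoder, its best
    parameters, and the per-epoch monitored losses.
    """
    train = ds.split_proteins("train")
    if not train:
        raise ValueError("train split is empty")
    val = ds.split_proteins("val")
    monitor = val if len(val) >= 2 else train
    d = train[0].dim
    if sigma_aug is None:
        stacked = np.concatenate([p.embedding for p in train], axis=0)
        sigma_aug = 0.1 * stacked.std(axis=0)
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_init, rng_batch, rng_aug = (np.random.default_rng(s) for s in ss)
    encoder = PositionwiseEncoder(d, encoder_dims[0], encoder_dims[1])
    params = encoder.init_params(rng_init)
    opt = AdamW(params, lr=lr, weight_decay=weight_decay)

    def _padded(proteins):
        lmax = max(p.embedding.shape[0] for p in proteins)
        x = np.zeros((len(proteins), lmax, d))
        mask = np.zeros((len(proteins), lmax), dtype=bool)
        for a, p in enumerate(proteins):
            x[a, : p.length] = p.embedding
            mask[a, : p.length] = True
        return x, mask

    def _monitor_loss() -> float:
        total, count = 0.0, 0
        for lo in range(0, len(monitor), 64):
            chunk = monitor[lo : lo + 64]
            if len(chunk) < 2:
                continue
            x, mask = _padded(chunk)
            rep, _ = encoder.mean_representation(params, x, mask)
            loss, _ = rnc_loss_and_grad(rep, np.array([p.tm for p in chunk]), tau)
            total += loss * len(chunk)
            count += len(chunk)
        return total / max(count, 1)

    best = np.inf
    best_params = clone_params(params)
    bad = 0
    history: list[float] = []
    n = len(train)
    for _epoch in range(max_epochs):
        order = rng_batch.permutation(n)
        for lo in range(0, n, batch_size):
            chunk = [train[k] for k in order[lo : lo + batch_size]]
            if len(chunk) < 2:
                continue
            views = [gaussian_augment(p.embedding, sigma_aug, rng_aug) for p in chunk]
            lmax = max(max(p.length for p in chunk), max(v.shape[0] for v in views))
            b = len(chunk)
            x = np.zeros((2 * b, lmax, d))
            mask = np.zeros((2 * b, lmax), dtype=bool)
            for a, p in enumerate(chunk):
                x[a, : p.length] = p.embedding
                mask[a, : p.length] = True
                x[b + a, : p.length] = views[a]
                mask[b + a, : p.length] = True
            labels = np.array([p.tm for p in chunk] * 2)
            rep, cache = encoder.mean_representation(params, x, mask)
            loss, drep = rnc_loss_and_grad(rep, labels, tau)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"contrastive training diverged (non-finite loss) at epoch {_epoch}"
                )
            grads = encoder.mean_representation_backward(params, cache, drep)
            opt.step(grads)
        mloss = _monitor_loss()
        history.append(mloss)
        if mloss < best - 1e-9:
            best = mloss
            best_params = clone_params(params)
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    return encoder, best_params, history
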