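"""Synthetic meltome-style data with hierarchical species structure.

Real cross-species melting-temperature data mixes two very different scales
of variation: species means spread widely (thermophiles vs. mesophiles)
while proteins within a species spread narrowly around their species mean.
The generator reproduces exactly this two-level structure in both the
labels and the embeddings:

* species mean Tm: ``mu_s ~ Normal(mu0, sigma_between^2)``,
* protein Tm: ``Tm_i = mu_s + delta_i`` with ``delta_i ~ Normal(0,
  sigma_within^2)``,
* every residue row of protein *i*'s embedding is
  ``a_s * signature_s + kappa * delta_i * w + noise``, with
  ``a_s = (mu_s - mu0) / sigma_between`` so a linear probe of the pooled
  embedding recovers the between-species trend, ``signature_s`` a
  species-specific orthonormal direction, ``w`` a single within-species
  signal direction orthogonal to all signatures, and i.i.d.
  ``Normal(0, noise_sd^2)`` noise per coordinate.

``kappa`` dials the within-species signal from absent (``kappa = 0``, the
Simpson's-paradox regime where pooled metrics look good for the wrong
reason) to easily learnable. Embeddings carry no positional structure: each
protein has one underlying row repeated over its length plus per-residue
noise, which is all the pooling layer needs to be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EmbeddedProtein, MeltomeDataset

__all__ = [
    "SyntheticConfig",
    "SpeciesGroundTruth",
    "default_config",
    "sample_species_means",
    "generate_dataset",
    "generate_paired_datasets",
    "mean_predictor_rmse_oracle",
    "TABLE2_TRAIN_COUNTS",
]

# Per-species train-partition sizes of the FLIP meltome "mixed" split
# (25 species, largest first), clipped to [50, 3000]; used as the default
# per-species protein counts so the synthetic data matches the size
# imbalance of the real benchmark.
TABLE2_TRAIN_COUNTS = [
    3000, 2157, 1900, 1308, 1254, 1252, 1245, 1108, 931, 895, 735, 647, 628,
    573, 555, 541, 539, 499, 486, 426, 380, 293, 237, 185, 119,
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic meltome generator (temperatures in °C)."""

    n_species: int = 25
    proteins_per_species: int | tuple[int, ...] = tuple(TABLE2_TRAIN_COUNTS)
    embedding_dim: int = 32
    length_range: tuple[int, int] = (50, 120)
    mu0: float = 50.0
    sigma_between: float = 12.0
    sigma_within: float = 5.0
    kappa: float = 0.3
    noise_sd: float = 1.0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        counts = self.counts()
        if len(counts) != self.n_species or any(c < 1 for c in counts):
            raise ValueError("proteins_per_species must give a positive count per species")
        if self.embedding_dim < self.n_species + 1:
            raise ValueError(
                "embedding_dim must exceed n_species so the within-species "
                "direction can be orthogonalized against every species signature"
            )
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.sigma_between < 0 or self.sigma_within <= 0:
            raise ValueError("sigma_between must be >= 0 and sigma_within > 0")
        if self.noise_sd < 0 or self.kappa < 0:
            raise ValueError("noise_sd and kappa must be >= 0")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split_fractions must be three non-negative values summing to 1")

    def counts(self) -> list[int]:
        if isinstance(self.proteins_per_species, int):
            return [self.proteins_per_species] * self.n_species
        return list(self.proteins_per_species)


@dataclass(frozen=True)
class SpeciesGroundTruth:
    """True species mean Tm and the species' direction in embedding space."""

    species_id: str
    mu_s: float
    signature: np.ndarray  # unit vector, length embedding_dim

    def __post_init__(self):
        sig = np.asarray(self.signature, dtype=float)
        if abs(np.linalg.norm(sig) - 1.0) > 1e-9:
            raise ValueError(f"{self.species_id}: signature must have unit norm")
        object.__setattr__(self, "signature", sig)


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions (FLIP-meltome-like scale)."""
    return SyntheticConfig(**overrides)


def _species_directions(rng: np.random.Generator, dim: int, n_species: int):
    """Orthonormal species signatures plus the within-species direction w."""
    g = rng.standard_normal((dim, n_species + 1))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    return q[:, :n_species].T, q[:, n_species]


def _species_truth(config: SyntheticConfig, rng: np.random.Generator):
    mu = config.mu0 + config.sigma_between * rng.standard_normal(config.n_species)
    signatures, w = _species_directions(rng, config.embedding_dim, config.n_species)
    truths = [
        SpeciesGroundTruth(species_id=f"s{s:02d}", mu_s=float(mu[s]), signature=signatures[s])
        for s in range(config.n_species)
    ]
    return truths, w


def sample_species_means(config: SyntheticConfig) -> list[SpeciesGroundTruth]:
    """Draw the species-level ground truth (means and signatures)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    truths, _ = _species_truth(config, rng)
    return truths


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n proteins over (train, val, test)."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    order = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    for c, f in zip(counts, fractions):
        if f > 0 and c == 0:
            raise ValueError(
                f"{n} proteins per species is too small to populate every requested split"
            )
    return counts


def _shared_protein_structure(config: SyntheticConfig, rng: np.random.Generator):
    """Per-protein quantities shared across embedding views: lengths, Tm
    offsets and stratified split assignment."""
    lo, hi = config.length_range
    shared = []
    for s, n in enumerate(config.counts()):
        lengths = rng.integers(lo, hi + 1, size=n)
        deltas = config.sigma_within * rng.standard_normal(n)
        n_train, n_val, n_test = _split_counts(n, config.split_fractions)
        splits = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
        splits = splits[rng.permutation(n)]
        shared.append((lengths, deltas, splits))
    return shared


def _build_view(
    config: SyntheticConfig,
    truths: list[SpeciesGroundTruth],
    w: np.ndarray,
    shared,
    dim: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> MeltomeDataset:
    proteins = []
    for s, truth in enumerate(truths):
        a_s = (truth.mu_s - config.mu0) / config.sigma_between if config.sigma_between > 0 else 0.0
        base = a_s * truth.signature + 0.0  # (dim,)
        lengths, deltas, splits = shared[s]
        for i in range(len(lengths)):
            row = base + config.kappa * deltas[i] * w
            emb = row + noise_sd * rng.standard_normal((int(lengths[i]), dim))
            proteins.append(
                EmbeddedProtein(
                    protein_id=f"{truth.species_id}_{i:05d}",
                    species=truth.species_id,
                    embedding=emb.astype(np.float32),
                    tm=float(truth.mu_s + deltas[i]),
                    split=str(splits[i]),
                )
            )
    return MeltomeDataset(proteins)


def generate_dataset(config: SyntheticConfig) -> MeltomeDataset:
    """Generate a synthetic dataset; fully determined by ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    truths, w = _species_truth(config, np.random.default_rng(ss[0]))
    shared = _shared_protein_structure(config, np.random.default_rng(ss[1]))
    return _build_view(
        config, truths, w, shared, config.embedding_dim, config.noise_sd, np.random.default_rng(ss[2])
    )


def generate_paired_datasets(
    config: SyntheticConfig, struct_dim: int, struct_noise_sd: float | None = None
) -> tuple[MeltomeDataset, MeltomeDataset]:
    """Two embedding views of the same proteins (e.g. a sequence-model view
    and a structure-model view): identical labels, lengths and splits, but
    independent species signatures and noise per view."""
    if struct_dim < config.n_species + 1:
        raise ValueError("struct_dim must exceed n_species (orthogonalization)")
    ss = np.random.SeedSequence(config.seed).spawn(5)
    rng_species = np.random.default_rng(ss[0])
    truths, w = _species_truth(config, rng_species)
    shared = _shared_protein_structure(config, np.random.default_rng(ss[1]))
    seq_ds = _build_view(
        config, truths, w, shared, config.embedding_dim, config.noise_sd, np.random.default_rng(ss[2])
    )
    rng_struct = np.random.default_rng(ss[3])
    sig2, w2 = _species_directions(rng_struct, struct_dim, config.n_species)
    truths2 = [
        SpeciesGroundTruth(species_id=t.species_id, mu_s=t.mu_s, signature=sig2[s])
        for s, t in enumerate(truths)
    ]
    noise2 = config.noise_sd if struct_noise_sd is None else struct_noise_sd
    struct_ds = _build_view(
        config, truths2, w2, shared, struct_dim, noise2, np.random.default_rng(ss[4])
    )
    return seq_ds, struct_ds


def mean_predictor_rmse_oracle(config: SyntheticConfig, scope: str) -> float:
    """Population RMSE of the mean predictor in the infinite-train limit.

    Predicting each species' mean leaves only within-species spread
    (``sigma_within``); predicting one global mean leaves both levels,
    ``sqrt(sigma_between^2 + sigma_within^2)``.
    """
    if scope == "per_species":
        return config.sigma_within
    if scope == "global":
        return float(np.hypot(config.sigma_between, config.sigma_within))
    raise ValueError(f"scope must be 'global' or 'per_species', got {scope!r}")
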