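"""Dataset container and FLIP-style on-disk I/O.

A meltome-style dataset is a CSV table (one row per protein: identifier,
species, melting temperature in °C, train/val/test assignment) plus an HDF5
embedding store holding one ``L × d`` float32 per-residue embedding matrix
per identifier. The same layout is written by the synthetic generator and
read back by the experiment pipeline, so synthetic and real data are
interchangeable.

The FLIP benchmark marks validation rows inside the train partition with a
boolean flag; :func:`read_flip_meltome` normalizes this into the explicit
three-way split used everywhere else in the package.
"""

from __future__ import annotations

import os
from collections.abc import Callable, Iterator, Sequence
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

SPLITS = ("train", "val", "test")

__all__ = [
    "SPLITS",
    "EmbeddedProtein",
    "MeltomeDataset",
    "TableSchema",
    "read_flip_meltome",
    "write_dataset",
    "write_embedding_store",
    "filter_min_length",
    "species_partition",
    "concat_datasets",
    "export_fasta",
    "default_species_parser",
]


@dataclass(frozen=True)
class EmbeddedProtein:
    """One protein: identifier, species, per-residue embedding, Tm label."""

    protein_id: str
    species: str
    embedding: np.ndarray  # (L, d) float32
    tm: float
    split: str

    def __post_init__(self):
        emb = np.asarray(self.embedding, dtype=np.float32)
        if emb.ndim != 2 or emb.shape[0] < 1 or emb.shape[1] < 1:
            raise ValueError(
                f"{self.protein_id}: embedding must be a non-empty L x d matrix, got shape {emb.shape}"
            )
        if not np.isfinite(self.tm):
            raise ValueError(f"{self.protein_id}: Tm must be finite")
        if self.split not in SPLITS:
            raise ValueError(f"{self.protein_id}: split must be one of {SPLITS}, got {self.split!r}")
        object.__setattr__(self, "embedding", emb)

    @property
    def length(self) -> int:
        return self.embedding.shape[0]

    @property
    def dim(self) -> int:
        return self.embedding.shape[1]


@dataclass
class MeltomeDataset:
    """A collection of :class:`EmbeddedProtein` with split bookkeeping."""

    proteins: list[EmbeddedProtein] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[EmbeddedProtein]:
        return iter(self.proteins)

    def subset(self, keep: Sequence[EmbeddedProtein]) -> "MeltomeDataset":
        return MeltomeDataset(list(keep))

    def split_proteins(self, split: str) -> list[EmbeddedProtein]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return [p for p in self.proteins if p.split == split]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.proteins:
            seen.setdefault(p.species, None)
        return list(seen)

    @property
    def species_table(self) -> pd.DataFrame:
        """Counts per species and split (rows: species, columns: splits + total)."""
        rows = [(p.species, p.split) for p in self.proteins]
        df = pd.DataFrame(rows, columns=["species", "split"])
        if df.empty:
            return pd.DataFrame(columns=[*SPLITS, "total"])
        tab = df.value_counts(["species", "split"]).unstack(fill_value=0)
        tab = tab.reindex(columns=SPLITS, fill_value=0)
        tab["total"] = tab.sum(axis=1)
        return tab.loc[self.species]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.protein_id for p in self.proteins],
                "species": [p.species for p in self.proteins],
                "tm": [p.tm for p in self.proteins],
                "split": [p.split for p in self.proteins],
            }
        )


@dataclass(frozen=True)
class TableSchema:
    """Column names of the protein table; defaults match this package's own
    layout, alternates (e.g. FLIP's ``sequence``/``target``/``set``/
    ``validation``) are configured per call."""

    id: str = "id"
    species: str | None = "species"
    tm: str = "tm"
    split: str = "split"
    is_validation: str | None = "is_validation"
    sequence: str | None = "sequence"


FLIP_SCHEMA = TableSchema(
    id="id", species=None, tm="target", split="set", is_validation="validation", sequence="sequence"
)


def default_species_parser(protein_id: str) -> str | None:
    """Species = prefix of the identifier up to the last underscore-delimited
    token (the UniProt accession in FLIP meltome ids). Returns None when the
    identifier carries no underscore-delimited suffix."""
    prefix, sep, _ = protein_id.rpartition("_")
    return prefix if sep else None


def _normalize_split(split_value: str, is_validation) -> str:
    s = str(split_value).strip().lower()
    if s in ("val", "valid", "validation"):
        return "val"
    if s == "train":
        if is_validation is not None and bool(is_validation) and str(is_validation).lower() not in ("false", "0", "nan"):
            return "val"
        return "train"
    if s == "test":
        return "test"
    raise ValueError(f"unrecognized split value {split_value!r}")


def read_flip_meltome(
    table_path: str | os.PathLike,
    embedding_store_path: str | os.PathLike,
    schema: TableSchema = TableSchema(),
    species_parser: Callable[[str], str | None] = default_species_parser,
    strict_species: bool = True,
) -> MeltomeDataset:
    """Read a protein table plus embedding store into a :class:`MeltomeDataset`.

    Every identifier in the table must resolve in the store; a missing
    embedding raises ``KeyError`` naming the identifier. When the table has
    no species column, species labels are parsed from identifiers with
    ``species_parser``; in strict mode an unparseable identifier is a hard
    error, otherwise the full identifier is used as the species label.
    """
    df = pd.read_csv(table_path, float_precision="round_trip")
    for col in (schema.id, schema.tm, schema.split):
        if col not in df.columns:
            raise ValueError(f"table {table_path} lacks required column {col!r}")
    proteins: list[EmbeddedProtein] = []
    with h5py.File(embedding_store_path, "r") as store:
        for _, row in df.iterrows():
            pid = str(row[schema.id])
            if pid not in store:
                raise KeyError(f"no embedding stored for identifier {pid!r} in {embedding_store_path}")
            if schema.species is not None and schema.species in df.columns:
                species = str(row[schema.species])
            else:
                species = species_parser(pid)
                if species is None:
                    if strict_species:
                        raise ValueError(f"cannot parse species from identifier {pid!r}")
                    species = pid
            is_val = row[schema.is_validation] if (schema.is_validation and schema.is_validation in df.columns) else None
            proteins.append(
                EmbeddedProtein(
                    protein_id=pid,
                    species=species,
                    embedding=np.asarray(store[pid], dtype=np.float32),
                    tm=float(row[schema.tm]),
                    split=_normalize_split(row[schema.split], is_val),
                )
            )
    return MeltomeDataset(proteins)


def write_embedding_store(ds: MeltomeDataset, path: str | os.PathLike) -> None:
    """Write one float32 dataset per protein id into an HDF5 container."""
    tmp = str(path) + ".tmp"
    with h5py.File(tmp, "w") as store:
        store.attrs["dim"] = ds.proteins[0].dim if ds.proteins else 0
        for p in ds.proteins:
            # track_times=False keeps the file byte-reproducible across reruns
            store.create_dataset(p.protein_id, data=p.embedding.astype(np.float32), track_times=False)
    os.replace(tmp, path)


def write_dataset(ds: MeltomeDataset, table_path: str | os.PathLike, store_path: str | os.PathLike) -> None:
    """Write the CSV table and the embedding store; round-trips bit-exactly
    through :func:`read_flip_meltome`."""
    tmp = str(table_path) + ".tmp"
    # %.17g guarantees float64 Tm values survive the CSV round-trip exactly
    ds.to_table().to_csv(tmp, index=False, float_format="%.17g")
    os.replace(tmp, table_path)
    write_embedding_store(ds, store_path)


def filter_min_length(ds: MeltomeDataset, min_len: int = 50) -> MeltomeDataset:
    """Discard proteins shorter than ``min_len`` residues (boundary kept)."""
    return ds.subset([p for p in ds.proteins if p.length >= min_len])


def species_partition(ds: MeltomeDataset) -> dict[str, MeltomeDataset]:
    """Disjoint per-species sub-datasets, split labels preserved."""
    out: dict[str, list[EmbeddedProtein]] = {}
    for p in ds.proteins:
        out.setdefault(p.species, []).append(p)
    return {sp: MeltomeDataset(ps) for sp, ps in out.items()}


def concat_datasets(seq_ds: MeltomeDataset, struct_ds: MeltomeDataset) -> MeltomeDataset:
    """Row-wise concatenation of two embedding sets (sequence features first),
    matched on protein id; labels and splits must agree."""
    from .model import concat_embeddings

    by_id = {p.protein_id: p for p in struct_ds.proteins}
    out = []
    for p in seq_ds.proteins:
        if p.protein_id not in by_id:
            raise KeyError(f"protein {p.protein_id!r} missing from the structure-embedding dataset")
        q = by_id[p.protein_id]
        if (p.species, p.split) != (q.species, q.split) or p.tm != q.tm:
            raise ValueError(f"metadata mismatch for protein {p.protein_id!r}")
        out.append(replace(p, embedding=concat_embeddings(p.embedding, q.embedding)))
    return MeltomeDataset(out)


def export_fasta(
    table_path: str | os.PathLike, fasta_path: str | os.PathLike, schema: TableSchema = TableSchema()
) -> int:
    """Write sequences from the protein table as FASTA; returns the number of
    records written. Rows without a sequence are ignored."""
    df = pd.read_csv(table_path)
    if schema.sequence is None or schema.sequence not in df.columns:
        raise ValueError(f"table {table_path} has no sequence column {schema.sequence!r}")
    n = 0
    with open(fasta_path, "w") as fh:
        for _, row in df.iterrows():
            seq = row[schema.sequence]
            if isinstance(seq, str) and seq:
                fh.write(f">{row[schema.id]}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
                n += 1
    return n
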