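"""Core domain types and tab-separated readers/writers.

Every file the pipeline touches is a UTF-8, tab-separated table with a header
row.  Gene identifiers are opaque strings; a count of zero is the only
representation of "not detected" (count matrices are dense).  Population
labels are free strings — the pipeline configuration declares which two
labels form the focal low/high-latitude pair and which are outgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "CountsDataset",
    "TpmMatrix",
    "OrthologMap",
    "GeneSet",
    "read_counts",
    "write_counts",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_set",
    "write_gene_set",
    "read_tpm",
    "write_tpm",
]


class DataValidationError(ValueError):
    """An input file or in-memory table violates a type invariant."""


@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library: a replicate pool of one population × tissue."""

    sample_id: str
    species: str
    population: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DataValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate}"
            )

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.species, self.population, self.tissue, self.replicate)


@dataclass
class CountsDataset:
    """Gene × sample integer read counts with gene lengths and metadata.

    The raw input of everything downstream; stands in for the read-counting
    stage of an alignment pipeline.
    """

    genes: list[str]
    lengths: np.ndarray  # bp, positive, aligned with `genes`
    samples: list[SampleInfo]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise DataValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise DataValidationError(f"duplicate gene id {dup!r}")
        if self.lengths.shape != (len(self.genes),):
            raise DataValidationError("lengths must align with genes")
        if np.any(self.lengths <= 0):
            bad = self.genes[int(np.argmax(self.lengths <= 0))]
            raise DataValidationError(f"gene {bad!r} has non-positive length")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise DataValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.unravel_index(int(np.argmax(self.counts < 0)), self.counts.shape)
            raise DataValidationError(
                f"negative count at gene {self.genes[g]!r}, "
                f"sample {self.samples[s].sample_id!r}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataValidationError(f"duplicate sample id {_first_duplicate(ids)!r}")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise DataValidationError(
                f"duplicate (species, population, tissue, replicate) key "
                f"{_first_duplicate(keys)}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "CountsDataset":
        idx = np.arange(self.n_samples)[np.asarray(keep)]
        return CountsDataset(
            genes=list(self.genes),
            lengths=self.lengths.copy(),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )

    def select(self, species: str | None = None, tissue: str | None = None,
               populations: Iterable[str] | None = None) -> "CountsDataset":
        """Subset samples by species / tissue / population labels."""
        pops = set(populations) if populations is not None else None
        keep = [
            (species is None or s.species == species)
            and (tissue is None or s.tissue == tissue)
            and (pops is None or s.population in pops)
            for s in self.samples
        ]
        if not any(keep):
            raise DataValidationError(
                f"no samples match species={species!r} tissue={tissue!r} "
                f"populations={sorted(pops) if pops else None}"
            )
        return self.subset_samples(keep)


@dataclass
class TpmMatrix:
    """Gene × sample transcripts-per-million; columns of expressed samples sum to 1e6."""

    genes: list[str]
    samples: list[SampleInfo]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.genes), len(self.samples)):
            raise DataValidationError("tpm shape does not match genes x samples")
        if np.any(self.tpm < 0):
            raise DataValidationError("negative TPM value")
        colsum = self.tpm.sum(axis=0)
        nonzero = colsum > 0
        if np.any(np.abs(colsum[nonzero] - 1e6) > 1e6 * 1e-6):
            j = int(np.argmax(np.abs(colsum - 1e6) > 1))
            raise DataValidationError(
                f"TPM column for sample {self.samples[j].sample_id!r} sums to "
                f"{colsum[j]:.3f}, not 1e6"
            )


@dataclass
class OrthologMap:
    """1:1 (pairwise) or 1:1:1 (three-way) ortholog correspondences."""

    species_ids: list[str]
    rows: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        k = len(self.species_ids)
        if k not in (2, 3):
            raise DataValidationError(f"ortholog map needs 2 or 3 species, got {k}")
        for col in range(k):
            seen: set[str] = set()
            for row in self.rows:
                if len(row) != k or any(not g for g in row):
                    raise DataValidationError(f"ortholog row {row} has a null entry")
                g = row[col]
                if g in seen:
                    raise DataValidationError(
                        f"gene {g!r} not 1:1 (appears in more than one row)"
                    )
                seen.add(g)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, species: str) -> list[str]:
        try:
            j = self.species_ids.index(species)
        except ValueError:
            raise DataValidationError(
                f"species {species!r} not in ortholog map {self.species_ids}"
            ) from None
        return [row[j] for row in self.rows]

    def restrict(self, species_subset: Sequence[str]) -> "OrthologMap":
        """Project a three-way map onto a pair of species."""
        cols = [self.species_ids.index(s) for s in species_subset]
        return OrthologMap(
            species_ids=list(species_subset),
            rows=[tuple(row[j] for j in cols) for row in self.rows],
        )


@dataclass
class GeneSet:
    """A labelled gene class (e.g. Sfp, TF, cell-type marker) for one species."""

    label: str
    members: set[str] = field(default_factory=set)
    species: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise DataValidationError(f"gene set {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# Readers / writers.  All formats are headered TSV.

def _first_duplicate(items: Iterable) -> object:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


METADATA_COLUMNS = ["sample_id", "species", "population", "tissue", "replicate"]


def read_counts(counts_path: str | Path, metadata_path: str | Path,
                lengths_path: str | Path) -> CountsDataset:
    """Read a counts TSV (gene_id + one column per sample), sample metadata,
    and per-gene lengths into a validated :class:`CountsDataset`.

    Gene and sample order are preserved from the counts file.
    """
    cdf = _read_tsv(counts_path)
    if cdf.columns[0] != "gene_id":
        raise DataValidationError(
            f"{counts_path}: first column must be 'gene_id', got {cdf.columns[0]!r}"
        )
    genes = cdf["gene_id"].tolist()
    if len(set(genes)) != len(genes):
        raise DataValidationError(
            f"{counts_path}: duplicate gene id {_first_duplicate(genes)!r}"
        )
    sample_ids = list(cdf.columns[1:])

    mdf = _read_tsv(metadata_path)
    missing_cols = [c for c in METADATA_COLUMNS if c not in mdf.columns]
    if missing_cols:
        raise DataValidationError(f"{metadata_path}: missing columns {missing_cols}")
    meta = {r["sample_id"]: r for _, r in mdf.iterrows()}
    samples = []
    for sid in sample_ids:
        if sid not in meta:
            raise DataValidationError(
                f"sample {sid!r} in {counts_path} is missing from metadata"
            )
        r = meta[sid]
        try:
            rep = int(r["replicate"])
        except ValueError:
            raise DataValidationError(
                f"sample {sid!r}: non-integer replicate {r['replicate']!r}"
            ) from None
        samples.append(SampleInfo(sid, r["species"], r["population"], r["tissue"], rep))

    counts = np.empty((len(genes), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        col = cdf[sid]
        try:
            counts[:, j] = col.astype(np.int64)
        except ValueError:
            bad = next(i for i, v in enumerate(col) if not v.lstrip("-").isdigit())
            raise DataValidationError(
                f"{counts_path}: non-integer count {col.iloc[bad]!r} at gene "
                f"{genes[bad]!r}, sample {sid!r}"
            ) from None

    ldf = _read_tsv(lengths_path)
    for c in ("gene_id", "length_bp"):
        if c not in ldf.columns:
            raise DataValidationError(f"{lengths_path}: missing column {c!r}")
    lmap = dict(zip(ldf["gene_id"], ldf["length_bp"]))
    lengths = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g not in lmap:
            raise DataValidationError(f"gene {g!r} missing from lengths file")
        lengths[i] = float(lmap[g])

    return CountsDataset(genes=genes, lengths=lengths, samples=samples, counts=counts)


def write_counts(ds: CountsDataset, counts_path: str | Path,
                 metadata_path: str | Path, lengths_path: str | Path) -> None:
    cdf = pd.DataFrame(ds.counts, columns=ds.sample_ids())
    cdf.insert(0, "gene_id", ds.genes)
    cdf.to_csv(counts_path, sep="\t", index=False)
    mdf = pd.DataFrame(
        [(s.sample_id, s.species, s.population, s.tissue, s.replicate)
         for s in ds.samples],
        columns=METADATA_COLUMNS,
    )
    mdf.to_csv(metadata_path, sep="\t", index=False)
    ldf = pd.DataFrame({"gene_id": ds.genes,
                        "length_bp": ds.lengths.astype(np.int64)})
    ldf.to_csv(lengths_path, sep="\t", index=False)


def read_ortholog_map(path: str | Path, n_species: int | None = None) -> OrthologMap:
    """Read an ortholog TSV (one gene-id column per species).

    Any gene appearing in more than one row makes the whole file invalid.
    """
    df = _read_tsv(path)
    species_ids = list(df.columns)
    if n_species is not None and len(species_ids) != n_species:
        raise DataValidationError(
            f"{path}: expected {n_species} species columns, found {len(species_ids)}"
        )
    rows = [tuple(r) for r in df.itertuples(index=False, name=None)]
    return OrthologMap(species_ids=species_ids, rows=rows)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(omap.rows, columns=omap.species_ids).to_csv(
        path, sep="\t", index=False
    )


def read_gene_set(path: str | Path, label: str, species: str = "") -> GeneSet:
    """Read a gene set (first column = gene ids; extra columns ignored),
    de-duplicating membership.
    """
    df = _read_tsv(path)
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: gene set file is empty")
    members = set(df.iloc[:, 0])
    members.discard("")
    if not members:
        raise DataValidationError(f"{path}: gene set file has no gene ids")
    return GeneSet(label=label, members=members, species=species)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    pd.DataFrame({"gene_id": sorted(gs.members), "label": gs.label}).to_csv(
        path, sep="\t", index=False
    )


def read_tpm(path: str | Path, metadata_path: str | Path) -> TpmMatrix:
    df = _read_tsv(path)
    genes = df["gene_id"].tolist()
    sample_ids = list(df.columns[1:])
    mdf = _read_tsv(metadata_path)
    meta = {r["sample_id"]: r for _, r in mdf.iterrows()}
    samples = []
    for sid in sample_ids:
        if sid not in meta:
            raise DataValidationError(f"sample {sid!r} missing from metadata")
        r = meta[sid]
        samples.append(SampleInfo(sid, r["species"], r["population"], r["tissue"],
                                  int(r["replicate"])))
    tpm = df[sample_ids].astype(float).to_numpy()
    return TpmMatrix(genes=genes, samples=samples, tpm=tpm)


def write_tpm(tm: TpmMatrix, path: str | Path) -> None:
    df = pd.DataFrame(tm.tpm, columns=[s.sample_id for s in tm.samples])
    df.insert(0, "gene_id", tm.genes)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
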