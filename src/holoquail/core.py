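"""Shared data containers and plain-text I/O for the hologenomic pipeline.

The pipeline moves four kinds of objects between stages: a three-generation
pedigree, SNP genotypes on a genetic (cM) linkage map, a samples x taxa
abundance table with its taxonomy, and a phenotype table.  All of them are
thin wrappers around :class:`pandas.DataFrame` / :class:`numpy.ndarray` so
that downstream code can use ordinary pandas/numpy idioms; the wrappers only
add identity alignment, validation and TSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: integer code for a missing genotype call
MISSING = -1


class HoloquailError(ValueError):
    """Base class for user-facing errors raised by this package."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Three-generation pedigree (founder lines, F1, F2).

    ``table`` has columns ``id``, ``sire``, ``dam``, ``generation``; founders
    carry empty-string parents.  Row order is a valid topological order:
    every parent appears before its offspring.
    """

    table: pd.DataFrame

    REQUIRED = ("id", "sire", "dam", "generation")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise HoloquailError(f"pedigree table lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent and parent not in seen:
                    raise HoloquailError(
                        f"parent {parent!r} of {row.id!r} does not precede it "
                        "in the pedigree (loop or mis-ordered records)"
                    )
            seen.add(row.id)
        if len(seen) != len(self.table):
            raise HoloquailError("duplicate ids in pedigree")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def subset_generation(self, generation: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == generation]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of row indices of sire/dam; -1 for unknown."""
        pos = {ind: i for i, ind in enumerate(self.table["id"])}
        out = np.full((len(self.table), 2), -1, dtype=int)
        for i, row in enumerate(self.table.itertuples(index=False)):
            if row.sire:
                out[i, 0] = pos[row.sire]
            if row.dam:
                out[i, 1] = pos[row.dam]
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pedigree":
        tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(tab)


# ---------------------------------------------------------------------------
# Linkage map and genotypes
# ---------------------------------------------------------------------------

@dataclass
class LinkageMap:
    """Genetic map: one row per marker with chromosome and position in cM."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cm

    def __post_init__(self) -> None:
        for c in ("marker", "chrom", "pos_cm"):
            if c not in self.table.columns:
                raise HoloquailError(f"linkage map lacks column {c!r}")
        self.table = self.table.reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos_cm"].is_monotonic_increasing:
                raise HoloquailError(
                    f"marker positions not sorted on chromosome {chrom}"
                )

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LinkageMap":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GenotypeMatrix:
    """SNP genotypes coded as copies of the line-B (``1``) allele.

    ``values`` is (individuals x markers) int8 with entries in {0, 1, 2}
    or :data:`MISSING`.
    """

    ids: list[str]
    lmap: LinkageMap
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.ids), len(self.lmap.table)):
            raise HoloquailError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.lmap.table)} markers"
            )
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise HoloquailError("genotype codes must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        idx = [pos[k] for k in keep]
        return GenotypeMatrix(list(keep), self.lmap, self.values[idx])

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        lmap = LinkageMap(self.lmap.table[mask].reset_index(drop=True))
        return GenotypeMatrix(self.ids, lmap, self.values[:, mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.ids, columns=self.lmap.table["marker"]
        )

    # -- TSV matrix format ---------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, lmap: LinkageMap) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df[list(lmap.table["marker"])]
        return cls([str(i) for i in df.index], lmap, df.to_numpy(dtype=np.int8))

    # -- PLINK-style ped/map (cM in the position column) ---------------------
    def write_plink(self, prefix: str | Path, pedigree: "Pedigree | None" = None) -> None:
        prefix = Path(prefix)
        m = self.lmap.table
        with open(prefix.with_suffix(".map"), "w") as fh:
            for row in m.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.marker}\t{row.pos_cm}\t0\n")
        parents = {}
        if pedigree is not None:
            parents = {
                r.id: (r.sire or "0", r.dam or "0")
                for r in pedigree.table.itertuples(index=False)
            }
        allele = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for ind, row in zip(self.ids, self.values):
                sire, dam = parents.get(ind, ("0", "0"))
                calls = " ".join(allele[int(g)] for g in row)
                fh.write(f"FAM\t{ind}\t{sire}\t{dam}\t0\t0\t{calls}\n")

    @classmethod
    def read_plink(cls, prefix: str | Path) -> "GenotypeMatrix":
        prefix = Path(prefix)
        m = pd.read_csv(
            prefix.with_suffix(".map"), sep="\t", header=None,
            names=["chrom", "marker", "pos_cm", "bp"],
        )
        lmap = LinkageMap(m[["marker", "chrom", "pos_cm"]])
        ids, rows = [], []
        code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2,
                ("0", "0"): MISSING}
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                parts = line.split()
                ids.append(parts[1])
                alleles = parts[6:]
                rows.append(
                    [code[(alleles[2 * j], alleles[2 * j + 1])]
                     for j in range(len(alleles) // 2)]
                )
        return cls(ids, lmap, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# Abundances and taxonomy
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Samples x taxa abundance table (counts or relative abundances).

    ``level`` records whether columns are OTUs or genera.  ``relative``
    declares the values as per-sample fractions; in that case each row must
    sum to one.
    """

    data: pd.DataFrame
    level: str = "otu"
    relative: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("otu", "genus"):
            raise HoloquailError(f"unknown taxon level {self.level!r}")
        if (self.data.to_numpy() < 0).any():
            raise HoloquailError("abundances must be non-negative")
        if self.relative:
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                worst = self.data.index[int(np.argmax(np.abs(sums - 1)))]
                raise HoloquailError(
                    f"relative abundances of sample {worst!r} do not sum to 1"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, level: str = "otu",
                 relative: bool = False) -> "AbundanceTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), level, relative)


@dataclass
class TaxonomyMap:
    """OTU -> (genus, family, order, class, phylum); "unclassified" allowed."""

    table: pd.DataFrame  # index: otu; columns genus, family, order, class_, phylum

    COLUMNS = ("genus", "family", "order", "class_", "phylum")

    def __post_init__(self) -> None:
        for c in self.COLUMNS:
            if c not in self.table.columns:
                raise HoloquailError(f"taxonomy lacks column {c!r}")

    def genus_of(self, otu: str) -> str:
        return str(self.table.loc[otu, "genus"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "otu"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyMap":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Dense symmetric covariance structure among individuals.

    ``kind`` is ``"A"`` (pedigree numerator), ``"G"`` (genomic, VanRaden
    method 1, optionally leave-one-chromosome-out) or ``"M"`` (microbial).
    """

    kind: str
    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise HoloquailError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise HoloquailError(f"{self.kind} matrix is not symmetric")

    def align(self, ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix for ``ids`` in the given order."""
        pos = {ind: i for i, ind in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise HoloquailError(f"individual {exc} absent from {self.kind}")
        return self.values[np.ix_(idx, idx)]

    def stabilized(self, jitter: float = 1e-6) -> np.ndarray:
        """Copy with ``jitter`` added to the diagonal (PSD safeguard)."""
        out = self.values.copy()
        out[np.diag_indices_from(out)] += jitter
        return out

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(kind, [str(i) for i in df.index], df.to_numpy())


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: canonical phenotype columns; PU in % of P intake, masses in g, P in mg
PHENO_COLUMNS = (
    "id", "test_day", "BW10", "BW15", "FI",
    "P_intake", "P_excretion", "BWG", "FG", "PU",
)

TRAITS = ("PU", "FI", "BWG", "FG")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    tab["id"] = tab["id"].astype(str)
    return tab


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def test_day_design(test_day: Iterable) -> np.ndarray:
    """Incidence matrix (n x m) of a categorical test-day factor."""
    td = pd.Categorical(list(test_day))
    return np.eye(len(td.categories))[td.codes]
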