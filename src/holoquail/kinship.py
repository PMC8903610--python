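"""Covariance structures among individuals: A (pedigree), G (SNP), M (OTU).

A is the numerator relationship matrix from the recursive tabular method
with founders assumed unrelated and non-inbred.  G follows VanRaden's
method 1, ``G = ZZ' / (2 * sum p_j (1 - p_j))`` with allele-frequency
centring, optionally excluding one chromosome (LOCO) for association
scans.  M is the microbial relationship matrix built from log-transformed,
column-standardized OTU relative abundances, ``M = XX' / n_otus``.

Also here: the SNP quality-control step (Mendelian conflicts against the
pedigree, minor-allele-frequency and call-rate bounds, sex-chromosome
exclusion).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    MISSING, AbundanceTable, GenotypeMatrix, HoloquailError, Pedigree,
    RelationshipMatrix,
)

__all__ = ["qc_genotypes", "build_A", "build_G", "build_M"]


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

# offspring genotypes impossible given one parent's genotype
_PAIR_CONFLICT = {(0, 2), (2, 0)}


def _trio_conflict(off, sire, dam):
    """Vectorized Mendelian check; missing treated as compatible."""
    conflict = np.zeros(off.shape, dtype=bool)
    for par in (sire, dam):
        if par is None:
            continue
        conflict |= (off == 0) & (par == 2)
        conflict |= (off == 2) & (par == 0)
    if sire is not None and dam is not None:
        both = (sire != MISSING) & (dam != MISSING) & (off != MISSING)
        # homozygous x homozygous -> offspring fixed
        conflict |= both & (sire == 0) & (dam == 0) & (off != 0)
        conflict |= both & (sire == 2) & (dam == 2) & (off != 2)
        conflict |= both & (sire == 0) & (dam == 2) & (off != 1)
        conflict |= both & (sire == 2) & (dam == 0) & (off != 1)
    return conflict


def qc_genotypes(geno: GenotypeMatrix, pedigree: Pedigree | None = None,
                 maf_max_excl: float = 0.03,
                 callrate_max_excl: float = 0.9,
                 sex_chromosomes: tuple = ("Z", "W")):
    """Apply the SNP filters; returns (filtered genotypes, report).

    Removed are SNPs with one or more parent-offspring Mendelian conflicts,
    minor allele frequency <= ``maf_max_excl``, call frequency <=
    ``callrate_max_excl`` (both bounds inclusive on the removal side), and
    SNPs on the named sex chromosomes.
    """
    vals = geno.values
    n, m = vals.shape
    observed = vals != MISSING

    callrate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(observed, vals, 0).sum(axis=0) / (2.0 * np.maximum(
            observed.sum(axis=0), 1))
    maf = np.minimum(p, 1 - p)

    mendel = np.zeros(m, dtype=bool)
    if pedigree is not None:
        pos = {ind: i for i, ind in enumerate(geno.ids)}
        for row in pedigree.table.itertuples(index=False):
            if not (row.sire or row.dam):
                continue
            if row.id not in pos:
                continue
            missing_parent = [
                par for par in (row.sire, row.dam) if par and par not in pos
            ]
            if missing_parent:
                warnings.warn(
                    f"parent(s) {missing_parent} of {row.id!r} not genotyped; "
                    "conflict check skipped for that trio"
                )
                continue
            off = vals[pos[row.id]]
            sire = vals[pos[row.sire]] if row.sire else None
            dam = vals[pos[row.dam]] if row.dam else None
            mendel |= _trio_conflict(off, sire, dam)

    chrom = geno.lmap.table["chrom"].astype(str).to_numpy()
    sex = np.isin(chrom, [str(c) for c in sex_chromosomes])

    low_maf = maf <= maf_max_excl
    low_call = callrate <= callrate_max_excl
    drop = mendel | low_maf | low_call | sex
    report = {
        "n_input": m,
        "mendelian_conflict": int(mendel.sum()),
        "low_maf": int(low_maf.sum()),
        "low_callrate": int(low_call.sum()),
        "sex_chromosome": int(sex.sum()),
        "removed": int(drop.sum()),
        "kept": int((~drop).sum()),
    }
    return geno.subset_markers(~drop), report


# ---------------------------------------------------------------------------
# A: pedigree numerator relationship matrix
# ---------------------------------------------------------------------------

def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method."""
    parents = pedigree.parent_indices()  # topological order guaranteed
    n = len(parents)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        inb = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + inb
    return RelationshipMatrix("A", pedigree.ids, A)


# ---------------------------------------------------------------------------
# G: genomic relationship matrix (VanRaden method 1)
# ---------------------------------------------------------------------------

def build_G(geno: GenotypeMatrix, loco_chrom=None) -> RelationshipMatrix:
    """``G = ZZ' / (2 sum p(1-p))`` with mean imputation of missing calls.

    ``loco_chrom`` excludes that chromosome's SNPs (leave-one-chromosome-out).
    """
    keep = np.ones(geno.n_markers, dtype=bool)
    if loco_chrom is not None:
        keep = geno.lmap.table["chrom"].to_numpy() != loco_chrom
        if keep.sum() < 2:
            raise HoloquailError(
                f"fewer than 2 SNPs remain after excluding chromosome "
                f"{loco_chrom!r}"
            )
    vals = geno.values[:, keep].astype(float)
    obs = vals != MISSING
    vals[~obs] = np.nan
    p = np.nanmean(vals, axis=0) / 2.0
    # mean imputation per SNP
    fill = np.broadcast_to(2 * p, vals.shape)
    vals = np.where(np.isnan(vals), fill, vals)
    denom = 2.0 * float(np.sum(p * (1 - p)))
    if denom <= 0:
        raise HoloquailError("all SNPs monomorphic; G undefined")
    Z = vals - 2 * p
    G = (Z @ Z.T) / denom
    meta = {"n_markers": int(keep.sum())}
    if loco_chrom is not None:
        meta["loco_excluded"] = loco_chrom
    return RelationshipMatrix("G", list(geno.ids), G, meta)


# ---------------------------------------------------------------------------
# M: microbial relationship matrix
# ---------------------------------------------------------------------------

def build_M(otus: AbundanceTable, log_offset: float = 1e-6) -> RelationshipMatrix:
    """Microbial relationship matrix from OTU relative abundances.

    Per OTU: ``log(x + log_offset)`` then standardization to zero mean and
    unit variance across samples; ``M = XX' / n_otus``.  Zero-variance OTUs
    carry no between-sample information and are dropped with a warning.
    """
    X = np.log(otus.data.to_numpy(dtype=float) + log_offset)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise HoloquailError("fewer than 2 OTUs with non-zero variance")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant OTU column(s)")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    M = (X @ X.T) / keep.sum()
    return RelationshipMatrix(
        "M", list(otus.data.index.astype(str)), M,
        {"n_otus": int(keep.sum())},
    )
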