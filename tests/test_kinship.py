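"""QC filters and the A / G / M relationship matrices."""

import numpy as np
import pandas as pd
import pytest

from holoquail.core import (
    AbundanceTable, GenotypeMatrix, HoloquailError, LinkageMap, Pedigree,
)
from holoquail.kinship import build_A, build_G, build_M, qc_genotypes


def geno_from(values, chroms=None, ids=None):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    chroms = chroms if chroms is not None else [1] * m
    lmap = LinkageMap(pd.DataFrame({
        "marker": [f"m{j}" for j in range(m)],
        "chrom": chroms,
        "pos_cm": [float(j) for j in range(m)],
    }))
    return GenotypeMatrix(ids or [f"i{k}" for k in range(n)], lmap, values)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def trio_pedigree():
    return Pedigree(pd.DataFrame({
        "id": ["sire", "dam", "kid"],
        "sire": ["", "", "sire"],
        "dam": ["", "", "dam"],
        "generation": ["F0", "F0", "F1"],
    }))


def test_qc_removes_mendelian_conflict():
    # SNP0: both parents 0, kid 1 -> impossible; SNP1 consistent
    geno = geno_from([[0, 1], [0, 1], [1, 1]], ids=["sire", "dam", "kid"])
    kept, report = qc_genotypes(geno, trio_pedigree(), maf_max_excl=0.0,
                                callrate_max_excl=0.0)
    assert report["mendelian_conflict"] == 1
    assert list(kept.lmap.table["marker"]) == ["m1"]


def test_qc_maf_boundary_is_inclusive():
    # 50 individuals; SNP0 has 3 copies of allele 1 -> MAF 0.03 (removed);
    # SNP1 has 4 copies -> MAF 0.04 (kept)
    vals = np.zeros((50, 2), dtype=np.int8)
    vals[:3, 0] = 1
    vals[:4, 1] = 1
    kept, report = qc_genotypes(geno_from(vals), None,
                                callrate_max_excl=0.0)
    assert report["low_maf"] == 1
    assert list(kept.lmap.table["marker"]) == ["m1"]


def test_qc_callrate_boundary_is_inclusive():
    from holoquail.core import MISSING
    vals = np.ones((10, 2), dtype=np.int8)
    vals[0, 0] = MISSING              # 90% called -> removed (<= 0.9)
    vals[:5, 1] = 0                   # polymorphic, fully called -> kept
    kept, report = qc_genotypes(geno_from(vals), None, maf_max_excl=0.0)
    assert report["low_callrate"] == 1
    assert list(kept.lmap.table["marker"]) == ["m1"]


def test_qc_drops_sex_chromosomes_and_warns_on_ungenotyped_parent():
    geno = geno_from([[1, 1], [1, 1]], chroms=["Z", 1], ids=["dam", "kid"])
    ped = Pedigree(pd.DataFrame({
        "id": ["sire", "dam", "kid"],
        "sire": ["", "", "sire"],
        "dam": ["", "", "dam"],
        "generation": ["F0", "F0", "F1"],
    }))
    with pytest.warns(UserWarning, match="not genotyped"):
        kept, report = qc_genotypes(geno, ped, maf_max_excl=0.0,
                                    callrate_max_excl=0.0)
    assert report["sex_chromosome"] == 1


# ---------------------------------------------------------------------------
# A matrix
# ---------------------------------------------------------------------------

def test_A_textbook_values():
    ped = Pedigree(pd.DataFrame({
        "id": ["s", "d", "k1", "k2"],
        "sire": ["", "", "s", "s"],
        "dam": ["", "", "d", "d"],
        "generation": ["F0", "F0", "F1", "F1"],
    }))
    A = build_A(ped)
    i = {x: k for k, x in enumerate(A.ids)}
    assert A.values[i["s"], i["k1"]] == pytest.approx(0.5)   # parent-offspring
    assert A.values[i["k1"], i["k2"]] == pytest.approx(0.5)  # full sibs
    assert A.values[i["k1"], i["k1"]] == pytest.approx(1.0)  # non-inbred
    assert A.values[i["s"], i["d"]] == pytest.approx(0.0)


def test_A_inbreeding_from_full_sib_mating():
    ped = Pedigree(pd.DataFrame({
        "id": ["s", "d", "a", "b", "x"],
        "sire": ["", "", "s", "s", "a"],
        "dam": ["", "", "d", "d", "b"],
        "generation": ["F0", "F0", "F1", "F1", "F2"],
    }))
    A = build_A(ped)
    # offspring of full sibs: F = 0.25, diagonal 1.25
    assert A.values[-1, -1] == pytest.approx(1.25)


def random_pedigree(rng, n=40, n_founders=12):
    rows = [{"id": f"p{i}", "sire": "", "dam": "", "generation": "F0"}
            for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        rows.append({
            "id": f"p{i}", "sire": f"p{s}", "dam": f"p{d}",
            "generation": "F1",
        })
    return Pedigree(pd.DataFrame(rows))


def gene_drop_oracle(ped, n_rep, rng):
    """Monte-Carlo expected allele sharing: E[a_ij] over biallelic drops."""
    parents = ped.parent_indices()
    n = len(parents)
    alleles = np.empty((n, 2, n_rep), dtype=np.int32)
    counter = 0
    for i in range(n):
        s, d = parents[i]
        if s < 0:
            alleles[i, 0] = 2 * i
            alleles[i, 1] = 2 * i + 1
        else:
            pick_s = rng.integers(0, 2, size=n_rep)
            pick_d = rng.integers(0, 2, size=n_rep)
            alleles[i, 0] = alleles[s, pick_s, np.arange(n_rep)]
            alleles[i, 1] = alleles[d, pick_d, np.arange(n_rep)]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = sum(
                np.mean(alleles[i, a] == alleles[j, b])
                for a in range(2) for b in range(2)
            )
            A[i, j] = A[j, i] = ibd / 2.0
    return A


@pytest.mark.parametrize("seed", [0, 1])
def test_A_matches_gene_dropping_oracle(seed):
    """Tabular A equals Monte-Carlo identity-by-descent sharing."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng)
    A = build_A(ped).values
    oracle = gene_drop_oracle(ped, n_rep=40000, rng=rng)
    assert np.max(np.abs(A - oracle)) < 0.03


def test_A_rejects_pedigree_loop():
    tab = pd.DataFrame({
        "id": ["a", "b"], "sire": ["", "a"], "dam": ["b", ""],
        "generation": ["F0", "F1"],
    })
    with pytest.raises(HoloquailError):
        Pedigree(tab)


# ---------------------------------------------------------------------------
# G matrix
# ---------------------------------------------------------------------------

def test_G_single_snp_hand_value():
    """p = 0.5, genotype 2: diagonal = (2 - 1)^2 / (2 * 0.25 * ... ) = 2."""
    # two SNPs to satisfy the >= 2 SNP precondition; second is the mirror
    vals = np.array([[2, 0], [0, 2], [1, 1], [1, 1]], dtype=np.int8)
    G = build_G(geno_from(vals))
    # per-SNP p = 0.5; denominator 2 * (0.25 + 0.25) = 1; Z row 0 = (1, -1)
    assert G.values[0, 0] == pytest.approx(2.0)
    assert G.values[0, 1] == pytest.approx(-2.0)


def test_G_mean_diagonal_near_one_in_hwe(rng):
    n, m = 150, 2000
    p = rng.uniform(0.1, 0.9, size=m)
    vals = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    G = build_G(geno_from(vals))
    assert 0.9 < np.mean(np.diag(G.values)) < 1.1


def test_G_loco_excludes_chromosome_and_errors_when_empty():
    vals = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1]], dtype=np.int8)
    geno = geno_from(vals, chroms=[1, 1, 2])
    G = build_G(geno, loco_chrom=2)
    assert G.meta == {"n_markers": 2, "loco_excluded": 2}
    with pytest.raises(HoloquailError, match="fewer than 2"):
        build_G(geno_from(vals[:, :2], chroms=[1, 1]), loco_chrom=1)


def test_G_monomorphic_errors():
    vals = np.zeros((4, 3), dtype=np.int8)
    with pytest.raises(HoloquailError, match="monomorphic"):
        build_G(geno_from(vals))


def test_G_correlates_with_A_for_outbred_founder_lines():
    """With divergent outbred founder lines (the realistic situation), G
    tracks pedigree relationships.  With lines fixed for alternate alleles
    every F1 is identically heterozygous and F2 single-locus genotypes are
    pairwise independent, so no such correlation can exist there."""
    from conftest import small_config
    from holoquail.simdata import simulate_population
    cfg = small_config(
        n_f2=200, n_phenotyped=200, n_snps=2000, n_chromosomes=10,
        chrom_lengths=[100.0] * 10, founder_line_freq=0.8, seed=4242,
    )
    pop = simulate_population(cfg)
    A = build_A(pop.pedigree)
    ids = pop.sample_ids
    G = build_G(pop.genotypes.subset_individuals(ids))
    A_sub = A.align(ids)
    iu = np.triu_indices(len(ids), k=1)
    r = np.corrcoef(A_sub[iu], G.values[iu])[0, 1]
    assert r > 0.5


def test_G_offdiagonal_centers_at_zero_for_fixed_founder_lines(small_pop):
    """Inbred founder lines: E[G_ij] = 0 for every F2 pair by design."""
    ids = small_pop.sample_ids
    G = build_G(small_pop.genotypes.subset_individuals(ids))
    iu = np.triu_indices(len(ids), k=1)
    assert abs(np.mean(G.values[iu])) < 0.02


# ---------------------------------------------------------------------------
# M matrix
# ---------------------------------------------------------------------------

def test_M_identical_profiles_and_unit_mean_diagonal(rng):
    base = rng.uniform(0.0, 1.0, size=(6, 30))
    base[5] = base[4]  # two identical OTU profiles
    base /= base.sum(axis=1, keepdims=True)
    table = AbundanceTable(
        pd.DataFrame(base, index=[f"s{i}" for i in range(6)],
                     columns=[f"o{j}" for j in range(30)]),
        level="otu", relative=True,
    )
    M = build_M(table)
    assert M.values[4, 5] == pytest.approx(M.values[4, 4])
    assert np.mean(np.diag(M.values)) == pytest.approx(1.0, abs=1e-9)


def test_M_drops_constant_columns_with_warning(rng):
    vals = rng.uniform(0.1, 1.0, size=(5, 4))
    vals[:, 0] = 0.25  # constant column
    table = AbundanceTable(
        pd.DataFrame(vals, index=[f"s{i}" for i in range(5)],
                     columns=list("abcd")),
    )
    with pytest.warns(UserWarning, match="constant"):
        M = build_M(table)
    assert M.meta["n_otus"] == 3


def test_M_too_few_variable_otus_errors():
    table = AbundanceTable(
        pd.DataFrame([[0.5, 0.5]] * 3, index=list("xyz"),
                     columns=["a", "b"]),
    )
    with pytest.raises(HoloquailError, match="non-zero variance"):
        build_M(table)


# ---------------------------------------------------------------------------
# Shared properties
# ---------------------------------------------------------------------------

def test_matrices_symmetric_and_near_psd(small_pop):
    A = build_A(small_pop.pedigree)
    ids = small_pop.sample_ids
    G = build_G(small_pop.genotypes.subset_individuals(ids))
    M = build_M(small_pop.otus)
    for mat in (A, G, M):
        v = mat.values
        assert np.allclose(v, v.T, atol=1e-10)
        min_eig = np.linalg.eigvalsh(v).min()
        assert min_eig >= -1e-8
        stab = mat.stabilized()
        assert np.linalg.eigvalsh(stab).min() >= 0
    assert np.all(np.diag(A.values) >= 1.0)
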