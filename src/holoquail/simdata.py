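"""Synthetic F2-cross hologenomic datasets with known ground truth.

Emulates the study design the pipeline is built for: two divergent founder
lines (12 males + 12 females each) crossed to an F1 generation, 17 F1
sires each mated to 2 F1 dams, up to 920 F2 birds of which 758 carry
complete records; ~4k SNPs on 24 linkage groups; 59 bacterial genera
(expanded into ~1.2k OTUs) whose latent values follow an animal model with
test-day and residual effects plus optional QTL; and performance traits
(PU, FI, BWG, with F:G derived) that receive recursive genus effects on
the standardized transformed-abundance scale, so that "lambda in
phenotypic-SD units" is meaningful.

Founder lines are modelled as inbred and fixed for alternate alleles at
every SNP, which makes F1 individuals fully heterozygous and F2 genotype
probabilities exact; gametes recombine without interference (Haldane map
function), matching the linkage-scan HMM.  Latent genus values are mapped
to compositions by exponentiation and per-sample renormalization, so a
Box-Cox transform of the resulting relative abundances is approximately
linearizing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable, GenotypeMatrix, HoloquailError, LinkageMap, Pedigree,
    TaxonomyMap,
)

__all__ = [
    "SimConfig", "GenusParams", "QtlEffect", "TraitParams", "TrueParams",
    "SimPopulation", "default_chrom_lengths", "default_true_params",
    "simulate_pedigree", "simulate_linkage_map", "simulate_genotypes",
    "simulate_microbiota", "simulate_traits", "simulate_population",
    "write_population",
]


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

def default_chrom_lengths(n_chromosomes: int) -> list[float]:
    """Decreasing avian-style map lengths, ~200 cM down to ~20 cM."""
    return [round(x, 1) for x in np.linspace(200.0, 20.0, n_chromosomes)]


@dataclass
class SimConfig:
    """Design of the simulated line cross; defaults follow the study design."""

    n_founders_per_line_per_sex: int = 12
    n_f1_sires: int = 17
    dams_per_sire: int = 2
    n_f2: int = 920
    n_phenotyped: int = 758   # F2 with microbiota + trait records
    n_chromosomes: int = 24
    chrom_lengths: list[float] | None = None
    n_snps: int = 3986
    n_test_days: int = 12
    n_genera: int = 59
    n_otus: int = 1188
    detection_floor: float = 1e-6  # relative abundances below this are zeroed
    #: probability that a founder haplotype carries its line's characteristic
    #: allele; 1.0 = lines fixed for alternate alleles (fully informative F2),
    #: < 1.0 = divergent outbred founder lines
    founder_line_freq: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = default_chrom_lengths(self.n_chromosomes)
        counts = (
            self.n_founders_per_line_per_sex, self.n_f1_sires,
            self.dams_per_sire, self.n_f2, self.n_chromosomes, self.n_snps,
            self.n_test_days, self.n_genera, self.n_otus,
        )
        if any(c <= 0 for c in counts):
            raise HoloquailError("all design counts must be positive")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise HoloquailError("chrom_lengths length != n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise HoloquailError("chromosome lengths must be positive")
        if not (0 < self.n_phenotyped <= self.n_f2):
            raise HoloquailError("n_phenotyped must be in (0, n_f2]")
        if not (0.5 <= self.founder_line_freq <= 1.0):
            raise HoloquailError("founder_line_freq must be in [0.5, 1]")


#: how an additive value is generated: drawn along the pedigree
#: (infinitesimal model; resemblance follows A) or as a sum of genome-wide
#: SNP effects (resemblance follows the realized G)
_ARCHITECTURES = ("pedigree", "markers")


@dataclass
class GenusParams:
    """Latent-scale animal-model parameters of one genus (variances sum ~1)."""

    mu: float
    s2_a: float
    s2_td: float
    s2_e: float
    architecture: str = "pedigree"

    def __post_init__(self) -> None:
        if min(self.s2_a, self.s2_td, self.s2_e) < 0:
            raise HoloquailError("genus variances must be non-negative")
        if self.architecture not in _ARCHITECTURES:
            raise HoloquailError(
                f"unknown genetic architecture {self.architecture!r}"
            )

    @property
    def h2(self) -> float:
        tot = self.s2_a + self.s2_td + self.s2_e
        return self.s2_a / tot if tot > 0 else 0.0


@dataclass
class QtlEffect:
    """Additive/dominance QTL at a map position acting on one genus."""

    chrom: int
    pos_cm: float
    add: float
    dom: float
    genus: str


@dataclass
class TraitParams:
    """One performance trait: affine scale plus unit-variance latent model.

    The latent trait is ``z = td + u + sum_g lambda_g * g_std + e`` where
    ``g_std`` is the standardized log relative abundance of genus ``g``;
    the recorded phenotype is ``mu + scale * z``.  With variances chosen so
    var(z) ~= 1, each ``lambda_g`` is directly in phenotypic-SD units.
    """

    mu: float
    scale: float
    s2_a: float
    s2_td: float
    s2_e: float
    lambdas: dict[str, float] = field(default_factory=dict)
    architecture: str = "pedigree"

    def __post_init__(self) -> None:
        if min(self.s2_a, self.s2_td, self.s2_e) < 0:
            raise HoloquailError("trait variances must be non-negative")
        h2 = self.s2_a / max(self.s2_a + self.s2_td + self.s2_e, 1e-300)
        if not 0 <= h2 <= 1:
            raise HoloquailError("implied trait h2 outside [0, 1]")
        if self.architecture not in _ARCHITECTURES:
            raise HoloquailError(
                f"unknown genetic architecture {self.architecture!r}"
            )


@dataclass
class TrueParams:
    """Ground truth of a simulated population."""

    genus_params: dict[str, GenusParams]
    qtl_effects: list[QtlEffect]
    trait_params: dict[str, TraitParams]

    def __post_init__(self) -> None:
        for q in self.qtl_effects:
            if q.genus not in self.genus_params:
                raise HoloquailError(
                    f"QTL effect targets unknown genus {q.genus!r}"
                )
        for trait, tp in self.trait_params.items():
            for g in tp.lambdas:
                if g not in self.genus_params:
                    raise HoloquailError(
                        f"lambda of trait {trait!r} references unsimulated "
                        f"genus {g!r}"
                    )

    @property
    def genera(self) -> list[str]:
        return list(self.genus_params)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genus_params": {
                g: dataclasses.asdict(p) for g, p in self.genus_params.items()
            },
            "qtl_effects": [dataclasses.asdict(q) for q in self.qtl_effects],
            "trait_params": {
                t: dataclasses.asdict(p) for t, p in self.trait_params.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            genus_params={
                g: GenusParams(**p)
                for g, p in payload["genus_params"].items()
            },
            qtl_effects=[QtlEffect(**q) for q in payload["qtl_effects"]],
            trait_params={
                t: TraitParams(**p)
                for t, p in payload["trait_params"].items()
            },
        )


#: number of genera given a non-zero heritability by default (cf. the 24
#: significantly heritable genera of the emulated study)
_N_HERITABLE = 24


def default_true_params(config: SimConfig, n_qtl: int = 6,
                        qtl_varfrac: float = 0.05) -> TrueParams:
    """Study-condition ground truth.

    The first 24 genera get latent heritabilities spread over 0.04-0.17
    (test-day variance 0.10, total latent variance 1); the remainder are
    environmental only.  ``n_qtl`` QTL are placed mid-chromosome on
    distinct chromosomes, each explaining ``qtl_varfrac`` of the latent
    variance of one heritable genus.  Traits carry h2 0.09-0.12,
    microbiota effects |lambda| <= 0.1 phenotypic SD on a few heritable
    genera, and field-realistic means/SDs (PU in %, FI/BWG in g).
    """
    rng = np.random.default_rng(987654321)  # truth layout, not data noise
    names = [f"Genus_{i + 1:02d}" for i in range(config.n_genera)]
    mus = rng.normal(0.0, 2.0, size=config.n_genera)
    n_her = min(_N_HERITABLE, config.n_genera)
    h2s = np.zeros(config.n_genera)
    h2s[:n_her] = np.linspace(0.17, 0.04, n_her)
    genus_params = {}
    for name, mu, h2 in zip(names, mus, h2s):
        s2_td = 0.10
        genus_params[name] = GenusParams(
            mu=float(mu), s2_a=float(h2), s2_td=s2_td,
            s2_e=float(1.0 - h2 - s2_td),
        )
    # additive QTL: var_add at an F2 locus (p = 1/2) is a^2 / 2
    a = float(np.sqrt(2.0 * qtl_varfrac))
    qtl = []
    for k in range(min(n_qtl, config.n_chromosomes, n_her)):
        chrom = k + 1
        qtl.append(QtlEffect(
            chrom=chrom, pos_cm=round(config.chrom_lengths[k] / 2.0, 1),
            add=a, dom=0.0, genus=names[k],
        ))
    # polymicrobial recursive effects: many heritable genera with small
    # |lambda| <= 0.1, alternating sign, sized so each trait's
    # microbiota-driven variance share (~ sum lambda^2) sits in the same
    # 0.05-0.15 range as its heritability
    def lam_set(magnitudes, offset):
        out = {}
        for j, mag in enumerate(magnitudes):
            i = (offset + j) % n_her
            out[names[i]] = mag if j % 2 == 0 else -mag
        return out

    lam = {
        "PU": lam_set([0.10] * 4 + [0.08] * 4 + [0.06] * 4, offset=2),
        "FI": lam_set([0.10] * 8 + [0.08] * 4, offset=4),
        "BWG": lam_set([0.09] * 4 + [0.07] * 4 + [0.05] * 2, offset=6),
    }
    base = {"PU": (65.0, 6.0, 0.12), "FI": (60.0, 8.0, 0.10),
            "BWG": (30.0, 5.0, 0.09)}
    trait_params = {}
    for trait, (mu, scale, h2) in base.items():
        lams = {g: l for g, l in lam[trait].items() if g in genus_params}
        s2_td = 0.10
        s2_e = 1.0 - h2 - s2_td - sum(l * l for l in lams.values())
        trait_params[trait] = TraitParams(
            mu=mu, scale=scale, s2_a=h2, s2_td=s2_td, s2_e=s2_e,
            lambdas=lams,
        )
    return TrueParams(genus_params, qtl, trait_params)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Three-generation pedigree: founder lines A/B -> F1 -> F2.

    Every F1 has a line-A sire and a line-B dam; F1 matings follow one sire
    x ``dams_per_sire`` dams; F2 are assigned to matings as evenly as
    possible (the emulated design does not state the per-family counts).
    """
    n_matings = config.n_f1_sires * config.dams_per_sire
    if n_matings == 0:
        raise HoloquailError("invalid design: no F1 matings")
    nf = config.n_founders_per_line_per_sex
    rows = []
    for line in "AB":
        for sex, tag in (("M", "M"), ("F", "F")):
            for i in range(nf):
                rows.append({
                    "id": f"{line}{tag}{i + 1:02d}", "sire": "", "dam": "",
                    "generation": "F0", "line": line,
                })
    n_f1 = config.n_f1_sires + n_matings
    a_males = [f"AM{i + 1:02d}" for i in range(nf)]
    b_females = [f"BF{i + 1:02d}" for i in range(nf)]
    f1_ids = []
    for j in range(n_f1):
        ind = f"F1_{j + 1:03d}"
        rows.append({
            "id": ind, "sire": a_males[j % nf], "dam": b_females[j % nf],
            "generation": "F1", "line": "",
        })
        f1_ids.append(ind)
    sires = f1_ids[:config.n_f1_sires]
    dams = f1_ids[config.n_f1_sires:]
    matings = [
        (sires[i], dams[i * config.dams_per_sire + j])
        for i in range(config.n_f1_sires)
        for j in range(config.dams_per_sire)
    ]
    base, extra = divmod(config.n_f2, n_matings)
    k = 0
    for m_idx, (sire, dam) in enumerate(matings):
        n_off = base + (1 if m_idx < extra else 0)
        for _ in range(n_off):
            k += 1
            rows.append({
                "id": f"F2_{k:04d}", "sire": sire, "dam": dam,
                "generation": "F2", "line": "",
            })
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Linkage map and gene dropping
# ---------------------------------------------------------------------------

def simulate_linkage_map(config: SimConfig,
                         rng: np.random.Generator) -> LinkageMap:
    """Markers spread over the chromosomes proportionally to map length."""
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    raw = lengths / lengths.sum() * config.n_snps
    counts = np.maximum(np.floor(raw).astype(int), 2)
    # distribute the remainder to the largest fractional parts
    while counts.sum() < config.n_snps:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > config.n_snps:
        counts[np.argmax(counts)] -= 1
    rows = []
    for c, (n_c, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.uniform(0.0, length, size=n_c))
        for i, p in enumerate(pos):
            rows.append({
                "marker": f"S{c}_{i + 1:03d}", "chrom": c,
                "pos_cm": round(float(p), 3),
            })
    return LinkageMap(pd.DataFrame(rows))


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance (cM), no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_genotypes(pedigree: Pedigree, lmap: LinkageMap,
                       config: SimConfig,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Gene dropping through the pedigree with Haldane recombination.

    Founder lines are fixed for alternate alleles (line A = 0 copies of the
    B allele, line B = 2), so all F1 are heterozygous at every marker and
    F2 genotypes count copies of the line-B allele.
    """
    tab = lmap.table
    m = len(tab)
    # per-interval recombination probabilities; 0.5 across chromosome breaks
    d = np.diff(tab["pos_cm"].to_numpy())
    same = tab["chrom"].to_numpy()[1:] == tab["chrom"].to_numpy()[:-1]
    r = np.where(same, _haldane_r(np.maximum(d, 0.0)), 0.5)

    ped = pedigree.table
    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def gamete(parent: str) -> np.ndarray:
        h0, h1 = haplos[parent]
        switch = rng.random(m - 1) < r
        use_h1 = np.empty(m, dtype=bool)
        use_h1[0] = rng.random() < 0.5
        use_h1[1:] = use_h1[0] ^ np.logical_xor.accumulate(switch)
        return np.where(use_h1, h1, h0)

    geno = np.empty((len(ped), m), dtype=np.int8)
    for i, row in enumerate(ped.itertuples(index=False)):
        if not row.sire and not row.dam:
            line = getattr(row, "line", "") or ("A" if row.id.startswith("A")
                                                else "B")
            f = config.founder_line_freq
            if f >= 1.0:  # lines fixed for alternate alleles
                allele = np.uint8(0) if line == "A" else np.uint8(1)
                h = np.full(m, allele, dtype=np.uint8)
                haplos[row.id] = (h, h)
            else:  # divergent outbred lines
                p_b = 1.0 - f if line == "A" else f
                haplos[row.id] = (
                    (rng.random(m) < p_b).astype(np.uint8),
                    (rng.random(m) < p_b).astype(np.uint8),
                )
        elif row.sire and row.dam:
            haplos[row.id] = (gamete(row.sire), gamete(row.dam))
        else:
            raise HoloquailError(
                f"individual {row.id!r} has exactly one recorded parent"
            )
        geno[i] = haplos[row.id][0] + haplos[row.id][1]
    return GenotypeMatrix(pedigree.ids, lmap, geno)


# ---------------------------------------------------------------------------
# Breeding values (infinitesimal gene dropping along the pedigree)
# ---------------------------------------------------------------------------

def _polygenic_values(pedigree: Pedigree, s2_a: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """(n_pedigree, k) additive values; founders ~ N(0, s2_a), offspring
    mid-parent plus Mendelian-sampling deviation of variance s2_a / 2."""
    parents = pedigree.parent_indices()
    n = len(parents)
    k = len(s2_a)
    sd_f = np.sqrt(s2_a)
    sd_m = np.sqrt(s2_a / 2.0)
    u = np.empty((n, k))
    for i in range(n):
        s, d = parents[i]
        if s < 0 and d < 0:
            u[i] = rng.standard_normal(k) * sd_f
        else:
            u[i] = 0.5 * (u[s] + u[d]) + rng.standard_normal(k) * sd_m
    return u


def _additive_values(pedigree: Pedigree, genotypes: GenotypeMatrix,
                     sample_ids: list[str], params,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_samples, k) additive values honouring each column's architecture.

    "pedigree" columns follow the infinitesimal model along the pedigree;
    "markers" columns are sums of genome-wide SNP effects, rescaled so the
    sample variance equals the requested s2_a.
    """
    s2 = np.array([p.s2_a for p in params])
    ped_pos = {ind: i for i, ind in enumerate(pedigree.ids)}
    u = _polygenic_values(pedigree, s2, rng)[
        [ped_pos[s] for s in sample_ids]]
    marker_cols = [j for j, p in enumerate(params)
                   if p.architecture == "markers"]
    if marker_cols:
        geno_pos = {ind: i for i, ind in enumerate(genotypes.ids)}
        Zc = genotypes.values[[geno_pos[s] for s in sample_ids]].astype(float)
        Zc -= Zc.mean(axis=0)
        for j in marker_cols:
            beta = rng.standard_normal(Zc.shape[1])
            raw = Zc @ beta
            sd = raw.std(ddof=0)
            u[:, j] = raw * (np.sqrt(s2[j]) / sd) if (sd > 0 and s2[j] > 0) \
                else 0.0
    return u


# ---------------------------------------------------------------------------
# Microbiota
# ---------------------------------------------------------------------------

_PHYLA = ("Firmicutes", "Actinobacteria", "Proteobacteria", "Bacteroidetes")


def _qtl_contribution(geno: GenotypeMatrix, truth: TrueParams,
                      genus_index: dict[str, int]) -> np.ndarray:
    """(n_geno, n_genera) latent QTL contributions at the nearest marker."""
    out = np.zeros((geno.n_individuals, len(genus_index)))
    tab = geno.lmap.table
    for q in truth.qtl_effects:
        on_chrom = np.flatnonzero(tab["chrom"].to_numpy() == q.chrom)
        if on_chrom.size == 0:
            raise HoloquailError(f"QTL chromosome {q.chrom} has no markers")
        j = on_chrom[np.argmin(
            np.abs(tab["pos_cm"].to_numpy()[on_chrom] - q.pos_cm))]
        g = geno.values[:, j].astype(float)
        out[:, genus_index[q.genus]] += q.add * (g - 1.0) + q.dom * (g == 1)
    return out


def simulate_microbiota(genotypes: GenotypeMatrix, pedigree: Pedigree,
                        truth: TrueParams, config: SimConfig,
                        rng: np.random.Generator,
                        sample_ids: list[str] | None = None,
                        test_day: pd.Series | None = None,
                        otu_concentration: float = 300.0):
    """Simulate relative abundances; returns (otu table, taxonomy, genus table).

    Per genus the latent value is mu + QTL + pedigree polygenic value +
    test-day effect + residual; samples' latent vectors are exponentiated
    and renormalized to compositions, floored at the detection limit, and
    each genus is split into its OTUs by Dirichlet-proportional draws
    around fixed within-genus weights.
    """
    genera = truth.genera
    gp = [truth.genus_params[g] for g in genera]
    genus_index = {g: i for i, g in enumerate(genera)}
    if sample_ids is None:
        sample_ids = list(pedigree.subset_generation("F2")["id"])
    if test_day is None:
        test_day = pd.Series(
            rng.integers(1, config.n_test_days + 1, size=len(sample_ids)),
            index=sample_ids, name="test_day",
        )
    geno_pos = {ind: i for i, ind in enumerate(genotypes.ids)}
    rows_geno = [geno_pos[s] for s in sample_ids]

    u = _additive_values(pedigree, genotypes, sample_ids, gp, rng)
    qtl = _qtl_contribution(genotypes, truth, genus_index)[rows_geno]
    td_effects = rng.standard_normal((config.n_test_days, len(genera)))
    td_effects *= np.sqrt([p.s2_td for p in gp])
    day_idx = test_day.loc[sample_ids].to_numpy() - 1
    e = rng.standard_normal((len(sample_ids), len(genera)))
    e *= np.sqrt([p.s2_e for p in gp])

    latent = np.array([p.mu for p in gp]) + u + qtl + td_effects[day_idx] + e
    scores = np.exp(np.clip(latent, -30.0, 30.0))
    rel = scores / scores.sum(axis=1, keepdims=True)
    rel[rel < config.detection_floor] = 0.0
    rel /= rel.sum(axis=1, keepdims=True)
    genus_table = AbundanceTable(
        pd.DataFrame(rel, index=sample_ids, columns=genera),
        level="genus", relative=True,
    )

    # OTU expansion: fixed within-genus weights, per-sample Dirichlet noise
    base, extra = divmod(config.n_otus, config.n_genera)
    otu_cols, tax_rows, blocks = [], [], []
    for gi, genus in enumerate(genera):
        k = base + (1 if gi < extra else 0)
        w = rng.dirichlet(np.ones(k))
        gam = rng.gamma(np.maximum(otu_concentration * w, 1e-3),
                        size=(len(sample_ids), k))
        gam /= gam.sum(axis=1, keepdims=True)
        blocks.append(gam * rel[:, gi:gi + 1])
        phylum = _PHYLA[gi % len(_PHYLA)]
        for j in range(k):
            otu = f"OTU_{genus}_{j + 1:02d}"
            otu_cols.append(otu)
            tax_rows.append({
                "otu": otu, "genus": genus, "family": f"Family_{gi + 1:02d}",
                "order": f"Order_{gi % 9 + 1}", "class_": f"Class_{gi % 5 + 1}",
                "phylum": phylum,
            })
    otu_rel = np.hstack(blocks)
    otu_rel /= otu_rel.sum(axis=1, keepdims=True)
    otus = AbundanceTable(
        pd.DataFrame(otu_rel, index=sample_ids, columns=otu_cols),
        level="otu", relative=True,
    )
    taxonomy = TaxonomyMap(pd.DataFrame(tax_rows).set_index("otu"))
    return otus, taxonomy, genus_table, test_day


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

#: assumed total P content of the low-P diet, mg per g feed
P_CONTENT_MG_PER_G = 4.5


def _standardized_log(rel: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardized log abundance with a half-minimum offset."""
    vals = rel.to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        pos = col[col > 0]
        offset = pos.min() / 2.0 if pos.size else 1.0
        vals[:, j] = np.log(np.where(col > 0, col, offset))
    vals -= vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame(vals / sd, index=rel.index, columns=rel.columns)


def simulate_traits(abundances: AbundanceTable, genotypes: GenotypeMatrix,
                    pedigree: Pedigree, truth: TrueParams,
                    config: SimConfig, rng: np.random.Generator,
                    test_day: pd.Series) -> pd.DataFrame:
    """Phenotype table with recursive microbiota effects.

    Latent trait z = test-day + direct polygenic value + sum of
    lambda * standardized log genus abundance + residual; the recorded
    phenotype is ``mu + scale * z``.  Body weights, P intake and P
    excretion are emitted so that the derived traits (BWG = BW15 - BW10,
    F:G = FI/BWG, PU from the P balance) are consistent with the simulated
    PU/FI/BWG values.
    """
    if abundances.level != "genus":
        raise HoloquailError("simulate_traits expects a genus-level table")
    sample_ids = abundances.samples
    g_std = _standardized_log(abundances.data)
    n = len(sample_ids)

    traits = list(truth.trait_params)
    u = _additive_values(
        pedigree, genotypes, sample_ids,
        [truth.trait_params[t] for t in traits], rng,
    )
    day_idx = test_day.loc[sample_ids].to_numpy() - 1

    z = {}
    for j, trait in enumerate(traits):
        tp = truth.trait_params[trait]
        td_eff = rng.standard_normal(config.n_test_days) * np.sqrt(tp.s2_td)
        micro = np.zeros(n)
        for genus, lam in tp.lambdas.items():
            if genus not in g_std.columns:
                raise HoloquailError(
                    f"lambda of {trait!r} references genus {genus!r} absent "
                    "from the abundance table"
                )
            micro += lam * g_std[genus].to_numpy()
        e = rng.standard_normal(n) * np.sqrt(tp.s2_e)
        z[trait] = td_eff[day_idx] + u[:, j] + micro + e

    def scaled(trait):
        tp = truth.trait_params[trait]
        return tp.mu + tp.scale * z[trait]

    pu = scaled("PU") if "PU" in z else np.full(n, np.nan)
    fi = scaled("FI") if "FI" in z else np.full(n, np.nan)
    bwg = scaled("BWG") if "BWG" in z else np.full(n, np.nan)
    fi = np.maximum(fi, 1.0)
    bwg = np.maximum(bwg, 1.0)
    pu = np.clip(pu, 1.0, 99.0)
    bw10 = 50.0 + rng.standard_normal(n) * 4.0
    p_intake = fi * P_CONTENT_MG_PER_G
    p_excretion = p_intake * (1.0 - pu / 100.0) + rng.standard_normal(n) * 0.2
    p_excretion = np.clip(p_excretion, 0.0, p_intake)
    out = pd.DataFrame({
        "id": sample_ids,
        "test_day": test_day.loc[sample_ids].to_numpy(),
        "BW10": bw10,
        "BW15": bw10 + bwg,
        "FI": fi,
        "P_intake": p_intake,
        "P_excretion": p_excretion,
        "BWG": bwg,
        "FG": fi / bwg,
        "PU": 100.0 * (p_intake - p_excretion) / p_intake,
    })
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimPopulation:
    """One simulated dataset: all tables share individual identifiers."""

    config: SimConfig
    truth: TrueParams
    pedigree: Pedigree
    lmap: LinkageMap
    genotypes: GenotypeMatrix
    otus: AbundanceTable
    taxonomy: TaxonomyMap
    genus_abundances: AbundanceTable
    phenotypes: pd.DataFrame
    test_day: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.phenotypes["id"])


def simulate_population(config: SimConfig,
                        truth: TrueParams | None = None) -> SimPopulation:
    """Generate a complete dataset; reproducible for a fixed config.seed."""
    if truth is None:
        truth = default_true_params(config)
    rng = np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config)
    lmap = simulate_linkage_map(config, rng)
    genotypes = simulate_genotypes(pedigree, lmap, config, rng)
    f2 = list(pedigree.subset_generation("F2")["id"])
    if config.n_phenotyped < len(f2):
        chosen = rng.choice(len(f2), size=config.n_phenotyped, replace=False)
        sample_ids = [f2[i] for i in np.sort(chosen)]
    else:
        sample_ids = f2
    otus, taxonomy, genus_table, test_day = simulate_microbiota(
        genotypes, pedigree, truth, config, rng, sample_ids=sample_ids,
    )
    phenotypes = simulate_traits(
        genus_table, genotypes, pedigree, truth, config, rng, test_day,
    )
    return SimPopulation(
        config=config, truth=truth, pedigree=pedigree, lmap=lmap,
        genotypes=genotypes, otus=otus, taxonomy=taxonomy,
        genus_abundances=genus_table, phenotypes=phenotypes,
        test_day=test_day,
    )


def write_population(pop: SimPopulation, outdir: str | Path) -> None:
    """Write every table of a simulated population as TSV/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop.pedigree.write_tsv(out / "pedigree.tsv")
    pop.lmap.write_tsv(out / "map.tsv")
    pop.genotypes.write_tsv(out / "genotypes.tsv")
    pop.genotypes.write_plink(out / "genotypes", pop.pedigree)
    pop.otus.write_tsv(out / "otu_abundance.tsv")
    pop.genus_abundances.write_tsv(out / "genus_abundance.tsv")
    pop.taxonomy.write_tsv(out / "taxonomy.tsv")
    pop.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    pop.truth.to_json(out / "truth.json")
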