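"""F2 linkage mapping of transformed genus abundances.

Stages: (1) hidden-Markov genotype-class probabilities (AA/AB/BB) on a
cM grid, with Haldane transitions and a genotyping-error emission — the
inbred-line F2 model, exact here because the simulated founder lines are
fixed for alternate alleles (externally computed probability grids can be
supplied instead); (2) a Haley-Knott regression scan of the phenotype on
the additive score P(BB) - P(AA) and dominance score P(AB) with test-day
dummy covariates, LOD = (n/2) log10(RSS0/RSS1); (3) permutation
genome-wide thresholds (phenotype and covariate rows permuted jointly
against the genotype probabilities); (4) LOD-drop support intervals; and
(5) single-marker mixed-model association within a support interval using
a leave-one-chromosome-out genomic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MISSING, GenotypeMatrix, HoloquailError, LinkageMap, RelationshipMatrix,
    test_day_design,
)
from .mixedmodel import ModelSpec, VarComp, reml_fit

__all__ = [
    "GenoProb", "calc_genoprobs", "scan_hk", "permute_thresholds",
    "SupportInterval", "support_interval", "snp_assoc_loco",
]

_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def _haldane_r(d_cm):
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _transition(r: float) -> np.ndarray:
    """F2 genotype-class transition matrix over one interval (two meioses)."""
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


@dataclass
class GenoProb:
    """Per-individual genotype-class probabilities on an evaluation grid."""

    ids: list[str]
    positions: pd.DataFrame      # columns: chrom, pos_cm, marker ("" if none)
    probs: np.ndarray            # (n_individuals, n_positions, 3)
    step: float
    error_prob: float

    def chrom_index(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.positions["chrom"].to_numpy() == chrom)


def calc_genoprobs(geno: GenotypeMatrix, lmap: LinkageMap | None = None,
                   step: float = 1.0,
                   error_prob: float = 1e-4) -> GenoProb:
    """Forward-backward genotype probabilities on a ``step``-cM grid.

    The grid spans 0 to the last marker of each chromosome and always
    includes the typed marker positions.  At positions with no informative
    flanking data the posterior equals the 1:2:1 F2 segregation prior.
    """
    if lmap is None:
        lmap = geno.lmap
    if list(lmap.table["marker"]) != list(geno.lmap.table["marker"]):
        # accept any map covering exactly the genotyped markers, in order
        raise HoloquailError("linkage map does not match the genotyped markers")
    n = geno.n_individuals
    pos_frames, prob_blocks = [], []
    for chrom in lmap.chromosomes:
        sub = lmap.chrom_slice(chrom)
        marker_pos = sub["pos_cm"].to_numpy(dtype=float)
        cols = sub.index.to_numpy()
        obs = geno.values[:, cols]
        grid = np.arange(0.0, marker_pos.max() + step / 2.0, step)
        eval_pos = np.unique(np.round(np.concatenate([grid, marker_pos]), 9))
        marker_at = np.full(eval_pos.size, -1)
        for j, mp in enumerate(np.round(marker_pos, 9)):
            marker_at[np.searchsorted(eval_pos, mp)] = j

        # emission probabilities (n, L, 3); markers sharing a grid point
        # multiply their emissions
        emis = np.ones((n, eval_pos.size, 3))
        for j, mp in enumerate(np.round(marker_pos, 9)):
            t = int(np.searchsorted(eval_pos, mp))
            g = obs[:, j]
            typed = g != MISSING
            e = np.full((n, 3), 1.0)
            e[typed] = error_prob / 2.0
            e[typed, g[typed]] = 1.0 - error_prob
            emis[:, t, :] *= e

        trans = [
            _transition(float(_haldane_r(d)))
            for d in np.diff(eval_pos)
        ]
        # forward
        alpha = np.empty((n, eval_pos.size, 3))
        a = _F2_PRIOR * emis[:, 0, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0, :] = a
        for t in range(1, eval_pos.size):
            a = (a @ trans[t - 1]) * emis[:, t, :]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, t, :] = a
        # backward
        b = np.ones((n, 3))
        post = np.empty_like(alpha)
        post[:, -1, :] = alpha[:, -1, :]
        for t in range(eval_pos.size - 2, -1, -1):
            b = (b * emis[:, t + 1, :]) @ trans[t].T
            b /= b.sum(axis=1, keepdims=True)
            p = alpha[:, t, :] * b
            post[:, t, :] = p / p.sum(axis=1, keepdims=True)

        markers = np.where(
            marker_at >= 0,
            sub["marker"].to_numpy(object)[np.maximum(marker_at, 0)], "",
        )
        pos_frames.append(pd.DataFrame({
            "chrom": chrom, "pos_cm": eval_pos, "marker": markers,
        }))
        prob_blocks.append(post)
    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProb(list(geno.ids), positions, probs, step, error_prob)


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

def _covariate_basis(n: int, covariates) -> np.ndarray:
    """Orthonormal basis of [1, covariates]; warns on collinear columns."""
    X0 = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X0 = np.hstack([X0, C])
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        warnings.warn(
            f"covariate matrix is rank deficient ({rank} < {X0.shape[1]}); "
            "redundant columns are dropped"
        )
    q, r = np.linalg.qr(X0)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def _scores(probs: GenoProb) -> np.ndarray:
    """(n, L, 2) additive (P(BB) - P(AA)) and dominance (P(AB)) scores."""
    add = probs.probs[:, :, 2] - probs.probs[:, :, 0]
    dom = probs.probs[:, :, 1]
    return np.stack([add, dom], axis=2)


def _lod_from_scores(S, Q, ry, rss0, n):
    """Batched 2-df regression improvement over the covariate-only null.

    ``S`` is (n, L, 2); returns (lod (L,), effects (L, 2))."""
    n_obs, L, _ = S.shape
    flat = S.reshape(n_obs, L * 2)
    MS = flat - Q @ (Q.T @ flat)
    MS = MS.reshape(n_obs, L, 2)
    c = np.einsum("nlp,n->lp", MS, ry)
    Gm = np.einsum("nlp,nlq->lpq", MS, MS)
    g00, g01, g11 = Gm[:, 0, 0], Gm[:, 0, 1], Gm[:, 1, 1]
    det = g00 * g11 - g01 * g01
    tiny = 1e-12 * np.maximum(g00 * g11, 1.0)
    eff = np.zeros((L, 2))
    red = np.zeros(L)
    ok = det > tiny
    eff[ok, 0] = (c[ok, 0] * g11[ok] - c[ok, 1] * g01[ok]) / det[ok]
    eff[ok, 1] = (c[ok, 1] * g00[ok] - c[ok, 0] * g01[ok]) / det[ok]
    red[ok] = c[ok, 0] * eff[ok, 0] + c[ok, 1] * eff[ok, 1]
    # dominance (or both) scores degenerate: fall back to additive only
    deg = ~ok & (g00 > tiny)
    eff[deg, 0] = c[deg, 0] / g00[deg]
    red[deg] = c[deg, 0] ** 2 / g00[deg]
    red = np.clip(red, 0.0, rss0 * (1 - 1e-14))
    lod = 0.5 * n * np.log10(rss0 / (rss0 - red))
    return lod, eff


def scan_hk(probs: GenoProb, y, covariates=None) -> pd.DataFrame:
    """Haley-Knott regression scan; one row per grid position.

    At each position the phenotype is regressed on intercept + covariates
    + additive and dominance scores; ``lod = (n/2) log10(RSS0/RSS1)``
    against the covariate-only null.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != len(probs.ids):
        raise HoloquailError("phenotype length does not match genoprobs")
    Q = _covariate_basis(n, covariates)
    ry = y - Q @ (Q.T @ y)
    rss0 = float(ry @ ry)
    lod, eff = _lod_from_scores(_scores(probs), Q, ry, rss0, n)
    out = probs.positions.copy()
    out["lod"] = lod
    out["add_effect"] = eff[:, 0]
    out["dom_effect"] = eff[:, 1]
    return out


def permute_thresholds(probs: GenoProb, y, covariates=None,
                       n_perm: int = 10000, levels=(0.05, 0.10),
                       rng=None):
    """Genome-wide significance thresholds by permutation.

    Phenotype and covariate rows are permuted jointly against the genotype
    probabilities (implemented by inversely permuting the probability
    scores, which yields identical LOD profiles); thresholds are the
    empirical (1 - level) quantiles of the per-permutation maximum LOD.
    Returns ``(thresholds dict, max-LOD array)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; thresholds will be noisy")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Q = _covariate_basis(n, covariates)
    ry = y - Q @ (Q.T @ y)
    rss0 = float(ry @ ry)
    S = _scores(probs)
    L = S.shape[1]
    # permuting (y, C) jointly by pi relabels rows: the permuted residual
    # is ry[pi] (ry is orthogonal to the covariate basis), so only the
    # cross-products S'ry[pi] and Q[pi]'S change per permutation.
    flat = np.ascontiguousarray(S.reshape(n, L * 2))
    StS = np.einsum("nlp,nlq->lpq", S, S)
    maxlod = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(n)
        c = (ry[idx] @ flat).reshape(L, 2)
        QtS = Q[idx].T @ flat                       # (k, 2L)
        QtS3 = QtS.reshape(-1, L, 2)
        Gm = StS - np.einsum("klp,klq->lpq", QtS3, QtS3)
        g00, g01, g11 = Gm[:, 0, 0], Gm[:, 0, 1], Gm[:, 1, 1]
        det = g00 * g11 - g01 * g01
        tiny = 1e-12 * np.maximum(g00 * g11, 1.0)
        red = np.zeros(L)
        ok = det > tiny
        red[ok] = (c[ok, 0] ** 2 * g11[ok]
                   - 2 * c[ok, 0] * c[ok, 1] * g01[ok]
                   + c[ok, 1] ** 2 * g00[ok]) / det[ok]
        deg = ~ok & (g00 > tiny)
        red[deg] = c[deg, 0] ** 2 / g00[deg]
        red = np.clip(red, 0.0, rss0 * (1 - 1e-14))
        maxlod[i] = 0.5 * n * np.log10(rss0 / (rss0 - red.max()))
    thresholds = {
        float(level): float(np.quantile(maxlod, 1.0 - level))
        for level in levels
    }
    return thresholds, maxlod


# ---------------------------------------------------------------------------
# Support intervals
# ---------------------------------------------------------------------------

@dataclass
class SupportInterval:
    """LOD-drop support interval around a scan peak."""

    chrom: object
    peak_pos: float
    peak_lod: float
    low: float
    high: float
    drop: float


def support_interval(scan: pd.DataFrame, drop: float = 1.5,
                     chrom=None, threshold: float | None = None):
    """LOD-drop interval around the (leftmost) peak.

    The interval is the contiguous run of grid points around the peak with
    LOD above ``peak - drop``, extended by one grid point past the
    crossing on each side and clipped at the chromosome ends.  With
    ``threshold`` given, returns None when no position reaches it.
    """
    if chrom is None:
        peak_row = scan.loc[scan["lod"].idxmax()]
        chrom = peak_row["chrom"]
    sub = scan[scan["chrom"] == chrom].reset_index(drop=True)
    lod = sub["lod"].to_numpy()
    pos = sub["pos_cm"].to_numpy()
    k = int(np.argmax(lod))  # argmax returns the leftmost maximum
    if threshold is not None and lod[k] < threshold:
        return None
    cut = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo] > cut:
        lo -= 1
    hi = k
    while hi < lod.size - 1 and lod[hi] > cut:
        hi += 1
    return SupportInterval(
        chrom=chrom, peak_pos=float(pos[k]), peak_lod=float(lod[k]),
        low=float(pos[lo]), high=float(pos[hi]), drop=drop,
    )


# ---------------------------------------------------------------------------
# Within-interval single-marker mixed-model association (LOCO)
# ---------------------------------------------------------------------------

def snp_assoc_loco(y, snps_in_si: GenotypeMatrix, covariates,
                   G_loco: RelationshipMatrix | None,
                   alpha: float = 0.05,
                   variance_components: tuple[float, float] | None = None
                   ) -> pd.DataFrame:
    """Per-SNP allele-count association with a polygenic LOCO term.

    The polygenic and residual variances are estimated once under the
    covariates-only null model (or fixed via ``variance_components``);
    each SNP's allele count is then tested by generalized least squares
    at those components (Wald test).  Monomorphic SNPs are skipped; no
    multiple-testing correction is applied.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X0 = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X0 = np.hstack([X0, C])

    K = (G_loco.align(snps_in_si.ids) if G_loco is not None
         else np.eye(n))
    if variance_components is None:
        spec = ModelSpec(y, X0, [
            VarComp("polygenic", K), VarComp("residual", np.eye(n)),
        ])
        null = reml_fit(spec)
        s2_u, s2_e = null["polygenic"], null["residual"]
    else:
        s2_u, s2_e = variance_components
    V = s2_u * K + s2_e * np.eye(n)
    Vi = np.linalg.inv(V)

    rows = []
    for j, marker in enumerate(snps_in_si.lmap.table["marker"]):
        g = snps_in_si.values[:, j].astype(float)
        obs = g != MISSING
        g[~obs] = g[obs].mean() if obs.any() else 0.0
        if np.var(g) < 1e-12:
            continue
        X = np.hstack([X0, g[:, None]])
        XtVi = X.T @ Vi
        XtViX_inv = np.linalg.inv(XtVi @ X)
        beta = XtViX_inv @ (XtVi @ y)
        se = float(np.sqrt(XtViX_inv[-1, -1]))
        b = float(beta[-1])
        p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan
        rows.append({
            "marker": marker,
            "chrom": snps_in_si.lmap.table["chrom"].iloc[j],
            "pos_cm": snps_in_si.lmap.table["pos_cm"].iloc[j],
            "effect": b, "se": se, "p": p,
            "significant": bool(p <= alpha),
        })
    return pd.DataFrame(rows)
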