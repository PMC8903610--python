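"""From raw abundance and weight/intake tables to analysis inputs.

Covers: closure to relative abundances, OTU -> genus aggregation with
"unclassified" family buckets, the mean-abundance taxon filters (genus
rule: mean >= 0.01%; OTU rule: mean > 0.0001%), per-genus Box-Cox
transformation by profile-likelihood grid search, and derivation of the
four performance traits (BWG, F:G, PU) from body weights, feed intake and
the P balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceTable, HoloquailError, TaxonomyMap

__all__ = [
    "relative_abundance", "aggregate_to_genus", "filter_taxa",
    "BoxCoxFit", "fit_boxcox", "transform_genera",
    "derive_performance_traits",
    "GENUS_MIN_MEAN", "OTU_MIN_MEAN", "DEFAULT_GRID",
]

#: genus filter: keep mean relative abundance >= 0.01% (inclusive)
GENUS_MIN_MEAN = 1e-4
#: OTU filter: keep mean relative abundance strictly > 0.0001%
OTU_MIN_MEAN = 1e-6
#: Box-Cox lambda grid: estimates are expected down to -2; the upper bound
#: is the symmetric counterpart
DEFAULT_GRID = (-2.0, 2.0, 0.005)


def relative_abundance(counts: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total (idempotent on relative input)."""
    vals = counts.data.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.data.index[int(np.argmin(totals))]
        raise HoloquailError(f"sample {bad!r} has zero total abundance")
    rel = pd.DataFrame(vals / totals[:, None], index=counts.data.index,
                       columns=counts.data.columns)
    return AbundanceTable(rel, level=counts.level, relative=True)


def aggregate_to_genus(otus: AbundanceTable, tax: TaxonomyMap) -> AbundanceTable:
    """Sum member-OTU values per genus; totals are preserved.

    OTUs without a genus assignment (empty or "unclassified") are pooled
    into per-family ``unclassified_<family>`` buckets.
    """
    missing = [o for o in otus.taxa if o not in tax.table.index]
    if missing:
        raise HoloquailError(
            f"{len(missing)} OTU(s) missing from the taxonomy, e.g. "
            f"{missing[0]!r}"
        )
    sub = tax.table.loc[otus.taxa]
    genus = sub["genus"].fillna("").astype(str)
    family = sub["family"].fillna("").astype(str)
    unassigned = genus.str.lower().isin(("", "unclassified", "nan"))
    labels = np.where(
        unassigned,
        "unclassified_" + np.where(family == "", "unknown", family),
        genus,
    )
    out = otus.data.T.groupby(pd.Index(labels, name="genus")).sum().T
    return AbundanceTable(out, level="genus", relative=otus.relative)


def filter_taxa(table: AbundanceTable, min_mean: float | None = None,
                strict: bool | None = None):
    """Keep taxa by mean relative abundance; returns (table, report).

    Genus-level tables use the inclusive rule ``mean >= min_mean``
    (default 0.01%); OTU-level tables use the strict rule
    ``mean > min_mean`` (default 0.0001%).  ``strict`` overrides the
    level-based choice.
    """
    if min_mean is None:
        min_mean = OTU_MIN_MEAN if table.level == "otu" else GENUS_MIN_MEAN
    if strict is None:
        strict = table.level == "otu"
    means = table.data.mean(axis=0)
    keep = means > min_mean if strict else means >= min_mean
    if not keep.any():
        raise HoloquailError("no taxa pass the abundance filter")
    report = {
        "n_input": len(keep), "kept": int(keep.sum()),
        "removed": int((~keep).sum()), "threshold": float(min_mean),
        "rule": ">" if strict else ">=",
    }
    # rows no longer sum to 1 once taxa are removed, so the closure flag
    # is dropped; values remain fractions of the original totals
    out = AbundanceTable(table.data.loc[:, keep], level=table.level,
                         relative=False)
    return out, report


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxFit:
    """Grid-search Box-Cox fit of one genus."""

    genus: str
    lam: float
    grid: tuple[float, float, float]
    loglik: float
    transformed: np.ndarray


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """Two-branch power transform: (y^lam - 1)/lam, or log y at lam = 0.

    Computed as expm1(lam * log y)/lam, which stays accurate (and strictly
    increasing) down to arbitrarily small nonzero lam.
    """
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.log(y)
    return np.expm1(lam * np.log(y)) / lam


def _boxcox_llf_grid(lams: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normal profile log-likelihood of the transform over a lambda grid.

    llf(lam) = (lam - 1) sum(log y) - n/2 log(var(f_lam(y))), evaluated for
    all grid points at once (the transform is computed as exp(lam log y)).
    """
    logy = np.log(y)
    n = y.size
    lam_col = lams[:, None]
    with np.errstate(over="ignore"):
        z = np.where(lam_col == 0.0, logy,
                     (np.exp(lam_col * logy) - 1.0) / np.where(
                         lam_col == 0.0, 1.0, lam_col))
    var = z.var(axis=1, ddof=0)
    return (lams - 1.0) * logy.sum() - 0.5 * n * np.log(var)


def offset_zeros(y: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest positive value (rank-preserving)."""
    y = np.asarray(y, dtype=float).copy()
    pos = y[y > 0]
    if pos.size == 0:
        raise HoloquailError("vector is all zeros; Box-Cox undefined")
    y[y == 0] = pos.min() / 2.0
    return y


def fit_boxcox(y: np.ndarray, grid: tuple[float, float, float] = DEFAULT_GRID,
               genus: str = "") -> BoxCoxFit:
    """Profile-likelihood grid search for the Box-Cox parameter.

    Zeros are offset to half the minimum positive value first; negative
    values are an error.  The objective is the normal profile
    log-likelihood including the Jacobian term ``(lam - 1) sum(log y)``.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise HoloquailError("Box-Cox requires non-negative input")
    y = offset_zeros(y)
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2.0, step)
    llf = _boxcox_llf_grid(lams, y)
    best = int(np.argmax(llf))
    lam = float(lams[best])
    return BoxCoxFit(
        genus=genus, lam=lam, grid=grid, loglik=float(llf[best]),
        transformed=boxcox_transform(y, lam),
    )


def transform_genera(table: AbundanceTable,
                     grid: tuple[float, float, float] = DEFAULT_GRID):
    """Box-Cox transform every genus column; returns (values, lambdas).

    ``values`` is a samples x genera DataFrame of transformed abundances;
    ``lambdas`` summarizes the per-genus fits.
    """
    cols, lam_rows = {}, []
    for genus in table.data.columns:
        fit = fit_boxcox(table.data[genus].to_numpy(), grid=grid, genus=genus)
        cols[genus] = fit.transformed
        lam_rows.append({"genus": genus, "lambda": fit.lam,
                         "loglik": fit.loglik})
    values = pd.DataFrame(cols, index=table.data.index)
    return values, pd.DataFrame(lam_rows).set_index("genus")


# ---------------------------------------------------------------------------
# Performance traits
# ---------------------------------------------------------------------------

def derive_performance_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive BWG, F:G and PU from the raw weight/intake/P-balance columns.

    BWG = BW15 - BW10; F:G = FI / BWG; PU = 100 (P_intake - P_excretion) /
    P_intake (percentage of ingested P retained).  Rows with BWG <= 0 or
    P_intake <= 0 get missing derived values and a warning.
    """
    required = ("BW10", "BW15", "FI", "P_intake", "P_excretion")
    absent = [c for c in required if c not in raw.columns]
    if absent:
        raise HoloquailError(f"phenotype table lacks columns {absent}")
    out = raw.copy()
    out["BWG"] = out["BW15"] - out["BW10"]
    bad_bwg = out["BWG"] <= 0
    out["FG"] = np.where(bad_bwg, np.nan, out["FI"] / out["BWG"].where(~bad_bwg))
    bad_p = out["P_intake"] <= 0
    out["PU"] = np.where(
        bad_p, np.nan,
        100.0 * (out["P_intake"] - out["P_excretion"])
        / out["P_intake"].where(~bad_p),
    )
    n_bad = int(bad_bwg.sum() + bad_p.sum())
    if n_bad:
        warnings.warn(
            f"{int(bad_bwg.sum())} row(s) with BWG <= 0 and "
            f"{int(bad_p.sum())} with P intake <= 0: derived traits set to "
            "missing"
        )
    return out
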