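"""Two-step hologenomic prediction (MBLUP, GBLUP, microbiota-mediated GBLUP).

Step one fits the microbial mixed model y = mu + td + k + e with
k ~ N(0, M s2_k); the BLUP k-hat is the microbiota effect of each animal
and s2_k / (s2_k + s2_td + s2_e) its "microbiability".  Step two treats
k-hat as an observation in the genomic model k-hat = mu + m + e with
m ~ N(0, G s2_m), whose ratio h2_k = s2_m / (s2_m + s2_e) measures how
heritable the microbiota-mediated part of the trait is.

Prediction accuracy is assessed by repeated random-split cross-validation
with variance components fixed at their full-data estimates: validation
animals' effects are predicted through the covariance linking them to the
training animals (partitioned BLUP), and accuracy is the Pearson
correlation between predicted effects and observed phenotypes in the
validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HoloquailError, RelationshipMatrix, test_day_design
from .mixedmodel import FitResult, ModelSpec, VarComp, reml_fit

__all__ = [
    "MicrobiotaEffects", "MediatedGenomicFit", "PredictionResult",
    "fit_mblup", "fit_mediated_gblup", "cross_validate",
]


@dataclass
class MicrobiotaEffects:
    """Microbial mixed-model fit of one trait."""

    trait: str
    k_hat: pd.Series
    s2_k: float
    s2_td: float
    s2_e: float
    microbiability: float
    lrt_D: float
    lrt_p: float
    fit: FitResult = field(repr=False, default=None)


@dataclass
class MediatedGenomicFit:
    """Genomic fit of the estimated microbiota effects."""

    trait: str
    m_hat: pd.Series
    s2_m: float
    s2_e: float
    h2_k: float
    lrt_D: float
    lrt_p: float
    fit: FitResult = field(repr=False, default=None)


@dataclass
class PredictionResult:
    """Cross-validated accuracy of one predictor for one trait."""

    trait: str
    predictor: str
    accuracies: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_reps: int
    train_frac: float
    seed: int

    @classmethod
    def from_accuracies(cls, trait, predictor, acc, train_frac, seed):
        acc = np.asarray(acc, dtype=float)
        return cls(
            trait=trait, predictor=predictor, accuracies=acc,
            mean=float(acc.mean()),
            ci_low=float(np.quantile(acc, 0.025)),
            ci_high=float(np.quantile(acc, 0.975)),
            n_reps=acc.size, train_frac=train_frac, seed=seed,
        )


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_mblup(trait, M: RelationshipMatrix, test_day, ids=None,
              trait_name: str = "trait", method: str = "ai"
              ) -> MicrobiotaEffects:
    """Fit y = mu + td + k + e with k ~ N(0, M s2_k); LRT on the k term."""
    y = np.asarray(trait, dtype=float).ravel()
    if ids is None:
        ids = M.ids
    if len(ids) != y.size:
        raise HoloquailError("trait vector does not match M individuals")
    M_sub = M.align(list(ids))
    n = y.size
    Z = test_day_design(test_day)
    H = Z @ Z.T
    full = reml_fit(ModelSpec(y, np.ones((n, 1)), [
        VarComp("microbiota", M_sub), VarComp("test_day", H),
        VarComp("residual", np.eye(n)),
    ]), method=method)
    red = reml_fit(ModelSpec(y, np.ones((n, 1)), [
        VarComp("test_day", H), VarComp("residual", np.eye(n)),
    ]), method=method)
    s2_k, s2_td, s2_e = full["microbiota"], full["test_day"], full["residual"]
    D = max(0.0, 2.0 * (full.loglik - red.loglik))
    return MicrobiotaEffects(
        trait=trait_name,
        k_hat=pd.Series(full.blups["microbiota"], index=list(ids)),
        s2_k=s2_k, s2_td=s2_td, s2_e=s2_e,
        microbiability=s2_k / (s2_k + s2_td + s2_e),
        lrt_D=D, lrt_p=float(stats.chi2.sf(D, 1)), fit=full,
    )


def fit_mediated_gblup(khat, G: RelationshipMatrix, ids=None,
                       trait_name: str = "trait", method: str = "ai"
                       ) -> MediatedGenomicFit:
    """Fit k-hat = mu + m + e with m ~ N(0, G s2_m); h2_k and LRT."""
    if isinstance(khat, MicrobiotaEffects):
        ids = list(khat.k_hat.index)
        y = khat.k_hat.to_numpy(dtype=float)
        trait_name = khat.trait
    else:
        y = np.asarray(khat, dtype=float).ravel()
        if ids is None:
            ids = G.ids
    if np.var(y) < 1e-14:
        raise HoloquailError("degenerate k-hat: no variation to model")
    G_sub = G.align(list(ids))
    n = y.size
    full = reml_fit(ModelSpec(y, np.ones((n, 1)), [
        VarComp("genomic", G_sub), VarComp("residual", np.eye(n)),
    ]), method=method)
    red = reml_fit(ModelSpec(y, np.ones((n, 1)), [
        VarComp("residual", np.eye(n)),
    ]), method=method)
    s2_m, s2_e = full["genomic"], full["residual"]
    D = max(0.0, 2.0 * (full.loglik - red.loglik))
    return MediatedGenomicFit(
        trait=trait_name,
        m_hat=pd.Series(full.blups["genomic"], index=list(ids)),
        s2_m=s2_m, s2_e=s2_e, h2_k=s2_m / (s2_m + s2_e),
        lrt_D=D, lrt_p=float(stats.chi2.sf(D, 1)), fit=full,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _blup_predict(y_train, K, train, val, s2_u, s2_extra_kernels,
                  X_train=None):
    """Partitioned-BLUP prediction of validation effects.

    ``K`` is the full relationship matrix (numpy), ``s2_extra_kernels`` a
    list of (variance, kernel restricted to train) pairs completing V.
    """
    V = s2_u * K[np.ix_(train, train)]
    for s2, kern in s2_extra_kernels:
        V = V + s2 * kern
    X = X_train if X_train is not None else np.ones((len(train), 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y_train))
    resid = y_train - X @ beta
    w = Vi @ resid
    return s2_u * K[np.ix_(val, train)] @ w, w, beta


def cross_validate(y, test_day, M: RelationshipMatrix | None = None,
                   G: RelationshipMatrix | None = None, ids=None,
                   predictor: str = "gblup", n_reps: int = 500,
                   train_frac: float = 0.8, seed: int = 0,
                   refit_khat_per_fold: bool = True,
                   trait_name: str = "trait") -> PredictionResult:
    """Repeated random-split cross-validation of one predictor.

    ``predictor`` is ``"mblup"`` (microbial BLUP via M), ``"gblup"``
    (genomic BLUP via G) or ``"mediated"`` (microbiota effects estimated
    in the training fold via M, then genomically predicted via G).
    Variance components are estimated once on the full data and held
    fixed across repetitions.  Accuracy per repetition is the Pearson
    correlation of predicted effects with observed phenotypes in the
    ~``1 - train_frac`` validation split.
    """
    if predictor not in ("mblup", "gblup", "mediated"):
        raise HoloquailError(f"unknown predictor {predictor!r}")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    n_val = n - int(round(n * train_frac))
    if n_val < 10:
        raise HoloquailError(
            f"validation set of {n_val} animals is too small (< 10)"
        )
    if ids is None:
        ids = (M or G).ids
    td = np.asarray(pd.Categorical(list(test_day)).codes)
    Z = np.eye(td.max() + 1)[td]

    # full-data variance components, fixed across repetitions
    if predictor in ("mblup", "mediated"):
        if M is None:
            raise HoloquailError("predictor requires M")
        mfit = fit_mblup(y, M, test_day, ids=ids, trait_name=trait_name)
        M_full = M.align(list(ids))
    if predictor in ("gblup", "mediated"):
        if G is None:
            raise HoloquailError("predictor requires G")
        G_full = G.align(list(ids))
    if predictor == "gblup":
        gfit = reml_fit(ModelSpec(y, np.ones((n, 1)), [
            VarComp("genomic", G_full), VarComp("test_day", Z @ Z.T),
            VarComp("residual", np.eye(n)),
        ]))
    if predictor == "mediated":
        med = fit_mediated_gblup(mfit, G)

    rng = np.random.default_rng(seed)
    acc = np.empty(n_reps)
    for rep in range(n_reps):
        perm = rng.permutation(n)
        train = np.sort(perm[:n - n_val])
        val = np.sort(perm[n - n_val:])
        Zt = Z[train]
        if predictor == "mblup":
            pred, _, _ = _blup_predict(
                y[train], M_full, train, val, mfit.s2_k,
                [(mfit.s2_td, Zt @ Zt.T),
                 (mfit.s2_e, np.eye(train.size))],
            )
        elif predictor == "gblup":
            pred, _, _ = _blup_predict(
                y[train], G_full, train, val, gfit["genomic"],
                [(gfit["test_day"], Zt @ Zt.T),
                 (gfit["residual"], np.eye(train.size))],
            )
        else:  # mediated
            if refit_khat_per_fold:
                # training-fold microbiota effects (components fixed)
                _, w, beta = _blup_predict(
                    y[train], M_full, train, train, mfit.s2_k,
                    [(mfit.s2_td, Zt @ Zt.T),
                     (mfit.s2_e, np.eye(train.size))],
                )
                k_train = mfit.s2_k * M_full[np.ix_(train, train)] @ w
            else:
                k_train = mfit.k_hat.to_numpy()[train]
            pred, _, _ = _blup_predict(
                k_train, G_full, train, val, med.s2_m,
                [(med.s2_e, np.eye(train.size))],
            )
        acc[rep] = np.corrcoef(pred, y[val])[0, 1]
    return PredictionResult.from_accuracies(
        trait_name, predictor, acc, train_frac, seed,
    )


def prediction_table(results) -> pd.DataFrame:
    """Tabulate PredictionResults side by side (trait x predictor)."""
    rows = [{
        "trait": r.trait, "predictor": r.predictor,
        "accuracy": r.mean, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "n_reps": r.n_reps,
    } for r in results]
    return pd.DataFrame(rows)
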