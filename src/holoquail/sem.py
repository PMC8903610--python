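"""Bivariate recursive structural equation mixed model (genus -> trait).

The system stacks the transformed genus abundance (first equation) and a
host trait (second equation):

    y = (Lambda (x) I_n) y + Z_td td + Z_a a + e,

with strictly lower-triangular Lambda holding one free structural
coefficient lambda (the rate of change of the trait per unit genus).  The
test-day, additive-genetic and residual dispersions are 2x2 matrices T, G
and R; R is constrained diagonal, which identifies lambda.

Under one-way recursion with diagonal R the model is fit in reduced form:
the genus observation enters the trait equation as a fixed regression,
whose coefficient is lambda, inside a bivariate REML with unstructured T
and G.  Post-fit, the system dispersions are mapped to the parameters of
the equivalent no-recursion model by the (I - Lambda)^-1 sandwich:

    T* = (I-L)^-1 T (I-L)'^-1   (same for G*, R*),   P* = T* + G* + R*,

and genetic/phenotypic correlations are read off G* and P*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HoloquailError, RelationshipMatrix, test_day_design
from .mixedmodel import FitResult, ModelSpec, VarComp, reml_fit

__all__ = [
    "RecursiveSystem", "SystemCovariances", "TransformedCovariances",
    "fit_recursive_bivariate", "transform_parameters", "derive_correlations",
]

# response ordering convention: genus first, trait second
_S11 = np.array([[1.0, 0.0], [0.0, 0.0]])
_S12 = np.array([[0.0, 1.0], [1.0, 0.0]])
_S22 = np.array([[0.0, 0.0], [0.0, 1.0]])


@dataclass
class RecursiveSystem:
    """Structural part of the fitted pair (genus j -> trait i)."""

    trait: str
    genus: str
    lam: float              # raw scale: trait units per transformed-genus unit
    lam_se: float
    lam_std: float          # in phenotypic-SD units (see transform_parameters)
    lam_std_se: float
    lam_p: float

    @property
    def Lambda(self) -> np.ndarray:
        return np.array([[0.0, 0.0], [self.lam, 0.0]])


@dataclass
class SystemCovariances:
    """System-scale 2x2 dispersions (genus, trait ordering)."""

    T: np.ndarray
    G: np.ndarray
    R: np.ndarray           # diagonal by construction
    fit: FitResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("T", "G", "R"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise HoloquailError(f"{name} must be symmetric 2x2")
            setattr(self, name, m)
        if abs(self.R[0, 1]) > 1e-12:
            raise HoloquailError("residual covariance must be zero")


@dataclass
class TransformedCovariances:
    """Parameters of the equivalent no-recursion bivariate model."""

    T_star: np.ndarray
    G_star: np.ndarray
    R_star: np.ndarray
    P_star: np.ndarray


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _bivariate_kernels(n: int, A_sub: np.ndarray, test_day) -> list[VarComp]:
    Z = test_day_design(test_day)
    H = Z @ Z.T
    eye = np.eye(n)
    return [
        VarComp("T11", np.kron(_S11, H)),
        VarComp("T12", np.kron(_S12, H), kind="covariance"),
        VarComp("T22", np.kron(_S22, H)),
        VarComp("G11", np.kron(_S11, A_sub)),
        VarComp("G12", np.kron(_S12, A_sub), kind="covariance"),
        VarComp("G22", np.kron(_S22, A_sub)),
        VarComp("R11", np.kron(_S11, eye)),
        VarComp("R22", np.kron(_S22, eye)),
    ]


def fit_recursive_bivariate(genus: np.ndarray, trait: np.ndarray,
                            A: RelationshipMatrix | np.ndarray,
                            test_day, ids=None,
                            trait_name: str = "trait",
                            genus_name: str = "genus",
                            method: str = "ai", tol: float = 1e-8,
                            fixed_lambda: float | None = None,
                            se_method: str = "profile",
                            _start: np.ndarray | None = None):
    """REML fit of the reduced-form recursive pair.

    ``genus`` must already be Box-Cox transformed.  Returns
    ``(RecursiveSystem, SystemCovariances)``.  Non-convergence is flagged
    on the embedded :class:`FitResult`, not raised.  With ``fixed_lambda``
    the structural coefficient is held at that value (the genus term is
    moved into the trait response) and only the dispersions are estimated.

    ``se_method="profile"`` (default) derives the SE of lambda from the
    curvature of the restricted likelihood profiled over lambda, which
    accounts for the competition between lambda and the genetic/test-day
    covariances in explaining the genus-trait association; ``"gls"`` is
    the naive fixed-effect SE at the estimated dispersions
    (anticonservative here).
    """
    g = np.asarray(genus, dtype=float).ravel()
    t = np.asarray(trait, dtype=float).ravel()
    if g.size != t.size:
        raise HoloquailError("genus and trait vectors differ in length")
    n = g.size
    if isinstance(A, RelationshipMatrix):
        if ids is None:
            raise HoloquailError("ids required to align the A matrix")
        A_sub = A.align(list(ids))
    else:
        A_sub = np.asarray(A, dtype=float)
    # fixed effects: per-equation intercepts; the genus observation as a
    # regression in the trait equation (its coefficient is lambda)
    zeros = np.zeros(n)
    ones = np.ones(n)
    cols = [
        np.concatenate([ones, zeros]),
        np.concatenate([zeros, ones]),
    ]
    names = ["mu_genus", "mu_trait"]
    if fixed_lambda is None:
        y = np.concatenate([g, t])
        cols.append(np.concatenate([zeros, g]))
        names.append("lambda")
    else:
        y = np.concatenate([g, t - fixed_lambda * g])
    spec = ModelSpec(
        y, np.column_stack(cols), _bivariate_kernels(n, A_sub, test_day),
        fixed_names=names,
    )
    fit = reml_fit(spec, method=method, tol=tol, start=_start)

    if fixed_lambda is None:
        lam = float(fit.beta[2])
        lam_se = float(np.sqrt(fit.beta_cov[2, 2]))
        if se_method == "profile":
            lam_se = _profile_lambda_se(
                g, t, A_sub, test_day, lam, lam_se, fit.theta, method, tol,
            )
        elif se_method != "gls":
            raise HoloquailError(f"unknown se_method {se_method!r}")
    else:
        lam, lam_se = float(fixed_lambda), 0.0
    T = np.array([[fit["T11"], fit["T12"]], [fit["T12"], fit["T22"]]])
    G = np.array([[fit["G11"], fit["G12"]], [fit["G12"], fit["G22"]]])
    R = np.diag([fit["R11"], fit["R22"]])
    cov = SystemCovariances(T=T, G=G, R=R, fit=fit)

    # standardization to phenotypic-SD units via P*
    tc = transform_parameters(np.array([[0, 0], [lam, 0]]), cov)
    sd_g = np.sqrt(tc.P_star[0, 0])
    sd_t = np.sqrt(tc.P_star[1, 1])
    lam_std = lam * sd_g / sd_t
    lam_std_se = lam_se * sd_g / sd_t
    lam_p = 2.0 * stats.norm.sf(abs(lam) / lam_se) if lam_se > 0 else np.nan
    system = RecursiveSystem(
        trait=trait_name, genus=genus_name, lam=lam, lam_se=lam_se,
        lam_std=lam_std, lam_std_se=lam_std_se, lam_p=float(lam_p),
    )
    return system, cov


def _profile_lambda_se(g, t, A_sub, test_day, lam, naive_se, theta0,
                       method, tol) -> float:
    """SE of lambda from the profiled restricted likelihood.

    Three warm-started fixed-lambda fits give the second difference of the
    profile log-likelihood; its negative inverse is var(lambda-hat).  The
    step is the naive GLS SE (right order of magnitude by construction).
    """
    h = max(naive_se, 1e-6)

    def pl(lam_value):
        _, cov = fit_recursive_bivariate(
            g, t, A_sub, test_day, method=method, tol=tol,
            fixed_lambda=lam_value, _start=theta0,
        )
        return cov.fit.loglik

    ll0 = pl(lam)
    curv = (pl(lam + h) - 2.0 * ll0 + pl(lam - h)) / (h * h)
    if curv >= 0:  # flat or non-concave profile: keep the naive SE
        return naive_se
    return float(np.sqrt(-1.0 / curv))


# ---------------------------------------------------------------------------
# Parameter transformation and correlations
# ---------------------------------------------------------------------------

def transform_parameters(Lambda: np.ndarray | RecursiveSystem,
                         cov: SystemCovariances) -> TransformedCovariances:
    """Map system dispersions to the no-recursion scale via (I-Lambda)^-1."""
    L = Lambda.Lambda if isinstance(Lambda, RecursiveSystem) else np.asarray(
        Lambda, dtype=float)
    if L.shape != (2, 2) or L[0, 1] != 0 or L[0, 0] != 0 or L[1, 1] != 0:
        raise HoloquailError("Lambda must be strictly lower-triangular 2x2")
    ImL = np.eye(2) - L
    # strictly lower-triangular Lambda makes I - Lambda unit-triangular,
    # hence always invertible
    inv = np.linalg.inv(ImL)
    sandwich = lambda M: inv @ M @ inv.T
    T_star = sandwich(cov.T)
    G_star = sandwich(cov.G)
    R_star = sandwich(cov.R)
    return TransformedCovariances(
        T_star=T_star, G_star=G_star, R_star=R_star,
        P_star=T_star + G_star + R_star,
    )


def _corr(M: np.ndarray) -> float:
    denom = np.sqrt(M[0, 0] * M[1, 1])
    if denom <= 0:
        raise HoloquailError("zero variance: correlation undefined")
    # REML covariance estimates are not constrained PSD, so the ratio can
    # leave [-1, 1] near the boundary; report the clipped correlation
    return float(np.clip(M[0, 1] / denom, -1.0, 1.0))


def derive_correlations(system: RecursiveSystem, cov: SystemCovariances):
    """Genetic and phenotypic correlations from G* and P*, with SEs.

    Returns dict with r_g, r_p and delta-method standard errors propagated
    numerically from the REML asymptotic covariance of the dispersion
    parameters (lambda held at its estimate; REML estimates of fixed and
    dispersion parameters are asymptotically independent).
    """
    tc = transform_parameters(system, cov)
    r_g = _corr(tc.G_star)
    r_p = _corr(tc.P_star)

    se_g = se_p = np.nan
    fit = cov.fit
    if fit is not None:
        labels = ["T11", "T12", "T22", "G11", "G12", "G22", "R11", "R22"]
        idx = [fit.labels.index(l) for l in labels]
        th0 = fit.theta[idx]
        C = fit.cov_theta[np.ix_(idx, idx)]

        def corr_at(th):
            T = np.array([[th[0], th[1]], [th[1], th[2]]])
            G = np.array([[th[3], th[4]], [th[4], th[5]]])
            R = np.diag([th[6], th[7]])
            c = SystemCovariances(T=T, G=G, R=R)
            t = transform_parameters(system, c)
            gden = np.sqrt(max(t.G_star[0, 0] * t.G_star[1, 1], 1e-300))
            pden = np.sqrt(max(t.P_star[0, 0] * t.P_star[1, 1], 1e-300))
            return np.array([t.G_star[0, 1] / gden, t.P_star[0, 1] / pden])

        J = np.empty((2, len(th0)))
        for k in range(len(th0)):
            h = 1e-5 * max(abs(th0[k]), 1e-3)
            up, dn = th0.copy(), th0.copy()
            up[k] += h
            dn[k] -= h
            J[:, k] = (corr_at(up) - corr_at(dn)) / (2 * h)
        V = J @ C @ J.T
        se_g, se_p = np.sqrt(np.clip(np.diag(V), 0, None))
    return {"r_g": r_g, "r_g_se": float(se_g),
            "r_p": r_p, "r_p_se": float(se_p)}


def sem_table(genus_values: pd.DataFrame, traits: pd.DataFrame,
              A: RelationshipMatrix, test_day, pairs,
              method: str = "ai") -> pd.DataFrame:
    """Fit the recursive model for each (genus, trait) pair; tabulate.

    ``pairs`` is an iterable of (genus, trait) names, typically the output
    of the Pearson pre-screen.  The table mirrors the usual reporting:
    r_g, r_p (with SEs) and the standardized structural coefficient.
    """
    rows = []
    ids = list(genus_values.index)
    A_sub = A.align(ids)
    for genus, trait in pairs:
        system, cov = fit_recursive_bivariate(
            genus_values[genus].to_numpy(),
            traits.loc[ids, trait].to_numpy(),
            A_sub, test_day, trait_name=trait, genus_name=genus,
            method=method,
        )
        cors = derive_correlations(system, cov)
        rows.append({
            "trait": trait, "genus": genus,
            "r_g": cors["r_g"], "r_g_se": cors["r_g_se"],
            "r_p": cors["r_p"], "r_p_se": cors["r_p_se"],
            "lambda": system.lam_std, "lambda_se": system.lam_std_se,
            "lambda_p": system.lam_p,
            "converged": cov.fit.converged if cov.fit else True,
        })
    return pd.DataFrame(rows)
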