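"""REML machinery for animal models with arbitrary covariance kernels.

The variance model is linear in its parameters:

    y = X beta + sum_k u_k,      V = sum_k theta_k * K_k,

where each kernel ``K_k`` is a dense symmetric matrix (pedigree A, genomic
G, microbial M, a test-day incidence product Z Z', the identity for the
residual, or a cross-trait block in a bivariate system).  ``theta_k`` is a
variance (constrained to a small positive floor) or a covariance (free).

Estimation is average-information (AI) REML with step halving and an
EM-style multiplicative fallback; derivatives are exact because dV/dtheta_k
= K_k.  The restricted log-likelihood used throughout is

    logL = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ],

with P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1.

On top of the engine this module provides the per-genus heritability scan
(animal model with test-day and residual terms, likelihood-ratio test of
the animal term), FDR adjustment against a fixed family size, and the
Pearson pre-screen used to choose genus-trait pairs for the structural
equation models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import HoloquailError, RelationshipMatrix, test_day_design

__all__ = [
    "VarComp", "ModelSpec", "FitResult", "reml_fit",
    "heritability_scan", "fdr_adjust", "pearson_screen",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class VarComp:
    """One linear variance component: ``theta * K``."""

    label: str
    kernel: np.ndarray
    kind: str = "variance"  # "variance" (theta >= floor) or "covariance" (free)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kind not in ("variance", "covariance"):
            raise HoloquailError(f"unknown component kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Response, fixed-effect design and random components of one model."""

    y: np.ndarray
    X: np.ndarray
    components: list[VarComp]
    fixed_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise HoloquailError("X row count does not match y")
        if n <= self.X.shape[1]:
            raise HoloquailError("need more observations than fixed effects")
        for comp in self.components:
            if comp.kernel.shape != (n, n):
                raise HoloquailError(
                    f"kernel {comp.label!r} has shape {comp.kernel.shape}, "
                    f"expected ({n}, {n})"
                )
        if not self.fixed_names:
            self.fixed_names = [f"b{j}" for j in range(self.X.shape[1])]


@dataclass
class FitResult:
    """Converged (or flagged) REML fit."""

    labels: list[str]
    theta: np.ndarray
    se: np.ndarray
    cov_theta: np.ndarray
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    blups: dict
    converged: bool
    n_iter: int
    floor: float

    def __getitem__(self, label: str) -> float:
        return float(self.theta[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def at_floor(self, label: str) -> bool:
        return self[label] <= self.floor * (1 + 1e-6)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _State:
    """Quantities at one theta: likelihood pieces, lazily inverted V."""

    __slots__ = ("logL", "ViX", "cx", "Py", "beta", "_chol", "_Vi")

    def __init__(self, logL, ViX, cx, Py, beta, chol):
        self.logL, self.ViX, self.cx = logL, ViX, cx
        self.Py, self.beta, self._chol = Py, beta, chol
        self._Vi = None

    @property
    def Vi(self) -> np.ndarray:
        if self._Vi is None:  # invert from the Cholesky factor on demand
            inv, info = linalg.lapack.dpotri(self._chol, lower=True)
            if info != 0:  # pragma: no cover - factor already validated
                raise linalg.LinAlgError("dpotri failed")
            # dpotri fills only the lower triangle; mirror it
            self._Vi = np.tril(inv) + np.tril(inv, -1).T
        return self._Vi


def _loglik_parts(theta, kernels, y, X):
    """Evaluate the restricted likelihood at theta; None if V is not PD."""
    n = y.size
    V = np.zeros((n, n))
    for t, K in zip(theta, kernels):
        V += t * K
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    yX = np.column_stack([y, X])
    ViyX = linalg.cho_solve((c, low), yX, check_finite=False)
    Viy, ViX = ViyX[:, 0], ViyX[:, 1:]
    XtViX = X.T @ ViX
    try:
        cx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = linalg.cho_solve(cx, ViX.T @ y, check_finite=False)
    Py = Viy - ViX @ beta
    logL = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return _State(logL, ViX, cx, Py, beta, c)


def reml_fit(spec: ModelSpec, method: str = "ai", tol: float = 1e-8,
             max_iter: int = 100, floor_frac: float = 1e-6,
             start: np.ndarray | None = None) -> FitResult:
    """Maximize the restricted likelihood of ``spec``.

    ``method="ai"`` takes average-information Newton steps with step
    halving, falling back to the EM-style multiplicative update when a step
    cannot improve the likelihood; ``method="em"`` uses the multiplicative
    update throughout (slower, very stable).  Variances are clamped at
    ``floor_frac * var(y)``.  Non-convergence is reported through
    ``FitResult.converged`` rather than an exception.
    """
    if method not in ("ai", "em"):
        raise HoloquailError(f"unknown REML method {method!r}")
    y, X = spec.y, spec.X
    n = y.size
    kernels = [c.kernel for c in spec.components]
    kinds = [c.kind for c in spec.components]
    labels = [c.label for c in spec.components]
    n_var = sum(k == "variance" for k in kinds)
    if n_var == 0:
        raise HoloquailError("model needs at least one variance component")

    # base variance from OLS residuals
    q, _ = np.linalg.qr(X)
    resid = y - q @ (q.T @ y)
    s2y = float(resid @ resid) / max(n - X.shape[1], 1)
    s2y = max(s2y, np.finfo(float).tiny)
    floor = floor_frac * s2y

    if start is not None:
        theta = np.asarray(start, dtype=float).copy()
        if theta.shape != (len(kernels),):
            raise HoloquailError("start vector length mismatch")
        for k, kind in enumerate(kinds):
            if kind == "variance":
                theta[k] = max(theta[k], floor)
    else:
        theta = np.array(
            [s2y / n_var if k == "variance" else 0.0 for k in kinds]
        )

    state = _loglik_parts(theta, kernels, y, X)
    if state is None:  # pathological kernels; jitter the residual-like comp
        theta[np.argmax(theta)] += s2y
        state = _loglik_parts(theta, kernels, y, X)
        if state is None:
            raise HoloquailError("initial covariance matrix is singular")

    converged = False
    it = 0
    AI = np.eye(len(theta))
    for it in range(1, max_iter + 1):
        # score and average information at current theta
        Vi, ViX, cx, Py = state.Vi, state.ViX, state.cx, state.Py
        logL = state.logL
        W = [K @ Py for K in kernels]
        score = np.empty(len(theta))
        trPK = np.empty(len(theta))
        for k, K in enumerate(kernels):
            trViK = float(np.sum(Vi * K))
            B = K @ ViX
            M = linalg.cho_solve(cx, ViX.T @ B, check_finite=False)
            trPK[k] = trViK - float(np.trace(M))
            score[k] = -0.5 * (trPK[k] - float(Py @ W[k]))
        AI = np.empty((len(theta), len(theta)))
        PW = []
        for w in W:
            PW.append(Vi @ w - ViX @ linalg.cho_solve(cx, ViX.T @ w,
                                                      check_finite=False))
        for k in range(len(theta)):
            for j in range(k, len(theta)):
                AI[k, j] = AI[j, k] = 0.5 * float(W[k] @ PW[j])

        def em_update(th):
            out = th.copy()
            for k, kind in enumerate(kinds):
                if kind == "variance" and trPK[k] > 0:
                    ratio = float(Py @ W[k]) / trPK[k]
                    out[k] = max(th[k] * max(ratio, 1e-3), floor)
            return out

        new_theta = new_state = None
        if method == "ai":
            # components pinned at the floor with a negative score stay
            # fixed; the Newton step is solved in the remaining directions
            free = np.array([
                not (kind == "variance" and th <= floor * (1 + 1e-9)
                     and sc < 0)
                for kind, th, sc in zip(kinds, theta, score)
            ])
            if not free.any():
                free[:] = True
            delta = np.zeros(len(theta))
            try:
                sub = AI[np.ix_(free, free)]
                delta[free] = np.linalg.solve(
                    sub + 1e-10 * np.eye(int(free.sum())) * np.trace(AI),
                    score[free],
                )
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(25):
                    cand = theta + step * delta
                    for k, kind in enumerate(kinds):
                        if kind == "variance":
                            cand[k] = max(cand[k], floor)
                    cand_state = _loglik_parts(cand, kernels, y, X)
                    if cand_state is not None and cand_state.logL >= logL - 1e-10:
                        new_theta, new_state = cand, cand_state
                        break
                    step /= 2.0
        if new_theta is None:  # EM path, or AI failed to improve
            new_theta = em_update(theta)
            new_state = _loglik_parts(new_theta, kernels, y, X)
        if new_state is None:
            break
        dl = new_state.logL - logL
        theta = new_theta
        state = new_state
        if it > 1 and abs(dl) < tol:
            converged = True
            break

    cov_theta = np.linalg.pinv(AI)
    se = np.sqrt(np.clip(np.diag(cov_theta), 0, None))
    XtViX_inv = linalg.cho_solve(state.cx, np.eye(X.shape[1]),
                                 check_finite=False)
    blups = {
        lab: th * (K @ state.Py)
        for lab, th, K in zip(labels, theta, kernels)
    }
    return FitResult(
        labels=labels, theta=theta.copy(), se=se, cov_theta=cov_theta,
        loglik=state.logL, beta=state.beta, beta_cov=XtViX_inv, blups=blups,
        converged=converged, n_iter=it, floor=floor,
    )


# ---------------------------------------------------------------------------
# Heritability scan (per-genus animal model)
# ---------------------------------------------------------------------------

def animal_model_spec(y, A_sub: np.ndarray, test_day,
                      extra: list[VarComp] | None = None,
                      include_animal: bool = True) -> ModelSpec:
    """Animal model: y = mu + test-day + animal (+ extra kernels) + residual."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Z = test_day_design(test_day)
    comps: list[VarComp] = []
    if include_animal:
        comps.append(VarComp("animal", A_sub))
    comps.append(VarComp("test_day", Z @ Z.T))
    if extra:
        comps.extend(extra)
    comps.append(VarComp("residual", np.eye(n)))
    X = np.ones((n, 1))
    return ModelSpec(y, X, comps, fixed_names=["mu"])


def _h2_delta_se(fit: FitResult, labels=("animal", "test_day", "residual")):
    """Delta-method SE of h2 = theta_a / sum(theta) from the AI covariance."""
    idx = [fit.labels.index(l) for l in labels]
    th = fit.theta[idx]
    tot = th.sum()
    grad = np.full(len(idx), -th[0] / tot ** 2)
    grad[0] += 1.0 / tot
    C = fit.cov_theta[np.ix_(idx, idx)]
    return float(np.sqrt(max(grad @ C @ grad, 0.0)))


def heritability_scan(genus_values: pd.DataFrame, A: RelationshipMatrix,
                      test_day, mean_abundance: pd.Series | None = None,
                      method: str = "ai", boundary: str = "chi2",
                      m_total: int | None = None) -> pd.DataFrame:
    """Per-genus heritability with likelihood-ratio test and FDR q values.

    Each column of ``genus_values`` (Box-Cox-transformed abundances) is fit
    with the animal model and with the reduced model lacking the animal
    term; ``h2 = s2_a / (s2_a + s2_td + s2_e)``, i.e. the test-day variance
    stays in the denominator.  ``D = 2(logL_full - logL_reduced)`` is tested
    against a chi-square with 1 df (``boundary="mixture"`` switches to the
    50:50 point-mass mixture).
    """
    ids = list(genus_values.index)
    A_sub = A.align(ids)
    rows = []
    for genus in genus_values.columns:
        y = genus_values[genus].to_numpy(dtype=float)
        if np.var(y) < 1e-14:
            warnings.warn(f"genus {genus!r} has zero variance; skipped")
            continue
        full = reml_fit(animal_model_spec(y, A_sub, test_day), method=method)
        red = reml_fit(
            animal_model_spec(y, A_sub, test_day, include_animal=False),
            method=method,
        )
        s2a, s2td, s2e = full["animal"], full["test_day"], full["residual"]
        h2 = s2a / (s2a + s2td + s2e)
        D = max(0.0, 2.0 * (full.loglik - red.loglik))
        if boundary == "mixture":
            p = 0.5 * stats.chi2.sf(D, 1) if D > 0 else 1.0
        else:
            p = float(stats.chi2.sf(D, 1))
        rows.append({
            "genus": genus, "h2": h2, "se": _h2_delta_se(full),
            "D": D, "p": p,
            "mean_abundance": (
                float(mean_abundance[genus]) if mean_abundance is not None
                else np.nan
            ),
            "converged": full.converged and red.converged,
        })
    out = pd.DataFrame(rows).set_index("genus")
    m = m_total if m_total is not None else len(out)
    out["q"] = fdr_adjust(out["p"].to_numpy(), m_total=m)
    return out


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(p: np.ndarray, m_total: int, method: str = "bh") -> np.ndarray:
    """Step-up FDR q values against a family of ``m_total`` comparisons.

    The supplied vector may contain only the smallest (e.g. significant)
    p values of the family; ranks are assigned within the vector but the
    numerator uses ``m_total``, matching the convention of testing a fixed
    number of genera.  ``method="storey"`` rescales by an estimated null
    proportion pi0 (only meaningful when the full vector is supplied).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise HoloquailError("p values must lie in [0, 1]")
    if m_total < p.size:
        raise HoloquailError("m_total smaller than number of p values")
    pi0 = 1.0
    if method == "storey":
        if p.size == m_total and p.size > 0:
            lam = 0.5
            pi0 = min(1.0, np.mean(p > lam) / (1 - lam))
            pi0 = max(pi0, 1.0 / m_total)
        # else: partial family, keep pi0 = 1 (reduces to BH)
    elif method != "bh":
        raise HoloquailError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total * pi0 / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Pearson pre-screen
# ---------------------------------------------------------------------------

def pearson_screen(genus_values: pd.DataFrame, traits: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each genus with each trait, flagged at alpha.

    Pairs with fewer than 3 complete observations are skipped.  The flagged
    pairs are the candidates forwarded to the structural equation models.
    """
    rows = []
    for genus in genus_values.columns:
        g = genus_values[genus]
        for trait in traits.columns:
            t = traits[trait]
            ok = g.notna() & t.notna()
            if ok.sum() < 3:
                continue
            r, p = stats.pearsonr(g[ok], t[ok])
            rows.append({
                "genus": genus, "trait": trait, "r": float(r),
                "p": float(p), "n": int(ok.sum()),
                "selected": bool(p <= alpha),
            })
    return pd.DataFrame(rows)
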