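"""Independent reference implementations used to validate the package.

Everything here is written directly from textbook formulas with plain
numpy (inverses, slogdet, lstsq) and stays independent of the code paths
it checks.
"""

import numpy as np


def restricted_loglik(theta, kernels, y, X):
    """Restricted likelihood via explicit inverses and slogdet."""
    V = sum(t * K for t, K in zip(theta, kernels))
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign_x, logdet_X = np.linalg.slogdet(XtViX)
    if sign_x <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (logdet_V + logdet_X + float(y @ P @ y))


def grid_search_reml_2d(kernels, y, X, lo, hi, n_grid=41, n_zoom=4):
    """Dense 2-D grid maximization of the restricted likelihood.

    Coarse-to-fine: each stage re-grids around the best point with a
    10x smaller span.  Returns the (theta_1, theta_2) argmax.
    """
    best = None
    span = (hi - lo, hi - lo)
    center = ((lo + hi) / 2.0, (lo + hi) / 2.0)
    for _ in range(n_zoom):
        g1 = np.linspace(max(lo, center[0] - span[0] / 2),
                         center[0] + span[0] / 2, n_grid)
        g2 = np.linspace(max(lo, center[1] - span[1] / 2),
                         center[1] + span[1] / 2, n_grid)
        best_ll = -np.inf
        for t1 in g1:
            for t2 in g2:
                ll = restricted_loglik((t1, t2), kernels, y, X)
                if ll > best_ll:
                    best_ll, best = ll, (t1, t2)
        center = best
        span = (span[0] / 10.0, span[1] / 10.0)
    return np.array(best), best_ll


def lod_by_regression(y, covariates, add_score, dom_score):
    """(n/2) log10(RSS0/RSS1) via two independent lstsq fits."""
    n = y.size
    X0 = np.column_stack([np.ones(n)] + (
        [covariates] if covariates is not None else []))
    X1 = np.column_stack([X0, add_score, dom_score])
    rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    return 0.5 * n * np.log10(rss0 / rss1)


def bh_stepup(p, m_total):
    """Hand step-up q values: q_i = min_{j >= i} m p_(j) / j, capped at 1."""
    order = np.argsort(p)
    q = np.empty(len(p))
    running = np.inf
    for rank in range(len(p), 0, -1):
        i = order[rank - 1]
        running = min(running, m_total * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def pearson_t_test(x, y):
    """r and two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    from scipy import stats
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def f2_hmm_posterior(obs, positions, error_prob):
    """Forward-backward for one individual, one chromosome, 3 F2 states.

    ``obs``: genotype (0/1/2/-1) at each position (-1 = untyped/pseudo).
    Independent matrix-product implementation.
    """
    prior = np.array([0.25, 0.5, 0.25])

    def trans(d_cm):
        r = 0.5 * (1 - np.exp(-2 * d_cm / 100.0))
        s = 1 - r
        return np.array([
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ])

    def emit(g):
        if g < 0:
            return np.ones(3)
        e = np.full(3, error_prob / 2.0)
        e[g] = 1 - error_prob
        return e

    L = len(positions)
    alpha = np.zeros((L, 3))
    alpha[0] = prior * emit(obs[0])
    for t in range(1, L):
        T = trans(positions[t] - positions[t - 1])
        alpha[t] = (alpha[t - 1] @ T) * emit(obs[t])
    beta = np.zeros((L, 3))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        T = trans(positions[t + 1] - positions[t])
        beta[t] = T @ (emit(obs[t + 1]) * beta[t + 1])
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def blup_solution(y, X, V, K, sigma2_u):
    """Closed-form BLUP of u given fixed variance components."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return sigma2_u * K @ Vi @ (y - X @ beta)
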