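"""Independent oracle implementations used only by the tests.

These deliberately re-derive quantities from first principles (explicit
loops, closed forms, brute-force optimisation) so they share no code with
the library paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def cumlogit_loglik_grad(theta, y, X, n_categories):
    """Log-likelihood and gradient of the independent-data cumulative-logit
    (proportional-odds) model; categories 1..C."""
    nc = n_categories - 1
    eta, beta = theta[:nc], theta[nc:]
    lp = eta[None, :] + (X @ beta)[:, None]
    mu = expit(lp)  # (n, C-1) cumulative probabilities
    mu_ext = np.concatenate([np.zeros((len(y), 1)), mu, np.ones((len(y), 1))], axis=1)
    idx = np.arange(len(y))
    p = mu_ext[idx, y] - mu_ext[idx, y - 1]
    ll = np.log(np.clip(p, 1e-300, None)).sum()

    A = mu * (1.0 - mu)
    grad = np.zeros_like(theta)
    for i in range(len(y)):
        dp = np.zeros(len(theta))
        c_hi, c_lo = y[i], y[i] - 1  # P = mu_{y} - mu_{y-1}
        for c, sign in ((c_hi, 1.0), (c_lo, -1.0)):
            if 1 <= c <= nc:
                dp[c - 1] += sign * A[i, c - 1]
                dp[nc:] += sign * A[i, c - 1] * X[i]
        grad += dp / p[i]
    return ll, grad


def fit_cumlogit_ml(y, X, n_categories, start):
    """High-precision ML fit by quasi-Newton with the analytic gradient."""
    res = minimize(
        lambda th: -cumlogit_loglik_grad(th, y, X, n_categories)[0],
        start,
        jac=lambda th: -cumlogit_loglik_grad(th, y, X, n_categories)[1],
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x


def cwgee_estimating_function(theta, clusters, n_categories):
    """Loop-based re-derivation of the cluster-weighted estimating function.

    ``clusters`` is a list of (y_array, X_matrix); weights are 1/n_i; the
    working covariance across cutpoints is the exact nested-indicator
    covariance Cov(U_c, U_c') = mu_c (1 - mu_c') for c <= c'.
    """
    nc = n_categories - 1
    eta, beta = theta[:nc], theta[nc:]
    total = np.zeros_like(theta)
    for y_i, X_i in clusters:
        contrib = np.zeros_like(theta)
        for y_ij, x_ij in zip(y_i, X_i):
            mu = expit(eta + float(x_ij @ beta))
            U = (y_ij <= np.arange(1, n_categories)).astype(float)
            A = mu * (1.0 - mu)
            V = np.empty((nc, nc))
            for c in range(nc):
                for d in range(nc):
                    V[c, d] = mu[min(c, d)] * (1.0 - mu[max(c, d)])
            D = np.zeros((nc, len(theta)))
            for c in range(nc):
                D[c, c] = A[c]
                D[c, nc:] = A[c] * x_ij
            contrib += D.T @ np.linalg.solve(V, U - mu)
        total += contrib / len(y_i)
    return total
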