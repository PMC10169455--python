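"""Proportional-odds regression by cluster-weighted GEE.

The marginal model is ``logit Pr(Y_ij <= c) = eta_c + x_ij' beta`` for
``c = 1..C-1``.  Each C-category outcome is expanded into the nested binary
indicators ``U_c = 1(Y <= c)`` and the coefficients solve the estimating
equations

    sum_i w_i sum_j D_ij' V_ij^{-1} (U_ij - mu_ij) = 0,

with cluster weights ``w_i = 1/n_i`` (CWGEE, robust to informative cluster
size) or ``w_i = 1`` (ordinary GEE), working independence across members,
and a within-member working covariance across cutpoints.  By default the
working covariance is the exact covariance implied by the nested
indicators, ``Cov(U_c, U_c') = mu_c (1 - mu_c')`` for ``c <= c'``; for a
single independent member this makes the estimating function equal to the
multinomial cumulative-logit score, so the fit coincides with maximum
likelihood on independent data.

Standard errors come from the robust sandwich ``Psi = H^{-1} M H^{-1}``
where ``H`` stacks the weighted ``D'V^{-1}D`` and ``M`` the outer products
of the weighted per-cluster estimating functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

logger = logging.getLogger(__name__)

__all__ = ["CWGEEFit", "expand_cumulative", "cumulative_corr", "fit_cwgee", "wald_ci", "complete_cases"]


def expand_cumulative(y: int, n_categories: int) -> np.ndarray:
    """Expand an ordinal value into the C-1 nested indicators 1(y <= c)."""
    if not 1 <= y <= n_categories:
        raise ValueError(f"y={y} outside 1..{n_categories}")
    return (y <= np.arange(1, n_categories)).astype(float)


def cumulative_corr(mu: np.ndarray) -> np.ndarray:
    """Correlation matrix of the nested cumulative indicators.

    For strictly increasing cumulative means ``mu``, the indicators satisfy
    ``U_c <= U_c'`` (c < c'), which pins their joint distribution down
    completely: ``corr(U_c, U_c') = sqrt(mu_c (1-mu_c') / ((1-mu_c) mu_c'))``.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0) or np.any(np.diff(mu) <= 0.0):
        raise ValueError("mu must be strictly increasing within (0, 1)")
    lo = np.minimum.outer(mu, mu)
    hi = np.maximum.outer(mu, mu)
    corr = np.sqrt(lo * (1.0 - hi) / ((1.0 - lo) * hi))
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CWGEEFit:
    """Result of a cluster-weighted GEE fit."""

    coefficients: np.ndarray
    robust_vcov: np.ndarray
    names: list[str]
    weighting: str
    n_clusters: int
    n_members_used: int
    iterations: int
    converged: bool
    max_update_norm: float
    score_norm: float
    n_categories: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_vcov))


def complete_cases(table: pd.DataFrame, on: tuple[str, ...] = ("y",)) -> pd.DataFrame:
    """Drop rows with missing values in ``on`` (complete-case analysis)."""
    return table.dropna(subset=list(on)).copy()


def _working_moments(eta, beta, X, corr_across_cutpoints):
    """Cumulative means mu, variances A, and working covariance V per row."""
    lp = eta[None, :] + (X @ beta)[:, None]
    mu = np.clip(expit(lp), 1e-10, 1.0 - 1e-10)
    A = mu * (1.0 - mu)
    if corr_across_cutpoints:
        lo = np.minimum(mu[:, :, None], mu[:, None, :])
        hi = np.maximum(mu[:, :, None], mu[:, None, :])
        V = lo * (1.0 - hi)
    else:
        nc = mu.shape[1]
        V = np.zeros((mu.shape[0], nc, nc))
        idx = np.arange(nc)
        V[:, idx, idx] = A
    return mu, A, V


def fit_cwgee(
    table: pd.DataFrame,
    n_categories: int,
    weighting: str = "cwgee",
    *,
    covariates: tuple[str, ...] = ("x", "z"),
    outcome: str = "y",
    tol: float = 1e-8,
    max_iter: int = 100,
    cluster_sizes: pd.Series | None = None,
    corr_across_cutpoints: bool = True,
) -> CWGEEFit:
    """Fit the marginal proportional-odds model by (CW)GEE.

    Parameters
    ----------
    table
        Long-format panel with no missing values in ``outcome`` or the
        covariates among the supplied rows (drop or impute first).
    n_categories
        Number of outcome categories C.
    weighting
        ``"cwgee"`` weights each cluster by the inverse of its row count;
        ``"gee"`` uses unit weights.
    cluster_sizes
        Optional mapping cluster id -> size used for the weights instead of
        the row count (e.g. the pre-deletion size in a complete-case
        analysis).
    corr_across_cutpoints
        Use the exact nested-indicator working correlation across cutpoints
        (default) or independence (sensitivity option).
    tol
        Convergence tolerance on the largest coefficient update.
    """
    if weighting not in ("cwgee", "gee"):
        raise ValueError("weighting must be 'cwgee' or 'gee'")
    if table[outcome].isna().any():
        raise ValueError("missing outcome values among supplied rows; drop or impute first")

    y = table[outcome].to_numpy(dtype=float)
    if np.any((y < 1) | (y > n_categories) | (y != np.round(y))):
        raise ValueError(f"outcome values must be integers in 1..{n_categories}")
    y = y.astype(int)
    X = table[list(covariates)].to_numpy(dtype=float)
    codes, uniques = pd.factorize(table["cluster"], sort=True)
    n_rows, p = X.shape
    nc = n_categories - 1
    K = nc + p

    counts = np.bincount(codes)
    if cluster_sizes is not None:
        sizes = np.asarray([cluster_sizes[c] for c in uniques], dtype=float)
    else:
        sizes = counts.astype(float)
    w_cluster = 1.0 / sizes if weighting == "cwgee" else np.ones_like(sizes)
    w_row = w_cluster[codes]

    U = (y[:, None] <= np.arange(1, n_categories)[None, :]).astype(float)

    # initialise cutpoints at empirical cumulative logits, slopes at zero
    pc = np.clip(U.mean(axis=0), 1e-4, 1.0 - 1e-4)
    pc = np.maximum.accumulate(pc + 1e-9 * np.arange(nc))
    theta = np.concatenate([logit(pc), np.zeros(p)])

    def score_and_H(theta, with_meat=False):
        eta, beta = theta[:nc], theta[nc:]
        mu, A, V = _working_moments(eta, beta, X, corr_across_cutpoints)
        t = np.linalg.solve(V, (U - mu)[..., None])[..., 0]  # V^{-1}(U-mu)
        At = A * t
        g = np.concatenate([At, At.sum(axis=1, keepdims=True) * X], axis=1)  # (n,K)
        # per-cluster estimating functions, weighted
        wg = w_row[:, None] * g
        G = np.column_stack(
            [np.bincount(codes, weights=wg[:, k], minlength=len(uniques)) for k in range(K)]
        )
        S = G.sum(axis=0)
        Kmat = A[:, :, None] * np.linalg.inv(V) * A[:, None, :]
        rowsum = Kmat.sum(axis=2)
        totsum = rowsum.sum(axis=1)
        H = np.zeros((K, K))
        H[:nc, :nc] = np.einsum("n,nab->ab", w_row, Kmat)
        H[:nc, nc:] = np.einsum("n,na,nk->ak", w_row, rowsum, X)
        H[nc:, :nc] = H[:nc, nc:].T
        H[nc:, nc:] = np.einsum("n,nk,nl->kl", w_row * totsum, X, X)
        M = G.T @ G if with_meat else None
        return S, H, M

    converged = False
    max_update = np.inf
    S, H, _ = score_and_H(theta)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(H, S)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular scoring matrix H") from err
        step = 1.0
        norm0 = np.linalg.norm(S)
        S_new = H_new = None
        for _ in range(25):
            cand = theta + step * delta
            if np.all(np.diff(cand[:nc]) > 0.0):
                try:
                    S_new, H_new, _ = score_and_H(cand)
                except np.linalg.LinAlgError:
                    S_new = None  # degenerate working covariance: shrink step
                else:
                    if np.linalg.norm(S_new) <= norm0 or step < 1e-3:
                        break
            step *= 0.5
        if S_new is None:
            raise RuntimeError("step-halving failed to find an admissible update")
        theta = theta + step * delta
        S, H = S_new, H_new
        max_update = float(np.max(np.abs(step * delta)))
        if max_update < tol:
            converged = True
            break
    if not converged:
        logger.warning("CWGEE did not converge in %d iterations", max_iter)

    S, H, M = score_and_H(theta, with_meat=True)
    Hinv = np.linalg.inv(H)
    vcov = Hinv @ M @ Hinv
    vcov = 0.5 * (vcov + vcov.T)

    names = [f"eta_{c}" for c in range(1, n_categories)] + [f"beta_{c}" for c in covariates]
    return CWGEEFit(
        coefficients=theta,
        robust_vcov=vcov,
        names=names,
        weighting=weighting,
        n_clusters=len(uniques),
        n_members_used=n_rows,
        iterations=it,
        converged=converged,
        max_update_norm=max_update,
        score_norm=float(np.linalg.norm(S)),
        n_categories=n_categories,
    )


def wald_ci(fit: CWGEEFit, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter Wald intervals from the robust covariance.

    Returns estimates, robust SEs, interval bounds and the odds-ratio scale
    (exponentiated) bounds.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = ndtri(0.5 * (1.0 + level))
    se = fit.se
    est = fit.coefficients
    lower, upper = est - z * se, est + z * se
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "lower": lower,
            "upper": upper,
            "odds_ratio": np.exp(est),
            "or_lower": np.exp(lower),
            "or_upper": np.exp(upper),
        },
        index=fit.names,
    )
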