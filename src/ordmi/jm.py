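"""Joint-modelling imputation through a multivariate latent-normal
random-intercepts model.

Every C-category ordinal variable is represented by C-1 latent normal
columns (a *nominal* probit structure: the same representation is used even
though the variables are ordinal, mirroring the latent-normal JM software
this engine emulates).  A category is recovered from its block of latents
by the max-latent rule: category ``c < C`` iff latent ``c`` is positive and
maximal, category ``C`` iff all latents are negative.

Stacking the blocks of all four variables gives a latent row vector with
``L = sum_v (C_v - 1)`` entries, modelled as

    z_ij = B' g_ij + u_i + eps_ij,   u_i ~ N(0, Sigma_u),  eps_ij ~ N(0, Sigma_e)

where ``g_ij`` holds an intercept, X, Z and optionally the cluster size
(the "+CS" variant); every latent column has its own regression
coefficients.  Within each variable's block of ``Sigma_e`` the diagonal is
fixed at 1 and the off-diagonals at 0.5 (the identification constraint of
the nominal probit); the cross-variable blocks are free and sampled by a
random-walk Metropolis step, so the fixed blocks are conserved exactly.

A Gibbs sweep updates: (a) latent entries row-wise by element-wise Gibbs,
truncated to the decoding-consistent region for observed categories and
unconstrained for missing ones; (b) the coefficient matrix from its
matrix-normal conditional; (c) random intercepts and ``Sigma_u``
(inverse-Wishart); (d) the free blocks of ``Sigma_e`` by Metropolis with
step size adapted during burn-in toward 20-40% acceptance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .common import CompletedData, truncated_standard_normal
from .simulate import ORDINAL_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["JMConfig", "decode_latent", "jm_impute"]


@dataclass(frozen=True)
class JMConfig:
    """Settings of the JM sampler (same chain contracts as the FCS one)."""

    m: int = 5
    burn_in: int = 4000
    between: int = 1000
    include_cs: bool = False
    use_auxiliaries: bool = True
    mh_step: float = 0.02
    adapt_every: int = 50
    wishart_extra_df: int = 2

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.burn_in < 1 or self.between < 1:
            raise ValueError("burn_in and between must be >= 1")


def decode_latent(latents: np.ndarray) -> int:
    """Max-latent decoding of one variable's block of C-1 latents.

    Category ``c`` (c < C) iff latent c is positive and the maximum;
    category ``C`` iff all latents are negative.  Exact ties break toward
    the lower index (a measure-zero event).
    """
    latents = np.asarray(latents, dtype=float)
    if not np.all(np.isfinite(latents)):
        raise ValueError("latents must be finite")
    if latents.max() > 0.0:
        return int(np.argmax(latents)) + 1
    return latents.size + 1


def _decode_block(z: np.ndarray, n_cat: int) -> np.ndarray:
    """Vectorised max-latent decoding for an (n, C-1) block."""
    return np.where(z.max(axis=1) > 0.0, z.argmax(axis=1) + 1, n_cat)


class _JMState:
    def __init__(self, variables, blocks, n_rows, n_clusters, q, rng):
        self.variables = variables
        self.blocks = blocks  # name -> slice into the latent columns
        self.L = sum(s.stop - s.start for s in blocks.values())
        self.B = np.zeros((q, self.L))
        self.U = np.zeros((n_clusters, self.L))
        self.Sigma_u = 0.25 * np.eye(self.L)
        self.Sigma_e = self._fixed_pattern()
        self.Z = np.zeros((n_rows, self.L))
        self.accepted = 0
        self.proposed = 0

    def _fixed_pattern(self) -> np.ndarray:
        S = np.zeros((self.L, self.L))
        for sl in self.blocks.values():
            k = sl.stop - sl.start
            S[sl, sl] = 0.5 * (np.ones((k, k)) + np.eye(k))
        return S

    def free_mask(self) -> np.ndarray:
        """Upper-triangular mask of the free (cross-variable) elements."""
        fixed = np.zeros((self.L, self.L), dtype=bool)
        for sl in self.blocks.values():
            fixed[sl, sl] = True
        return np.triu(~fixed, k=1)


def _inv_wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart draw via the Bartlett decomposition.

    If X ~ Wishart(df, scale^{-1}) then X^{-1} ~ InvWishart(df, scale).
    """
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    A[np.tril_indices(p, k=-1)] = rng.standard_normal(p * (p - 1) // 2)
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    LA = L @ A
    W = LA @ LA.T
    return np.linalg.inv(W)


def _residual_loglik(S: np.ndarray, scatter: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    return -0.5 * (n * logdet + np.trace(np.linalg.solve(S, scatter)))


def jm_impute(
    table: pd.DataFrame,
    c_map: dict[str, int],
    config: JMConfig,
    rng: np.random.Generator,
) -> CompletedData:
    """Impute the incomplete ordinal columns of ``table`` by joint modelling.

    Same contract as :func:`ordmi.fcs.fcs_impute`: missingness confined to
    the ordinal level-1 columns, X and Z fully observed, observed cells
    never modified; returns M completed copies decoded from the latent
    draws at the saved iterations.
    """
    for col in ("x", "z", "cluster"):
        if table[col].isna().any():
            raise ValueError(f"column {col!r} must be fully observed")
    variables = [v for v in ORDINAL_COLUMNS if v in c_map]
    if not config.use_auxiliaries:
        variables = [v for v in variables if v == "y"]

    codes, uniques = pd.factorize(table["cluster"], sort=True)
    n_clusters, n = len(uniques), len(table)
    sizes = np.bincount(codes).astype(float)

    g_cols = [np.ones(n), table["x"].to_numpy(float), table["z"].to_numpy(float)]
    if config.include_cs:
        g_cols.append(sizes[codes])
    G = np.column_stack(g_cols)
    q = G.shape[1]
    GtG = G.T @ G
    cf_G = np.linalg.cholesky(GtG)
    A_coef = np.linalg.inv(cf_G).T  # A A' = (G'G)^{-1}

    blocks, start = {}, 0
    for v in variables:
        blocks[v] = slice(start, start + c_map[v] - 1)
        start += c_map[v] - 1
    st = _JMState(variables, blocks, n, n_clusters, q, rng)
    L = st.L
    free = st.free_mask()
    free_idx = np.argwhere(free)

    obs_masks, cats = {}, {}
    for v in variables:
        raw = table[v].to_numpy(dtype=float)
        obs_masks[v] = ~np.isnan(raw)
        cats[v] = np.where(obs_masks[v], raw, 0).astype(int)

    # consistent latent initialisation: winner slightly positive, rest negative
    for v in variables:
        sl = blocks[v]
        k = c_map[v] - 1
        block = -0.5 - 0.2 * rng.random((n, k))
        ok = obs_masks[v] & (cats[v] <= k)
        block[ok, cats[v][ok] - 1] = 0.5 + 0.2 * rng.random(int(ok.sum()))
        st.Z[:, sl] = block

    mh_step = config.mh_step
    df0 = L + config.wishart_extra_df

    # static per-column metadata for the latent updates: the observed
    # categories never change, so the constraint pattern of every column is
    # precomputable (only the numeric bounds move with the current latents)
    col_info = []
    for v in variables:
        sl = blocks[v]
        obs = obs_masks[v]
        k = cats[v]
        for l in range(sl.start, sl.stop):
            c_local = l - sl.start + 1
            top_rows = np.where(obs & (k == c_map[v]))[0]
            win_rows = np.where(obs & (k == c_local))[0]
            lose_rows = np.where(obs & (k < c_map[v]) & (k != c_local))[0]
            win_cols = sl.start + k[lose_rows] - 1
            col_info.append(
                (
                    l,
                    np.delete(np.arange(L), l),
                    [j for j in range(sl.start, sl.stop) if j != l],
                    top_rows,
                    win_rows,
                    lose_rows,
                    win_cols,
                )
            )

    def sweep() -> None:
        nonlocal mh_step
        mean_rows = G @ st.B + st.U[codes]
        # --- (a) element-wise Gibbs on the latent columns
        # conditionals in precision form: one inverse of Sigma_e per sweep
        Omega = np.linalg.inv(st.Sigma_e)
        dev = st.Z - mean_rows
        for l, others, others_in_block, top_rows, win_rows, lose_rows, win_cols in col_info:
            o_ll = Omega[l, l]
            sd = np.sqrt(max(1.0 / o_ll, 1e-12))
            t = dev @ Omega[:, l] - dev[:, l] * o_ll
            cond_mean = mean_rows[:, l] - t / o_ll

            lo = np.full(n, -np.inf)
            hi = np.full(n, np.inf)
            hi[top_rows] = 0.0
            if win_rows.size:
                if others_in_block:
                    block_max = st.Z[np.ix_(win_rows, others_in_block)].max(axis=1)
                    lo[win_rows] = np.maximum(0.0, block_max)
                else:
                    lo[win_rows] = 0.0
            if lose_rows.size:
                hi[lose_rows] = st.Z[lose_rows, win_cols]
            st.Z[:, l] = cond_mean + sd * truncated_standard_normal(
                rng, (lo - cond_mean) / sd, (hi - cond_mean) / sd
            )
            dev[:, l] = st.Z[:, l] - mean_rows[:, l]

        # --- (b) fixed effects: matrix-normal conditional, flat prior
        target = st.Z - st.U[codes]
        Bhat = np.linalg.solve(GtG, G.T @ target)
        cf_e = np.linalg.cholesky(st.Sigma_e)
        st.B = Bhat + A_coef @ rng.standard_normal((q, L)) @ cf_e.T

        # --- (c) random intercepts and Sigma_u
        Se_inv = np.linalg.inv(st.Sigma_e)
        resid = st.Z - G @ st.B
        rsum = np.column_stack(
            [np.bincount(codes, weights=resid[:, l], minlength=n_clusters) for l in range(L)]
        )
        Su_inv = np.linalg.inv(st.Sigma_u)
        prec = sizes[:, None, None] * Se_inv[None] + Su_inv[None]
        mean_u = np.linalg.solve(prec, (rsum @ Se_inv.T)[..., None])[..., 0]
        cf_p = np.linalg.cholesky(prec)
        eps = rng.standard_normal((n_clusters, L, 1))
        st.U = mean_u + np.linalg.solve(np.transpose(cf_p, (0, 2, 1)), eps)[..., 0]
        scale = np.eye(L) + st.U.T @ st.U
        st.Sigma_u = _inv_wishart_rvs(df0 + n_clusters, scale, rng)

        # --- (d) Metropolis on the free cross-variable blocks of Sigma_e
        if free_idx.size:
            resid2 = resid - st.U[codes]
            scatter = resid2.T @ resid2
            cur_ll = _residual_loglik(st.Sigma_e, scatter, n)
            prop = st.Sigma_e.copy()
            jitter = mh_step * rng.standard_normal(len(free_idx))
            prop[free_idx[:, 0], free_idx[:, 1]] += jitter
            prop[free_idx[:, 1], free_idx[:, 0]] = prop[free_idx[:, 0], free_idx[:, 1]]
            prop_ll = _residual_loglik(prop, scatter, n)
            st.proposed += 1
            if np.log(rng.random()) < prop_ll - cur_ll:
                st.Sigma_e = prop
                st.accepted += 1

    def save_copy() -> pd.DataFrame:
        out = table.copy()
        for v in variables:
            sl = blocks[v]
            decoded = _decode_block(st.Z[:, sl], c_map[v])
            obs = obs_masks[v]
            if not np.array_equal(decoded[obs], cats[v][obs]):
                raise RuntimeError(
                    f"latent draws for observed {v} left the decoding region"
                )
            col = out[v].to_numpy(dtype=float)
            col[~obs] = decoded[~obs].astype(float)
            out[v] = col
        return out

    datasets = []
    total = 0
    for i in range(config.burn_in):
        sweep()
        total += 1
        if free_idx.size and (i + 1) % config.adapt_every == 0 and st.proposed:
            rate = st.accepted / st.proposed
            if rate < 0.2:
                mh_step *= 0.7
            elif rate > 0.4:
                mh_step *= 1.4
            st.accepted = st.proposed = 0
    datasets.append(save_copy())
    while len(datasets) < config.m:
        for _ in range(config.between):
            sweep()
            total += 1
        datasets.append(save_copy())

    if not np.all(np.isfinite(st.B)):
        raise RuntimeError(f"chain divergence in coefficients at sweep {total}")

    return CompletedData(
        datasets=datasets,
        method="jm+cs" if config.include_cs else "jm",
        n_sweeps=total,
        burn_in=config.burn_in,
        between=config.between,
        include_cs=config.include_cs,
        diagnostics={"mh_step": mh_step, "sigma_e": st.Sigma_e.copy(), "sigma_u": st.Sigma_u.copy()},
    )
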