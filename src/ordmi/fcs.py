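"""Fully conditional specification (FCS / chained-equations) imputation for
multilevel ordinal variables.

Each incomplete ordinal variable is imputed from its own random-intercept
cumulative-probit model: a latent normal variable with unit residual
variance is linked to the categories through an increasing threshold vector
``(tau_1, ..., tau_{C-1})``; the linear predictor contains an intercept,
the other ordinals as numeric scores, the cluster-level covariates X and Z,
optionally the cluster size n_i (the "+CS" variant), and a cluster random
intercept.  One Gibbs sweep visits the variables in the fixed order
(Y, M1, M2, M3) and, for each:

1. samples latents for observed entries from truncated normals within
   their category's threshold interval;
2. samples regression coefficients (flat prior) and cluster random
   intercepts from their normal full conditionals;
3. samples the random-intercept variance (inverse-gamma conditional);
4. samples the free thresholds uniformly between the adjacent latent order
   statistics (tau_1 is fixed at 0 for identification, the intercept is
   free, and the residual variance is fixed at 1);
5. draws latents for missing entries unconstrained from the linear
   predictor and converts them to categories by the threshold partition.

After ``burn_in`` sweeps a completed copy of the panel is saved, then one
more copy every ``between`` sweeps, until M copies exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .common import CompletedData, truncated_standard_normal
from .simulate import ORDINAL_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["FCSConfig", "fcs_impute"]


@dataclass(frozen=True)
class FCSConfig:
    """Settings of the FCS sampler.

    ``sigma_u_fixed`` pins the random-intercept standard deviation instead
    of sampling it (0 removes the random intercept entirely); it exists for
    reductions of the sampler to single-level probit models.
    """

    m: int = 5
    burn_in: int = 4000
    between: int = 1000
    include_cs: bool = False
    use_auxiliaries: bool = True
    prior_ig_shape: float = 0.001
    prior_ig_scale: float = 0.001
    threshold_bound: float = 8.0
    sigma_u_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.burn_in < 1 or self.between < 1:
            raise ValueError("burn_in and between must be >= 1")


class _VariableState:
    """Sampler state for one incomplete ordinal variable."""

    def __init__(self, name, n_cat, obs_mask, values, n_pred, rng):
        self.name = name
        self.n_cat = n_cat
        self.obs = obs_mask
        self.miss = ~obs_mask
        self.beta = np.zeros(n_pred)
        self.sigma2_u = 0.25
        self.latent = np.zeros(values.shape[0])
        # thresholds: tau[0] = 0 fixed; category k occupies (tau[k-2], tau[k-1])
        pc = np.clip(
            np.array([(values[obs_mask] <= c).mean() for c in range(1, n_cat)]),
            1e-3,
            1 - 1e-3,
        )
        pc = np.maximum.accumulate(pc + 1e-6 * np.arange(n_cat - 1))
        probits = ndtri(pc)
        self.tau = probits - probits[0]
        self.beta[0] = -probits[0]  # intercept consistent with tau[0] = 0
        self.latent = rng.standard_normal(values.shape[0]) * 0.5
        # observed categories are immutable: cache row indices per category
        self.obs_cat = values[obs_mask].astype(int)
        obs_idx = np.where(obs_mask)[0]
        self.cat_rows = {k: obs_idx[self.obs_cat == k] for k in range(1, n_cat + 1)}

    def bounds(self, cats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Threshold interval (lo, hi) for each observed category."""
        edges = np.concatenate([[-np.inf], self.tau, [np.inf]])
        return edges[cats - 1], edges[cats]


def _sweep_variable(
    st: _VariableState,
    pred: np.ndarray,
    codes: np.ndarray,
    n_clusters: int,
    u: np.ndarray,
    cfg: FCSConfig,
    rng: np.random.Generator,
    values: np.ndarray,
    cluster_counts: np.ndarray,
) -> np.ndarray:
    """One Gibbs update of a single variable; returns its new values."""
    # (1) latents for observed entries, truncated to the category interval
    mean = pred @ st.beta + u[codes]
    lo, hi = st.bounds(st.obs_cat)
    st.latent[st.obs] = mean[st.obs] + truncated_standard_normal(
        rng, lo - mean[st.obs], hi - mean[st.obs]
    )

    # (2) regression coefficients: flat prior => N(betahat, (X'X)^-1)
    target = st.latent - u[codes]
    XtX = pred.T @ pred
    cf = np.linalg.cholesky(XtX)
    betahat = np.linalg.solve(XtX, pred.T @ target)
    eps = rng.standard_normal(len(betahat))
    st.beta = betahat + np.linalg.solve(cf.T, eps)

    # (2b) cluster random intercepts
    resid = st.latent - pred @ st.beta
    if cfg.sigma_u_fixed is not None and cfg.sigma_u_fixed == 0.0:
        u[:] = 0.0
    else:
        rsum = np.bincount(codes, weights=resid, minlength=n_clusters)
        prec = cluster_counts + 1.0 / st.sigma2_u
        u[:] = rsum / prec + rng.standard_normal(n_clusters) / np.sqrt(prec)

    # (3) random-intercept variance
    if cfg.sigma_u_fixed is None:
        shape = cfg.prior_ig_shape + 0.5 * n_clusters
        scale = cfg.prior_ig_scale + 0.5 * float(u @ u)
        st.sigma2_u = scale / rng.gamma(shape)
    else:
        st.sigma2_u = max(cfg.sigma_u_fixed**2, 1e-12)

    # (4) free thresholds between adjacent latent order statistics
    B = cfg.threshold_bound
    for j in range(1, st.n_cat - 1):  # tau[0] fixed at 0
        below = st.latent[st.cat_rows[j + 1]]
        above = st.latent[st.cat_rows[j + 2]]
        lo_j = max(st.tau[j - 1], below.max() if below.size else -B)
        hi_j = min(st.tau[j + 1] if j + 1 < st.n_cat - 1 else B, above.min() if above.size else B)
        if hi_j <= lo_j:
            warnings.warn(
                f"degenerate threshold conditional for {st.name}; widening via prior bounds"
            )
            hi_j = lo_j + 1e-6
        st.tau[j] = rng.uniform(lo_j, hi_j)

    # (5) unconstrained latents for missing entries -> categories
    if np.any(st.miss):
        mean = pred @ st.beta + u[codes]
        st.latent[st.miss] = mean[st.miss] + rng.standard_normal(int(st.miss.sum()))
        new = values.copy()
        new[st.miss] = np.searchsorted(st.tau, st.latent[st.miss]) + 1
        return new
    return values


def fcs_impute(
    table: pd.DataFrame,
    c_map: dict[str, int],
    config: FCSConfig,
    rng: np.random.Generator,
) -> CompletedData:
    """Impute the incomplete ordinal columns of ``table`` by FCS.

    ``c_map`` gives the number of categories per ordinal column.  Rows must
    have complete ``x`` and ``z``; missingness is allowed only in the
    ordinal level-1 columns.  Returns M completed copies; observed cells are
    never modified.
    """
    for col in ("x", "z", "cluster"):
        if table[col].isna().any():
            raise ValueError(f"column {col!r} must be fully observed")
    variables = [v for v in ORDINAL_COLUMNS if v in c_map]
    if not config.use_auxiliaries:
        variables = [v for v in variables if v == "y"]
    codes, uniques = pd.factorize(table["cluster"], sort=True)
    n_clusters = len(uniques)
    n = len(table)
    sizes = np.bincount(codes).astype(float)

    x = table["x"].to_numpy(dtype=float)
    z = table["z"].to_numpy(dtype=float)
    cs = sizes[codes]

    obs_masks, values = {}, {}
    states: dict[str, _VariableState] = {}
    u_effects = {}
    for v in variables:
        raw = table[v].to_numpy(dtype=float)
        obs = ~np.isnan(raw)
        vals = raw.copy()
        if np.any(~obs):
            # initialise missing entries from the observed marginal
            observed_vals = raw[obs]
            vals[~obs] = rng.choice(observed_vals, size=int((~obs).sum()))
        obs_masks[v], values[v] = obs, vals
        n_pred = 1 + (len(variables) - 1) + 2 + (1 if config.include_cs else 0)
        states[v] = _VariableState(v, c_map[v], obs, vals, n_pred, rng)
        u_effects[v] = np.zeros(n_clusters)

    def design_for(v: str) -> np.ndarray:
        cols = [np.ones(n)]
        cols += [values[w] for w in variables if w != v]
        cols += [x, z]
        if config.include_cs:
            cols.append(cs)
        return np.column_stack(cols)

    cluster_counts = np.bincount(codes, minlength=n_clusters).astype(float)

    def run_sweep() -> None:
        for v in variables:
            values[v] = _sweep_variable(
                states[v],
                design_for(v),
                codes,
                n_clusters,
                u_effects[v],
                config,
                rng,
                values[v],
                cluster_counts,
            )

    def save_copy() -> pd.DataFrame:
        out = table.copy()
        for v in variables:
            col = out[v].to_numpy(dtype=float)
            col[~obs_masks[v]] = values[v][~obs_masks[v]]
            out[v] = col
        return out

    datasets = []
    total = 0
    for _ in range(config.burn_in):
        run_sweep()
        total += 1
    datasets.append(save_copy())
    while len(datasets) < config.m:
        for _ in range(config.between):
            run_sweep()
            total += 1
        datasets.append(save_copy())

    for v in variables:
        if not np.all(np.isfinite(states[v].beta)):
            raise RuntimeError(f"chain divergence in coefficients of {v} at sweep {total}")

    return CompletedData(
        datasets=datasets,
        method="fcs+cs" if config.include_cs else "fcs",
        n_sweeps=total,
        burn_in=config.burn_in,
        between=config.between,
        include_cs=config.include_cs,
        diagnostics={
            v: {"sigma2_u": states[v].sigma2_u, "tau": states[v].tau.copy()} for v in variables
        },
    )
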