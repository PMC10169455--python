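"""Synthetic clustered ordinal data with informative cluster size (ICS).

This module generates the kind of data that motivates cluster-weighted
analyses of periodontal outcomes: each cluster (subject) contributes up to
``max_size`` members (teeth), each member carries an ordinal outcome ``y``
and three ordinal auxiliaries ``m1``-``m3``, and the number of members per
cluster is itself driven by the latent health of the cluster, making cluster
size informative.

The generative model is a conditional cumulative-logit model with a
member-level random effect ``b_ij`` drawn from the bridge distribution,

    Pr(Y_ij <= c | b_ij) = expit{ b_ij + (eta_c + x_i' beta) / phi },

whose defining property is that integrating ``b`` out returns a marginal
proportional-odds logistic model with the *same* coefficients
``(eta, beta)``.  Within-cluster dependence is induced by drawing the
``b_ij`` of a cluster from a Gaussian copula with exchangeable correlation
and bridge marginals.  Cluster size is ``Binomial(max_size, lambda_i)`` with
``lambda_i = expit(nu * mean(b_i))``, so ``nu > 0`` links size to latent
health (informative cluster size).

Missingness is imposed afterwards through a logistic model on the member's
covariates, outcome and auxiliaries, with the intercept calibrated by Monte
Carlo to hit a target overall rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr

__all__ = [
    "GenerativeSpec",
    "MissingnessModel",
    "bridge_density",
    "bridge_quantile",
    "bridge_variance",
    "draw_cluster_effects",
    "draw_cluster_sizes",
    "simulate_full_table",
    "make_missingness_model",
    "default_aux_models",
    "calibrate_alpha0",
    "apply_missingness",
    "write_panel",
    "read_panel",
    "validate_panel",
]

ORDINAL_COLUMNS = ("y", "m1", "m2", "m3")

#: Default missingness slopes on (X, Z, Y, M1, M2, M3).  Mechanism tags zero
#: out entries: MCAR zeroes all six, MAR zeroes the outcome slope alpha_3.
#: The common auxiliary slope 0.4 is calibrated so that, at a 20% overall
#: outcome missing rate under MAR, the realized per-category missing-rate
#: profile is approximately (7%, 16%, 27%, 45%) across the four outcome
#: categories (see docs/methods.md).
DEFAULT_ALPHAS = (0.1, 0.2, 0.3, 0.4, 0.4, 0.4)


# ---------------------------------------------------------------------------
# bridge distribution
# ---------------------------------------------------------------------------

def bridge_density(b, phi: float):
    """Density of the bridge distribution,
    f(b | phi) = sin(phi*pi) / (2*pi * (cosh(phi*b) + cos(phi*pi))).
    """
    _check_phi(phi)
    b = np.asarray(b, dtype=float)
    return np.sin(phi * np.pi) / (2.0 * np.pi * (np.cosh(phi * b) + np.cos(phi * np.pi)))


def bridge_quantile(u, phi: float):
    """Quantile function of the bridge distribution.

    ``Q(u) = (1/phi) * log( sin(phi*pi*u) / sin(phi*pi*(1-u)) )``; applying
    it to i.i.d. uniforms yields draws with density :func:`bridge_density`.
    """
    _check_phi(phi)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    a = phi * np.pi
    return (np.log(np.sin(a * u)) - np.log(np.sin(a * (1.0 - u)))) / phi


def bridge_variance(phi: float) -> float:
    """Variance of the bridge distribution: pi^2 (phi^-2 - 1) / 3."""
    _check_phi(phi)
    return math.pi**2 * (phi**-2 - 1.0) / 3.0


def _check_phi(phi: float) -> None:
    if not (0.0 < phi < 1.0):
        raise ValueError(f"phi must lie in (0, 1), got {phi}")


# ---------------------------------------------------------------------------
# generative specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeSpec:
    """True parameters of the data-generating process.

    Parameters
    ----------
    n_clusters
        Number of clusters N (subjects).
    n_categories
        Number of ordinal categories C (>= 3) shared by outcome and
        auxiliaries.
    eta
        C-1 strictly increasing cutpoint intercepts on the logit scale.
    beta
        Coefficients (beta1 for the continuous X, beta2 for the binary Z).
    icc
        Intraclass correlation tau of the latent logistic scale, in [0, 1).
    ics_degree
        nu, degree of informative cluster size (0 switches ICS off).
    bridge_phi
        Bridge attenuation parameter phi in (0, 1).
    max_size
        Maximum cluster size (28 teeth for a full dentition).
    aux_etas
        Cutpoint vectors for the auxiliaries M1-M3; they share ``beta``
        and the member-level random effect with the outcome.
    """

    n_clusters: int = 50
    n_categories: int = 4
    eta: tuple[float, ...] = (-0.4, 0.8, 1.6)
    beta: tuple[float, float] = (-0.2, -0.5)
    icc: float = 0.3
    ics_degree: float = 0.1
    bridge_phi: float = 0.5
    max_size: int = 28
    aux_etas: tuple[tuple[float, ...], ...] = (
        (-0.8, 0.4, 1.2),
        (-0.2, 1.0, 1.8),
        (0.0, 1.2, 2.0),
    )

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_categories < 3:
            raise ValueError("n_categories must be >= 3")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        _check_phi(self.bridge_phi)
        if not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must lie in [0, 1)")
        for etas in (self.eta, *self.aux_etas):
            e = np.asarray(etas, dtype=float)
            if e.size != self.n_categories - 1:
                raise ValueError("each cutpoint vector needs n_categories - 1 entries")
            if np.any(np.diff(e) <= 0.0):
                raise ValueError("cutpoints must be strictly increasing")
        if len(self.aux_etas) != 3:
            raise ValueError("exactly three auxiliary cutpoint vectors required")
        if not (0.0 <= self.copula_rho < 1.0):
            raise ValueError(
                "icc / (1 - bridge_phi**2) must lie in [0, 1) for a valid "
                "exchangeable copula correlation"
            )

    @property
    def copula_rho(self) -> float:
        """Exchangeable Gaussian-copula correlation rho = tau / (1 - phi^2).

        The bridge random effect has variance pi^2 (phi^-2 - 1)/3 and the
        conditional logistic error has variance pi^2/3, so the share of
        latent variance owned by the random effect is 1 - phi^2; scaling the
        copula correlation by its inverse makes the latent-scale intraclass
        correlation equal ``icc``.
        """
        return self.icc / (1.0 - self.bridge_phi**2)


def draw_cluster_effects(
    spec: GenerativeSpec, rng: np.random.Generator, n_clusters: int | None = None
) -> np.ndarray:
    """Draw per-member bridge random effects, one row per cluster.

    Returns an ``(n_clusters, max_size)`` array: effects for every potential
    member, marginally bridge(phi), exchangeably correlated within a cluster
    through a one-factor Gaussian copula with correlation ``spec.copula_rho``,
    independent across clusters.
    """
    n = spec.n_clusters if n_clusters is None else n_clusters
    rho = spec.copula_rho
    g = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, spec.max_size))
    zscore = math.sqrt(rho) * g + math.sqrt(1.0 - rho) * e
    u = np.clip(ndtr(zscore), 1e-12, 1.0 - 1e-12)
    return bridge_quantile(u, spec.bridge_phi)


def draw_cluster_sizes(
    effects: np.ndarray,
    ics_degree: float,
    max_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw cluster sizes n_i ~ Binomial(max_size, expit(nu * mean(b_i))).

    ``mean(b_i)`` averages over all ``max_size`` potential members, so the
    size draw does not depend on which members end up retained.  Zero draws
    are redrawn (observed clusters have at least one member).
    """
    if effects.shape[1] != max_size:
        raise ValueError("effects must have max_size columns")
    lam = expit(ics_degree * effects.mean(axis=1))
    sizes = rng.binomial(max_size, lam)
    while np.any(sizes == 0):
        redo = sizes == 0
        sizes[redo] = rng.binomial(max_size, lam[redo])
    return sizes


def _draw_ordinal(
    b: np.ndarray,
    linpred: np.ndarray,
    etas: np.ndarray,
    phi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw categories from the conditional cumulative-logit model."""
    p_cum = expit(b[:, None] + (etas[None, :] + linpred[:, None]) / phi)
    if np.any(np.diff(p_cum, axis=1) < 0.0):
        raise RuntimeError("non-monotone cumulative probabilities")
    v = rng.random(b.shape[0])
    return 1 + (v[:, None] > p_cum).sum(axis=1)


def simulate_full_table(spec: GenerativeSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate a complete panel (no missing values).

    Cluster-level covariates are X ~ N(0, 2^2) and Z ~ Bernoulli(0.5).  The
    outcome and the three auxiliaries share the member-level bridge effect
    and the covariate coefficients; only the cutpoints differ, which makes
    the auxiliaries informative about the outcome.
    """
    effects = draw_cluster_effects(spec, rng)
    sizes = draw_cluster_sizes(effects, spec.ics_degree, spec.max_size, rng)
    n_total = int(sizes.sum())
    x = rng.normal(0.0, 2.0, spec.n_clusters)
    z = rng.integers(0, 2, spec.n_clusters)

    cluster = np.repeat(np.arange(1, spec.n_clusters + 1), sizes)
    member = np.concatenate([np.arange(1, s + 1) for s in sizes])
    keep = np.concatenate([effects[i, : sizes[i]] for i in range(spec.n_clusters)])
    linpred = spec.beta[0] * x + spec.beta[1] * z
    lin_rows = np.repeat(linpred, sizes)

    out = {"cluster": cluster, "member": member}
    for name, etas in zip(
        ORDINAL_COLUMNS, (spec.eta, *spec.aux_etas)
    ):
        out[name] = _draw_ordinal(
            keep, lin_rows, np.asarray(etas, dtype=float), spec.bridge_phi, rng
        ).astype(float)
    out["x"] = np.repeat(x, sizes)
    out["z"] = np.repeat(z, sizes).astype(float)
    table = pd.DataFrame(out)
    assert len(table) == n_total
    return table


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessModel:
    """Logistic missingness model for one variable.

    ``logit Pr(R=1) = alpha0 + alphas . (X, Z, Y, M1, M2, M3)``; ``R = 1``
    blanks the variable.  The mechanism tag must be consistent with the
    slopes: MCAR requires all six zero, MAR a zero outcome slope.
    """

    mechanism: str
    target_rate: float
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    alpha0: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "mar", "mnar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 < self.target_rate < 1.0):
            raise ValueError("target_rate must lie in (0, 1)")
        a = np.asarray(self.alphas, dtype=float)
        if a.size != 6:
            raise ValueError("alphas must have six entries (X, Z, Y, M1, M2, M3)")
        if self.mechanism == "mcar" and np.any(a != 0.0):
            raise ValueError("MCAR requires all slopes zero")
        if self.mechanism == "mar" and a[2] != 0.0:
            raise ValueError("MAR requires the outcome slope alpha_3 = 0")

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Slope part of the missingness logit evaluated on complete rows."""
        mat = table[["x", "z", "y", "m1", "m2", "m3"]].to_numpy(dtype=float)
        return mat @ np.asarray(self.alphas, dtype=float)


def make_missingness_model(
    mechanism: str,
    target_rate: float,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> MissingnessModel:
    """Build a missingness model, zeroing slopes as the mechanism requires."""
    a = np.asarray(alphas, dtype=float).copy()
    if mechanism == "mcar":
        a[:] = 0.0
    elif mechanism == "mar":
        a[2] = 0.0
    return MissingnessModel(mechanism=mechanism, target_rate=target_rate, alphas=tuple(a))


def default_aux_models(
    rates: tuple[float, float, float] = (0.3, 0.3, 0.1)
) -> tuple[MissingnessModel, ...]:
    """Missingness models for M1-M3: depend on the fully observed X and Z
    only, so auxiliary missingness is always ignorable."""
    return tuple(
        MissingnessModel(mechanism="mar", target_rate=r, alphas=(0.1, 0.2, 0, 0, 0, 0))
        for r in rates
    )


def calibrate_alpha0(
    model: MissingnessModel,
    pilot_tables: list[pd.DataFrame],
    target_rate: float | None = None,
    tol: float = 1e-10,
) -> float:
    """Root-find the intercept so the Monte-Carlo missing rate over the pilot
    rows equals the target.

    The expected rate ``mean(expit(alpha0 + s))`` is strictly increasing in
    ``alpha0``, so Brent's method on a wide bracket always succeeds unless
    the target is numerically unreachable.
    """
    target = model.target_rate if target_rate is None else target_rate
    s = np.concatenate([model.linear_predictor(t) for t in pilot_tables])

    def rate_gap(a0: float) -> float:
        return float(expit(a0 + s).mean() - target)

    lo, hi = -40.0, 40.0
    if rate_gap(lo) > 0.0 or rate_gap(hi) < 0.0:
        raise RuntimeError("target rate unreachable within intercept bounds")
    return float(brentq(rate_gap, lo, hi, xtol=tol))


def calibrated(
    model: MissingnessModel, pilot_tables: list[pd.DataFrame]
) -> MissingnessModel:
    """Return a copy of ``model`` with its intercept calibrated."""
    return replace(model, alpha0=calibrate_alpha0(model, pilot_tables))


def apply_missingness(
    table: pd.DataFrame,
    model: MissingnessModel,
    aux_models: tuple[MissingnessModel, ...],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Blank entries of y and m1-m3 according to calibrated logistic models.

    Returns a copy with NaN in blanked cells and 0/1 indicator columns
    ``r_y``, ``r_m1``, ``r_m2``, ``r_m3`` (1 = missing).  The input table
    must be complete; missingness probabilities are always evaluated on the
    complete values (the model may be MNAR).
    """
    if len(aux_models) != 3:
        raise ValueError("three auxiliary missingness models required")
    out = table.copy()
    for col, m in zip(ORDINAL_COLUMNS, (model, *aux_models)):
        if m.alpha0 is None:
            raise ValueError(f"missingness model for {col!r} is not calibrated")
        p = expit(m.alpha0 + m.linear_predictor(table))
        r = rng.random(len(table)) < p
        out.loc[r, col] = np.nan
        out[f"r_{col}"] = r.astype(int)
    return out


# ---------------------------------------------------------------------------
# panel I/O and validation
# ---------------------------------------------------------------------------

def write_panel(table: pd.DataFrame, path) -> None:
    """Write a panel as CSV with empty cells for missing values."""
    cols = ["cluster", "member", *ORDINAL_COLUMNS, "x", "z"]
    table[cols].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV produced by :func:`write_panel`."""
    table = pd.read_csv(path)
    table["cluster"] = table["cluster"].astype(int)
    table["member"] = table["member"].astype(int)
    for col in (*ORDINAL_COLUMNS, "x", "z"):
        table[col] = table[col].astype(float)
    return table


def validate_panel(table: pd.DataFrame, n_categories: int, max_size: int | None = None) -> None:
    """Check the panel invariants: level-2 covariates constant within
    cluster, ordinal values in range, cluster sizes within bounds."""
    for col in ("x", "z"):
        if table.groupby("cluster")[col].nunique().max() > 1:
            raise ValueError(f"{col!r} must be constant within a cluster")
    for col in ORDINAL_COLUMNS:
        vals = table[col].dropna()
        if len(vals) and (vals.min() < 1 or vals.max() > n_categories):
            raise ValueError(f"{col!r} has values outside 1..{n_categories}")
        if len(vals) and np.any(vals != np.round(vals)):
            raise ValueError(f"{col!r} has non-integer categories")
    sizes = table.groupby("cluster").size()
    if sizes.min() < 1:
        raise ValueError("every cluster must have at least one member")
    if max_size is not None and sizes.max() > max_size:
        raise ValueError(f"cluster size exceeds max_size={max_size}")
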