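"""Rubin's rules for combining multiply-imputed (CW)GEE fits.

With per-imputation estimates ``Q_m`` and covariance matrices ``W_m``
(m = 1..M), the pooled inference is

    Qbar = mean(Q_m)
    Wbar = mean(W_m)                      (within-imputation variance)
    B    = cov(Q_m)   (ddof = 1)          (between-imputation variance)
    T    = Wbar + (1 + 1/M) B             (total variance)

with per-parameter degrees of freedom
``df_k = (M - 1) (1 + Wbar_kk / ((1 + 1/M) B_kk))^2`` and t-based
confidence intervals; when a parameter has zero between-imputation variance
its interval degenerates to the normal interval.  An optional
Barnard-Rubin small-sample adjustment is available but off by default,
since the robust GEE variances being pooled are themselves large-sample
objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cwgee import CWGEEFit

__all__ = ["PooledFit", "rubin_pool"]


@dataclass
class PooledFit:
    """Rubin-pooled estimates and variance decomposition."""

    coefficients: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray
    df: np.ndarray
    names: list[str]
    m: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.total))

    def ci(self, level: float = 0.95, reference: str = "t") -> pd.DataFrame:
        """Confidence intervals from the pooled t (or normal) reference."""
        if reference == "t":
            crit = np.where(
                np.isfinite(self.df),
                stats.t.ppf(0.5 * (1 + level), np.maximum(self.df, 1e-8)),
                stats.norm.ppf(0.5 * (1 + level)),
            )
        elif reference == "normal":
            crit = stats.norm.ppf(0.5 * (1 + level))
        else:
            raise ValueError("reference must be 't' or 'normal'")
        se = self.se
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": se,
                "lower": self.coefficients - crit * se,
                "upper": self.coefficients + crit * se,
                "df": self.df,
            },
            index=self.names,
        )


def rubin_pool(fits: list[CWGEEFit], barnard_rubin: bool = False, n_obs: int | None = None) -> PooledFit:
    """Pool M per-imputation fits by Rubin's rules.

    All fits must share the parameterization and have converged; a
    non-converged fit indicates the completed dataset should be inspected,
    not silently averaged over.
    """
    if len(fits) < 2:
        raise ValueError("need at least M=2 fits to pool")
    bad = [i for i, f in enumerate(fits) if not f.converged]
    if bad:
        raise ValueError(f"non-converged fits at indices {bad}")
    names = fits[0].names
    if any(f.names != names for f in fits):
        raise ValueError("fits have mismatched parameter sets")

    M = len(fits)
    Q = np.stack([f.coefficients for f in fits])  # (M, K)
    W = np.stack([f.robust_vcov for f in fits])
    qbar = Q.mean(axis=0)
    wbar = W.mean(axis=0)
    dev = Q - qbar
    B = dev.T @ dev / (M - 1)
    T = wbar + (1.0 + 1.0 / M) * B

    bkk = np.diag(B)
    wkk = np.diag(wbar)
    with np.errstate(divide="ignore"):
        r = (1.0 + 1.0 / M) * bkk / wkk
        df = (M - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2
    df = np.where(bkk > 0, df, np.inf)
    if barnard_rubin:
        if n_obs is None:
            raise ValueError("Barnard-Rubin adjustment needs n_obs")
        k = len(qbar)
        lam = (1.0 + 1.0 / M) * bkk / np.diag(T)
        df_obs = (n_obs - k + 1) / (n_obs - k + 3) * (n_obs - k) * (1.0 - lam)
        df = 1.0 / (1.0 / df + 1.0 / np.maximum(df_obs, 1e-8))

    return PooledFit(
        coefficients=qbar, within=wbar, between=B, total=T, df=df, names=list(names), m=M
    )
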