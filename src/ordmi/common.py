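"""Shared pieces of the two imputation engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = ["CompletedData", "truncated_standard_normal", "stack_completed"]

_TINY = 1e-14


@dataclass
class CompletedData:
    """M completed copies of a panel plus sampler provenance."""

    datasets: list[pd.DataFrame]
    method: str
    n_sweeps: int
    burn_in: int
    between: int
    include_cs: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def stack_completed(completed: CompletedData) -> pd.DataFrame:
    """Stack the M completed tables with a 1-based ``.imp`` column."""
    frames = []
    for i, d in enumerate(completed.datasets, start=1):
        f = d.copy()
        f[".imp"] = i
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def truncated_standard_normal(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Vectorised draws from N(0,1) truncated to (lo, hi).

    Inverse-CDF sampling; bounds may be +-inf.  Deep-tail intervals whose
    probability underflows collapse to the nearer finite bound, which is the
    correct limit of the conditional distribution.
    """
    a = ndtr(lo)
    b = ndtr(hi)
    u = a + (b - a) * rng.random(np.broadcast(lo, hi).shape)
    draws = ndtri(np.clip(u, _TINY, 1.0 - _TINY))
    # guard against degenerate intervals in the extreme tails
    bad = ~np.isfinite(draws) | (b - a < _TINY)
    if np.any(bad):
        lo_f = np.where(np.isfinite(lo), lo, hi)
        hi_f = np.where(np.isfinite(hi), hi, lo)
        draws = np.where(bad, 0.5 * (lo_f + hi_f), draws)
    return np.clip(draws, lo, hi)
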