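"""Monte-Carlo study orchestration.

Runs the six analysis strategies (Full-data CWGEE, complete-case analysis,
FCS, FCS+CS, JM, JM+CS) over replicated simulated datasets and summarises
per-parameter performance with the six standard metrics: mean estimate,
mean robust SE, empirical SE, mean relative bias (%), 95% coverage (%),
and MSE.

Workflow per replicate: simulate a complete panel, impose calibrated
missingness, then each strategy produces an estimate and SE vector.  The
full-data fit uses the pre-amputation table; CCA drops rows with a missing
outcome and re-weights by the observed (post-deletion) cluster size; MI
strategies impute (M copies), fit each completed table and pool by Rubin's
rules.  Every fit uses inverse-cluster-size weighting.

Chain-length presets: ``full`` is the reference scale (burn-in 4000,
1000 sweeps between imputations); ``reduced`` (500/200) and ``fast``
(300/100) are shortened chains for desk-scale studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .cwgee import complete_cases, fit_cwgee
from .fcs import FCSConfig, fcs_impute
from .jm import JMConfig, jm_impute
from .pooling import rubin_pool
from .simulate import (
    GenerativeSpec,
    MissingnessModel,
    apply_missingness,
    calibrated,
    default_aux_models,
    make_missingness_model,
    simulate_full_table,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "StudyResult", "run_replication", "run_study", "summarize", "export_study"]

METHODS = ("full", "cca", "fcs", "fcs_cs", "jm", "jm_cs")
PRESETS = {"full": (4000, 1000), "reduced": (500, 200), "fast": (300, 100), "smoke": (25, 10)}

#: Supported grid values (sample size, ICC, degree of ICS, missing rate).
GRID = {"n_clusters": (50, 250), "icc": (0.0, 0.1, 0.3, 0.6), "ics_degree": (0.0, 0.1, 0.4), "rate": (0.2, 0.5)}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid."""

    gen: GenerativeSpec = field(default_factory=GenerativeSpec)
    mechanism: str = "mar"
    outcome_rate: float = 0.2
    aux_rates: tuple[float, float, float] = (0.3, 0.3, 0.1)
    n_replicates: int = 100
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    preset: str = "reduced"
    m_imputations: int = 5
    use_auxiliaries: bool = True  # False = misspecified imputation model
    n_pilot: int = 30
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")
        if self.gen.n_clusters not in GRID["n_clusters"]:
            logger.info("sample size %d outside the standard grid", self.gen.n_clusters)

    @property
    def truth(self) -> np.ndarray:
        return np.concatenate([self.gen.eta, self.gen.beta])

    @property
    def parameter_names(self) -> list[str]:
        C = self.gen.n_categories
        return [f"eta_{c}" for c in range(1, C)] + ["beta_x", "beta_z"]


def _rng_for(spec: ScenarioSpec, purpose: int, replicate: int = 0) -> np.random.Generator:
    """Deterministic per-(scenario, purpose, replicate) generator."""
    return np.random.default_rng(np.random.SeedSequence([spec.seed, purpose, replicate]))


def calibrate_models(spec: ScenarioSpec) -> tuple[MissingnessModel, tuple[MissingnessModel, ...]]:
    """Calibrate the missingness intercepts on fresh pilot tables."""
    rng = _rng_for(spec, purpose=0)
    pilots = [simulate_full_table(spec.gen, rng) for _ in range(spec.n_pilot)]
    outcome = calibrated(make_missingness_model(spec.mechanism, spec.outcome_rate), pilots)
    aux = tuple(calibrated(m, pilots) for m in default_aux_models(spec.aux_rates))
    return outcome, aux


def _chain_config(spec: ScenarioSpec, kind: str, include_cs: bool):
    burn, between = PRESETS[spec.preset]
    cls = FCSConfig if kind == "fcs" else JMConfig
    return cls(
        m=spec.m_imputations,
        burn_in=burn,
        between=between,
        include_cs=include_cs,
        use_auxiliaries=spec.use_auxiliaries,
    )


def run_replication(
    spec: ScenarioSpec,
    replicate_index: int,
    outcome_model: MissingnessModel,
    aux_models: tuple[MissingnessModel, ...],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Run one replicate; returns method -> (estimates, SEs).

    A method that fails (non-convergence, sampler divergence) is recorded
    as absent for this replicate; other methods are unaffected.
    """
    rng = _rng_for(spec, purpose=1, replicate=replicate_index)
    full = simulate_full_table(spec.gen, rng)
    amputed = apply_missingness(full, outcome_model, aux_models, rng)
    C = spec.gen.n_categories
    c_map = {v: C for v in ("y", "m1", "m2", "m3")}

    results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for method in spec.methods:
        try:
            if method == "full":
                fit = fit_cwgee(full, C)
                results[method] = (fit.coefficients, fit.se)
            elif method == "cca":
                fit = fit_cwgee(complete_cases(amputed), C)
                results[method] = (fit.coefficients, fit.se)
            else:
                include_cs = method.endswith("_cs")
                if method.startswith("fcs"):
                    cfg = _chain_config(spec, "fcs", include_cs)
                    completed = fcs_impute(amputed, c_map, cfg, rng)
                else:
                    cfg = _chain_config(spec, "jm", include_cs)
                    completed = jm_impute(amputed, c_map, cfg, rng)
                fits = [fit_cwgee(d, C) for d in completed.datasets]
                pooled = rubin_pool(fits)
                results[method] = (pooled.coefficients, pooled.se)
        except Exception:  # noqa: BLE001 - per-method failure is a study event
            logger.exception("replicate %d method %s failed", replicate_index, method)
    return results


def summarize(
    estimates: np.ndarray,
    ses: np.ndarray,
    truth: np.ndarray,
    parameter_names: list[str],
    method: str,
    scenario_id: str,
    level_z: float = float(ndtri(0.975)),
) -> pd.DataFrame:
    """Six performance metrics per parameter over the replicate axis.

    ``estimates``/``ses`` are (R, K).  Relative bias is undefined for a
    zero true value and reported as NaN (the absolute ``bias`` column is
    always available).
    """
    if estimates.shape[0] < 2:
        raise ValueError("need at least two successful replicates")
    mean_est = estimates.mean(axis=0)
    mean_se = ses.mean(axis=0)
    emp_se = estimates.std(axis=0, ddof=1)
    bias = mean_est - truth
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(truth != 0, 100.0 * ((estimates - truth) / truth).mean(axis=0), np.nan)
    covered = np.abs(estimates - truth) <= level_z * ses
    cov = 100.0 * covered.mean(axis=0)
    mse = ((estimates - truth) ** 2).mean(axis=0)
    return pd.DataFrame(
        {
            "scenario": scenario_id,
            "method": method,
            "parameter": parameter_names,
            "true_value": truth,
            "mean_est": mean_est,
            "mean_se": mean_se,
            "empirical_se": emp_se,
            "bias": bias,
            "rel_bias_pct": rel,
            "cov_prob_pct": cov,
            "mse": mse,
            "n_successful_replicates": estimates.shape[0],
        }
    )


@dataclass
class StudyResult:
    """Raw per-replicate draws and the metric table for one scenario."""

    spec: ScenarioSpec
    estimates: dict[str, np.ndarray]
    ses: dict[str, np.ndarray]
    metrics: pd.DataFrame
    failures: dict[str, int]


def run_study(spec: ScenarioSpec, progress: bool = False) -> StudyResult:
    """Run all replicates of one scenario and summarise."""
    outcome_model, aux_models = calibrate_models(spec)
    per_method: dict[str, list] = {m: [] for m in spec.methods}
    for r in range(spec.n_replicates):
        res = run_replication(spec, r, outcome_model, aux_models)
        for m, pair in res.items():
            per_method[m].append(pair)
        if progress and (r + 1) % 20 == 0:
            logger.info("%s: %d/%d replicates", spec.scenario_id, r + 1, spec.n_replicates)

    estimates, ses, failures = {}, {}, {}
    frames = []
    for m in spec.methods:
        pairs = per_method[m]
        failures[m] = spec.n_replicates - len(pairs)
        if len(pairs) < 2:
            logger.warning("method %s: fewer than 2 successful replicates", m)
            continue
        estimates[m] = np.stack([p[0] for p in pairs])
        ses[m] = np.stack([p[1] for p in pairs])
        frames.append(
            summarize(estimates[m], ses[m], spec.truth, spec.parameter_names, m, spec.scenario_id)
        )
    metrics = pd.concat(frames, ignore_index=True)
    return StudyResult(spec=spec, estimates=estimates, ses=ses, metrics=metrics, failures=failures)


def export_study(
    results: list[StudyResult], out_table, out_tidy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the metric rows in two layouts.

    ``out_table``: one CSV in the familiar results-table shape (rows =
    scenario x parameter x method, metric columns).  ``out_tidy``: a tidy
    nested-loop layout with explicit ordering columns, sorted
    lexicographically by (parameter, ics_degree, icc, n_clusters).
    """
    rows = []
    for res in results:
        df = res.metrics.copy()
        df["n_clusters"] = res.spec.gen.n_clusters
        df["icc"] = res.spec.gen.icc
        df["ics_degree"] = res.spec.gen.ics_degree
        df["mechanism"] = res.spec.mechanism
        df["outcome_rate"] = res.spec.outcome_rate
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    tidy = table.sort_values(
        ["parameter", "ics_degree", "icc", "n_clusters", "method"], kind="mergesort"
    ).reset_index(drop=True)
    if out_table is not None:
        table.to_csv(out_table, index=False)
    if out_tidy is not None:
        tidy.to_csv(out_tidy, index=False)
    return table, tidy
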