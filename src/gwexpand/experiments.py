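"""Replicate-level drivers: false-positive error rate and power estimation.

Each replicate simulates a study (source cases/controls plus external
cohorts), computes IBS from the null structure panel, extracts MDS axes,
and runs the three trend tests.  Summaries mirror the standard reporting
layout: rejection rate at the test level, mean allelic odds ratio and its
empirical 5th/95th percentiles across replicates.

Replicates draw their RNG streams deterministically from (base_seed,
replicate index), so any execution order — or a resumed run — yields the
identical summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocResult, run_three_tests
from .ibs_mds import classical_mds, ibs_matrix
from .simulate import SimulationConfig, replicate_rng, simulate_replicate

logger = logging.getLogger("gwexpand")

TEST_NAMES = ("T_CC", "T_F", "T_Fmds")

STRATEGIES = ("select@0.05", "select@0.10", "all-axes", "t_max=10")

__all__ = [
    "ExperimentSummary",
    "run_replicate",
    "estimate_error_rate",
    "estimate_power",
    "sensitivity_analysis",
    "STRATEGIES",
]


@dataclass
class ExperimentSummary:
    """Per-test Monte-Carlo summary of one simulation condition."""

    fst: tuple[float, ...]
    n_reps: int
    rejection_rate: dict[str, float]
    mean_or: dict[str, float]
    or_p5: dict[str, float]
    or_p95: dict[str, float]
    n_degenerate: dict[str, int]
    alpha_test: float
    prop_gt3_axes: float | None = None  # only tracked when t_max > 3

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in TEST_NAMES:
            rows.append({
                "test": t,
                "rejection_rate": self.rejection_rate[t],
                "mean_or": self.mean_or[t],
                "or_p5": self.or_p5[t],
                "or_p95": self.or_p95[t],
                "n_reps": self.n_reps,
                "n_degenerate": self.n_degenerate[t],
            })
        return pd.DataFrame(rows)


def run_replicate(
    config: SimulationConfig,
    rep_seed_or_rng,
    selection: str = "forward",
    alpha_select: float | None = None,
    t_max: int | None = None,
) -> tuple[AssocResult, AssocResult, AssocResult]:
    """Simulate one replicate and return its (T_CC, T_F, T_Fmds) results."""
    data = simulate_replicate(config, rep_seed_or_rng)
    sim = ibs_matrix(data.null_genotypes)
    mds = classical_mds(sim, t_max if t_max is not None else config.t_max_axes)
    return run_three_tests(
        data, mds,
        t_max=t_max if t_max is not None else config.t_max_axes,
        alpha_select=alpha_select if alpha_select is not None else config.alpha_select,
        selection=selection,
    )


def _summarize(
    config: SimulationConfig,
    results: list[tuple[AssocResult, AssocResult, AssocResult]],
    n_big_axes: int | None,
) -> ExperimentSummary:
    n_reps = len(results)
    alpha = config.alpha_test
    rej, mean_or, p5, p95, ndeg = {}, {}, {}, {}, {}
    for idx, t in enumerate(TEST_NAMES):
        per = [r[idx] for r in results]
        # degenerate replicates are non-rejections by construction (P = 1)
        rej[t] = float(np.mean([r.p_value < alpha for r in per]))
        ors = np.array([r.odds_ratio for r in per
                        if r.status == "ok" and np.isfinite(r.odds_ratio)])
        if ors.size:
            mean_or[t] = float(ors.mean())
            p5[t] = float(np.quantile(ors, 0.05))   # type-7 interpolation
            p95[t] = float(np.quantile(ors, 0.95))
        else:
            mean_or[t] = p5[t] = p95[t] = float("nan")
        ndeg[t] = sum(r.status != "ok" for r in per)
        if ndeg[t]:
            logger.info("%s: %d/%d degenerate replicates", t, ndeg[t], n_reps)
    prop = None if n_big_axes is None else n_big_axes / n_reps
    return ExperimentSummary(config.fst, n_reps, rej, mean_or, p5, p95, ndeg,
                             alpha, prop)


def _run_condition(
    config: SimulationConfig,
    n_reps: int,
    base_seed: int,
    selection: str = "forward",
    alpha_select: float | None = None,
    t_max: int | None = None,
) -> ExperimentSummary:
    results = []
    n_big = 0
    track_big = (t_max or config.t_max_axes) > 3
    for rep in range(n_reps):
        rng = replicate_rng(base_seed, rep)
        data = simulate_replicate(config, rng)
        sim = ibs_matrix(data.null_genotypes)
        tm = t_max if t_max is not None else config.t_max_axes
        mds = classical_mds(sim, tm)
        res = run_three_tests(
            data, mds, t_max=tm,
            alpha_select=alpha_select if alpha_select is not None
            else config.alpha_select,
            selection=selection,
        )
        if track_big and any(a >= 3 for a in res[2].axes_used):
            n_big += 1
        results.append(res)
        if (rep + 1) % 100 == 0:
            logger.info("replicate %d/%d done", rep + 1, n_reps)
    return _summarize(config, results, n_big if track_big else None)


def estimate_error_rate(
    config: SimulationConfig, n_reps: int, base_seed: int
) -> ExperimentSummary:
    """False-positive error rate of the three tests under the null (GRR = 1)."""
    if config.disease.het_grr != 1.0:
        raise ValueError("error-rate estimation requires het_grr = 1")
    return _run_condition(config, n_reps, base_seed)


def estimate_power(
    config: SimulationConfig, n_reps: int, base_seed: int
) -> ExperimentSummary:
    """Power of the three tests under the alternative (GRR > 1)."""
    if config.disease.het_grr <= 1.0:
        raise ValueError("power estimation requires het_grr > 1")
    return _run_condition(config, n_reps, base_seed)


def grr_sweep(
    config: SimulationConfig,
    grr_grid: np.ndarray,
    n_reps: int,
    base_seed: int,
) -> pd.DataFrame:
    """Rejection rates over a genotype-relative-risk grid (power-curve data)."""
    rows = []
    for i, grr in enumerate(grr_grid):
        disease = dataclasses.replace(config.disease, het_grr=float(grr))
        cfg = dataclasses.replace(config, disease=disease)
        # distinct, deterministic seed block per grid point
        summary = _run_condition(cfg, n_reps, base_seed + 1_000_003 * i)
        for t in TEST_NAMES:
            rows.append({"grr": float(grr), "test": t,
                         "rejection_rate": summary.rejection_rate[t]})
    return pd.DataFrame(rows)


def sensitivity_analysis(
    config: SimulationConfig, n_reps: int, base_seed: int, strategy: str
) -> ExperimentSummary:
    """Re-run the pipeline under an alternative axis-selection strategy.

    Strategies: ``select@0.05`` (reference), ``select@0.10`` (looser
    retention threshold), ``all-axes`` (force all first three axes in),
    ``t_max=10`` (forward selection over the first ten axes; the summary
    also reports the proportion of replicates retaining any axis beyond
    the third).
    """
    if strategy == "select@0.05":
        return _run_condition(config, n_reps, base_seed, alpha_select=0.05)
    if strategy == "select@0.10":
        return _run_condition(config, n_reps, base_seed, alpha_select=0.10)
    if strategy == "all-axes":
        return _run_condition(config, n_reps, base_seed, selection="all")
    if strategy == "t_max=10":
        return _run_condition(config, n_reps, base_seed, t_max=10)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
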