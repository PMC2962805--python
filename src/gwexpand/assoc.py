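"""Logistic-regression trend tests with structure adjustment.

The machinery behind the three association tests:

* ``T_CC``   — cases vs within-study controls, no adjustment;
* ``T_F``    — cases vs the expanded control group (within-study controls
  plus all external samples), no adjustment;
* ``T_Fmds`` — the expanded-control contrast adjusted for MDS axes of
  genetic variation that are themselves associated with phenotype.

All tests are 1-df likelihood-ratio "trend" tests of the additive dosage
term in a logistic model; axis selection is a forward pass over axes in
decreasing-eigenvalue order, retaining any axis whose LRT P-value clears
the selection threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .ibs_mds import MDSResult
from .simulate import StudyData

logger = logging.getLogger("gwexpand")

SEPARATION_BOUND = 15.0  # |coef| beyond this => quasi-separation, flag the fit

__all__ = [
    "LogisticFit",
    "AxisSelection",
    "AssocResult",
    "fit_logistic",
    "likelihood_ratio_test",
    "select_axes",
    "trend_test",
    "run_three_tests",
]


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int


@dataclass
class AxisSelection:
    """Forward-selection outcome: per-axis retain indicators and P-values."""

    indicators: np.ndarray  # z_t in {0,1}, one per tested axis
    p_values: np.ndarray
    threshold: float

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.indicators == 1)


@dataclass
class AssocResult:
    test: str
    beta: float
    odds_ratio: float
    lrt: float
    p_value: float
    axes_used: tuple[int, ...] = ()
    status: str = "ok"          # ok | degenerate
    fit: LogisticFit | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_logistic(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``X`` must include its intercept column.  Convergence is declared when
    the log-likelihood moves by less than 1e-10; quasi-separation (any
    non-intercept coefficient beyond ``SEPARATION_BOUND`` in magnitude)
    flags the fit as not converged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("shape mismatch between y and X")
    if y.min() == y.max():
        raise ValueError("response takes a single value; both classes required")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X)
        dep = np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())
        raise ValueError(f"design matrix is rank deficient (columns {dep.tolist()})")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    ll = 0.0
    for it in range(1, 101):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
        if abs(ll - ll_old) < 1e-10:
            break
        ll_old = ll
        w = p * (1.0 - p)
        xtw = X.T * w
        try:
            beta = np.linalg.solve(xtw @ X, xtw @ eta + X.T @ (y - p))
        except np.linalg.LinAlgError:
            return LogisticFit(beta, ll, False, it)
    else:
        return LogisticFit(beta, ll, False, 100)
    # scale-invariant quasi-separation check: a coefficient is suspect when
    # one standard deviation of its covariate moves the log-odds beyond the
    # bound (raw |beta| for binary/unit-scale columns, where sd <= 1)
    sd = X[:, 1:].std(axis=0) if X.shape[1] > 1 else np.empty(0)
    effect = np.abs(beta[1:]) * np.where(sd > 0, np.minimum(sd, 1.0), 1.0)
    separated = bool(np.any(effect > SEPARATION_BOUND))
    return LogisticFit(beta, ll, not separated, it)


def likelihood_ratio_test(
    fit_null: LogisticFit, fit_alt: LogisticFit, df: int
) -> tuple[float, float]:
    """LRT statistic 2*(ll_alt - ll_null) (floored at 0) and chi-square P."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if stat < -1e-6:
        raise RuntimeError(
            f"alternative fit has lower likelihood than null (LRT={stat:.3g}); "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# axis selection
# ---------------------------------------------------------------------------

def select_axes(
    y: np.ndarray,
    mds: MDSResult,
    t_max: int,
    alpha_select: float = 0.05,
    mode: str = "conditional",
) -> AxisSelection:
    """Forward selection of phenotype-associated axes of genetic variation.

    Axes are tested in decreasing-eigenvalue order.  In ``conditional``
    mode (default) the null model at each step carries the previously
    retained axes; in ``marginal`` mode each axis is tested against the
    intercept-only model.  A non-converged axis fit is never retained.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown selection mode {mode!r}")
    t_max = int(t_max)
    n_axes = min(t_max, mds.n_axes)
    if t_max == 0 or n_axes == 0:
        return AxisSelection(np.zeros(0, dtype=int), np.zeros(0), alpha_select)

    y = np.asarray(y, dtype=float)
    ones = np.ones((y.size, 1))
    retained: list[int] = []
    indicators = np.zeros(n_axes, dtype=int)
    pvals = np.ones(n_axes)
    base_cols = [ones]
    fit_null = fit_logistic(y, ones)
    for t in range(n_axes):
        axis = mds.scores[:, t : t + 1]
        if mode == "marginal":
            null_fit = fit_logistic(y, ones)
            alt = fit_logistic(y, np.hstack([ones, axis]))
        else:
            null_fit = fit_null
            alt = fit_logistic(y, np.hstack(base_cols + [axis]))
        if not alt.converged:
            logger.warning("axis %d fit flagged (separation); not retained", t + 1)
            pvals[t] = 1.0
            continue
        _, p = likelihood_ratio_test(null_fit, alt, df=1)
        pvals[t] = p
        if p < alpha_select:
            indicators[t] = 1
            retained.append(t)
            if mode == "conditional":
                base_cols.append(axis)
                fit_null = alt
    return AxisSelection(indicators, pvals, alpha_select)


# ---------------------------------------------------------------------------
# trend tests
# ---------------------------------------------------------------------------

def trend_test(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    test_name: str = "trend",
    axes_used: tuple[int, ...] = (),
) -> AssocResult:
    """1-df LRT of the additive dosage term, adjusted for given covariates.

    A monomorphic SNP yields a degenerate result (P = 1, odds ratio
    undefined) rather than an error so that replicate loops never abort.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if g.size != y.size:
        raise ValueError("dosage vector length mismatch")
    ones = np.ones((y.size, 1))
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x_null = ones
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        x_null = np.hstack([ones, covariates])
    if g.min() == g.max():
        return AssocResult(test_name, float("nan"), float("nan"), 0.0, 1.0,
                           axes_used, status="degenerate")
    fit0 = fit_logistic(y, x_null)
    fit1 = fit_logistic(y, np.hstack([x_null, g[:, None]]))
    stat, p = likelihood_ratio_test(fit0, fit1, df=1)
    beta = float(fit1.coefficients[-1])
    return AssocResult(test_name, beta, float(np.exp(beta)), stat, p,
                       axes_used, status="ok" if fit1.converged else "degenerate",
                       fit=fit1)


def _minor_allele_code(g: np.ndarray) -> np.ndarray:
    """Recode dosages so they count the minor allele of the combined sample."""
    g = np.asarray(g, dtype=float)
    if g.mean() > 1.0:  # allele frequency above 0.5
        return 2.0 - g
    return g


def run_three_tests(
    data: StudyData,
    mds: MDSResult,
    t_max: int = 3,
    alpha_select: float = 0.05,
    selection: str = "forward",
    selection_mode: str = "conditional",
) -> tuple[AssocResult, AssocResult, AssocResult]:
    """T_CC, T_F and T_Fmds for one replicate's disease SNP.

    ``selection='forward'`` runs forward selection over the first ``t_max``
    axes at ``alpha_select``; ``selection='all'`` forces all first ``t_max``
    axes into the adjusted model regardless of association.  When no axis
    is selected, T_Fmds is the identical model to T_F, statistic and all.
    """
    labels = data.cohort_label
    is_source = (labels == "case") | (labels == "control")
    y_full = np.asarray(data.phenotype, dtype=float)
    g_full = _minor_allele_code(data.test_genotypes)

    t_cc = trend_test(y_full[is_source], g_full[is_source], None, "T_CC")
    t_f = trend_test(y_full, g_full, None, "T_F")

    if selection == "all":
        chosen = tuple(range(min(int(t_max), mds.n_axes)))
    elif selection == "forward":
        sel = select_axes(y_full, mds, t_max, alpha_select, mode=selection_mode)
        chosen = tuple(int(t) for t in sel.selected)
    else:
        raise ValueError(f"unknown selection strategy {selection!r}")

    if chosen:
        cov = mds.scores[:, list(chosen)]
        t_fmds = trend_test(y_full, g_full, cov, "T_Fmds", axes_used=chosen)
    else:
        t_fmds = AssocResult("T_Fmds", t_f.beta, t_f.odds_ratio, t_f.lrt,
                             t_f.p_value, (), t_f.status, t_f.fit)
    return t_cc, t_f, t_fmds
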