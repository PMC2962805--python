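"""Closed-form power for the 1-df additive trend test.

Under the multiplicative disease model the genotype distributions in
ascertained cases and unaffected controls are fully determined by the
risk-allele frequency q, the heterozygous genotype relative risk g and
the prevalence K.  The trend test compares mean dosages; its large-sample
non-centrality is

    ncp = (mu_case - mu_ctrl)^2 / (sigma^2 * (1/n_case + 1/n_ctrl))

with sigma^2 the phenotype-pooled dosage variance, and power is the upper
tail of a 1-df noncentral chi-square past the central (1 - alpha) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ncx2

from .simulate import DiseaseModel, genotype_distributions

__all__ = ["PowerQuery", "analytic_trend_power"]


@dataclass(frozen=True)
class PowerQuery:
    n_cases: int
    n_controls: int
    risk_allele_freq: float
    het_grr: float
    prevalence: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        # DiseaseModel validates q, grr, prevalence and feasibility
        DiseaseModel(self.prevalence, self.het_grr, self.risk_allele_freq)


def _noncentrality(query: PowerQuery) -> float:
    model = DiseaseModel(query.prevalence, query.het_grr, query.risk_allele_freq)
    p_case, p_ctrl = genotype_distributions(model)
    dosages = np.array([0.0, 1.0, 2.0])
    mu_case = float(p_case @ dosages)
    mu_ctrl = float(p_ctrl @ dosages)
    n1, n0 = query.n_cases, query.n_controls
    w = n1 / (n1 + n0)
    p_pool = w * p_case + (1.0 - w) * p_ctrl
    var = float(p_pool @ dosages**2 - (p_pool @ dosages) ** 2)
    return (mu_case - mu_ctrl) ** 2 / (var * (1.0 / n1 + 1.0 / n0))


def analytic_trend_power(query: PowerQuery) -> float:
    """Power of the trend test at significance level ``query.alpha``.

    Returns exactly ``alpha`` when the relative risk is 1 (zero
    non-centrality) and approaches 1 as the non-centrality grows.
    """
    if query.het_grr == 1.0:
        return query.alpha  # zero non-centrality exactly
    ncp = _noncentrality(query)
    crit = chi2.ppf(1.0 - query.alpha, df=1)
    return float(ncx2.sf(crit, df=1, nc=ncp))
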