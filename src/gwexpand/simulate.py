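"""Replicate simulation for expanded-control association studies.

Each replicate consists of cases and controls drawn from a single source
population together with samples from one or more external cohorts that are
unselected for the phenotype.  Allele-frequency divergence between the source
population and each external cohort follows the Balding-Nichols model: the
cohort frequency at a SNP with source frequency ``q`` is a draw from
``Beta(q(1-Fst)/Fst, (1-q)(1-Fst)/Fst)``, which has mean ``q`` and variance
``Fst * q(1-q)``.

Genotypes are sampled under Hardy-Weinberg equilibrium everywhere except at
the disease SNP in the source case-control sample, where a multiplicative
penetrance model applies: genotype penetrances are ``f0, f0*g, f0*g**2`` for
0/1/2 copies of the risk allele, with heterozygous genotype relative risk
``g`` and baseline penetrance ``f0`` fixed by the population prevalence.

A panel of unlinked null SNPs (not associated with disease) is generated per
replicate; it is the substrate for identity-by-state relationships and never
includes the disease SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = -1  # missing-genotype marker in integer dosage matrices

__all__ = [
    "MISSING",
    "DiseaseModel",
    "SimulationConfig",
    "GenotypeMatrix",
    "StudyData",
    "derive_baseline_penetrance",
    "diverge_frequency",
    "sample_hwe_genotypes",
    "sample_case_control_genotypes",
    "simulate_replicate",
    "replicate_rng",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseModel:
    """Multiplicative disease model at a single biallelic SNP.

    Parameters
    ----------
    prevalence
        Population disease prevalence ``K`` (probability).
    het_grr
        Heterozygous genotype relative risk ``g`` (> 0); homozygote risk
        is ``g**2`` (multiplicative model).
    risk_allele_freq
        Risk-allele frequency ``q`` in the source population, in (0, 1).
    """

    prevalence: float
    het_grr: float
    risk_allele_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.het_grr <= 0.0:
            raise ValueError(f"het_grr must be > 0, got {self.het_grr}")
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(
                f"risk_allele_freq must be in (0,1), got {self.risk_allele_freq}"
            )
        derive_baseline_penetrance(self)  # raises if infeasible


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one simulation condition."""

    n_cases: int = 100
    n_controls: int = 100
    external_cohort_sizes: tuple[int, ...] = (100, 100, 100)
    n_null_snps: int = 10_000
    fst: tuple[float, ...] = (0.0, 0.0, 0.0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    disease: DiseaseModel = field(
        default_factory=lambda: DiseaseModel(0.001, 1.0, 0.2)
    )
    t_max_axes: int = 3
    alpha_select: float = 0.05
    alpha_test: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_cases, self.n_controls, self.n_null_snps,
                  *self.external_cohort_sizes)
        if any(int(c) < 1 for c in counts):
            raise ValueError("all sample/SNP counts must be >= 1")
        if len(self.fst) != len(self.external_cohort_sizes):
            raise ValueError(
                f"fst has {len(self.fst)} entries for "
                f"{len(self.external_cohort_sizes)} external cohorts"
            )
        if any(not 0.0 <= f < 1.0 for f in self.fst):
            raise ValueError("each fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low < high <= 0.5, got {self.maf_range}")
        if not 0.0 < self.alpha_select < 1.0 or not 0.0 < self.alpha_test < 1.0:
            raise ValueError("alpha_select and alpha_test must be in (0,1)")
        # normalise container types so configs hash/compare predictably
        object.__setattr__(self, "external_cohort_sizes",
                           tuple(int(s) for s in self.external_cohort_sizes))
        object.__setattr__(self, "fst", tuple(float(f) for f in self.fst))
        object.__setattr__(self, "maf_range",
                           (float(lo), float(hi)))

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls + sum(self.external_cohort_sizes)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs integer dosage matrix; ``MISSING`` marks no-calls."""

    values: np.ndarray  # (n_samples, n_snps), int8, entries in {0,1,2,MISSING}
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample ids / {len(self.snp_ids)} snp ids"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("genotype matrix must be integer-typed")
        if self.values.size and (self.values.min() < MISSING or self.values.max() > 2):
            bad = np.unique(self.values[(self.values < MISSING) | (self.values > 2)])
            raise ValueError(f"genotype entries outside {{0,1,2,missing}}: {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class StudyData:
    """One simulated replicate: structure panel, disease SNP, labels."""

    null_genotypes: GenotypeMatrix
    test_genotypes: np.ndarray      # dosage vector at the disease SNP
    phenotype: np.ndarray           # 1 = source case, 0 otherwise
    cohort_label: np.ndarray        # strings: case / control / external-<j>

    def __post_init__(self) -> None:
        n = self.null_genotypes.n_samples
        if not (len(self.test_genotypes) == len(self.phenotype)
                == len(self.cohort_label) == n):
            raise ValueError("per-sample vectors disagree on length")
        if not np.array_equal(self.phenotype == 1, self.cohort_label == "case"):
            raise ValueError("phenotype=1 must coincide with cohort 'case'")


# ---------------------------------------------------------------------------
# disease model arithmetic
# ---------------------------------------------------------------------------

def derive_baseline_penetrance(model: DiseaseModel) -> float:
    """Baseline penetrance f0 with K = f0 * [(1-q)^2 + 2q(1-q)g + q^2 g^2].

    Raises ``ValueError`` when the implied homozygote penetrance f0*g**2
    exceeds 1 (infeasible configuration).
    """
    q, g, k = model.risk_allele_freq, model.het_grr, model.prevalence
    mean_rr = (1 - q) ** 2 + 2 * q * (1 - q) * g + q * q * g * g
    f0 = k / mean_rr
    if f0 * g * g > 1.0:
        raise ValueError(
            f"infeasible disease model: homozygote penetrance "
            f"f0*g^2 = {f0 * g * g:.4g} > 1"
        )
    return f0


def genotype_distributions(model: DiseaseModel) -> tuple[np.ndarray, np.ndarray]:
    """P(G | case) and P(G | unaffected) for G = 0, 1, 2 under HWE + model."""
    q, g = model.risk_allele_freq, model.het_grr
    f0 = derive_baseline_penetrance(model)
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    pen = f0 * np.array([1.0, g, g * g])
    p_case = hwe * pen
    p_case /= p_case.sum()
    p_ctrl = hwe * (1.0 - pen)
    p_ctrl /= p_ctrl.sum()
    return p_case, p_ctrl


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def diverge_frequency(q, fst: float, rng: np.random.Generator):
    """Balding-Nichols draw of a diverged cohort allele frequency.

    ``q`` may be a scalar or an array (one draw per entry).  ``fst = 0`` is
    the degenerate case and returns ``q`` exactly.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("source frequency must lie strictly in (0,1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"fst must lie in [0,1), got {fst}")
    if fst == 0.0:
        return q.copy() if q.ndim else float(q)
    scale = (1.0 - fst) / fst
    out = rng.beta(q * scale, (1.0 - q) * scale)
    return out if q.ndim else float(out)


def _hwe_from_uniform(u: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Map uniforms to HWE dosages via the genotype CDF; q broadcasts over columns."""
    c0 = (1.0 - q) ** 2
    c1 = c0 + 2.0 * q * (1.0 - q)
    g = (u >= c0).astype(np.int8)
    g += u >= c1
    return g


def sample_hwe_genotypes(q: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent dosages with P(0,1,2) = ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must lie in [0,1], got {q}")
    u = rng.random(n)
    return _hwe_from_uniform(u, np.float64(q))


def _hwe_matrix(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, len(freqs)) HWE dosage matrix with per-SNP frequencies ``freqs``.

    Uses single-precision uniforms: the induced rounding of the genotype
    cell probabilities is ~1e-7, immaterial next to sampling noise.
    """
    u = rng.random((n, len(freqs)), dtype=np.float32)
    c0 = ((1.0 - freqs) ** 2).astype(np.float32)
    c1 = (c0 + (2.0 * freqs * (1.0 - freqs)).astype(np.float32)).astype(np.float32)
    g = (u >= c0[None, :]).astype(np.int8)
    g += u >= c1[None, :]
    return g


def sample_case_control_genotypes(
    model: DiseaseModel, n_cases: int, n_controls: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disease-SNP dosages for ascertained cases and unaffected controls.

    Cases follow P(G|case) proportional to HWE(G) * f0*g**G; controls follow
    P(G|unaffected) proportional to HWE(G) * (1 - f0*g**G).
    """
    p_case, p_ctrl = genotype_distributions(model)
    u = rng.random(n_cases)
    cases = (u >= p_case[0]).astype(np.int8) + (u >= p_case[0] + p_case[1])
    u = rng.random(n_controls)
    controls = (u >= p_ctrl[0]).astype(np.int8) + (u >= p_ctrl[0] + p_ctrl[1])
    return cases, controls


# ---------------------------------------------------------------------------
# replicate assembly
# ---------------------------------------------------------------------------

def replicate_rng(base_seed: int, index: int) -> np.random.Generator:
    """Independent, individually reproducible RNG stream for one replicate."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(index),))
    )


def simulate_replicate(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> StudyData:
    """Generate one replicate of the study design.

    The null-panel source MAFs are uniform on ``config.maf_range``; every
    external cohort's frequency at every SNP is an independent
    Balding-Nichols draw.  The disease SNP is generated separately (model
    for cases/controls, plain HWE at the diverged frequency for external
    samples) and is never part of the null panel.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))

    n_cc = config.n_cases + config.n_controls
    sizes = config.external_cohort_sizes
    n_total = config.n_samples
    m = config.n_null_snps

    # null structure panel
    lo, hi = config.maf_range
    q0 = rng.uniform(lo, hi, m)
    blocks = [_hwe_matrix(q0, n_cc, rng)]
    for size, fst in zip(sizes, config.fst):
        qj = diverge_frequency(q0, fst, rng)
        blocks.append(_hwe_matrix(qj, size, rng))
    null = np.vstack(blocks)

    # disease SNP
    cases, controls = sample_case_control_genotypes(
        config.disease, config.n_cases, config.n_controls, rng
    )
    test_blocks = [cases, controls]
    q_dis = config.disease.risk_allele_freq
    for size, fst in zip(sizes, config.fst):
        qj = diverge_frequency(q_dis, fst, rng)
        test_blocks.append(sample_hwe_genotypes(qj, size, rng))
    test = np.concatenate(test_blocks)

    phenotype = np.zeros(n_total, dtype=np.int8)
    phenotype[: config.n_cases] = 1
    labels = (
        ["case"] * config.n_cases
        + ["control"] * config.n_controls
        + [f"external-{j + 1}" for j, size in enumerate(sizes) for _ in range(size)]
    )

    sample_ids = [f"s{i:05d}" for i in range(n_total)]
    snp_ids = [f"null{k:06d}" for k in range(m)]
    gm = GenotypeMatrix(null, sample_ids, snp_ids)
    return StudyData(gm, test, phenotype, np.array(labels))
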