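# Methods

## The problem

A case-control genome-wide association study can gain power at no genotyping
cost by expanding its control group with publicly available reference or
disease samples from other studies.  Those external samples, however, may not
be genetically matched to the study's source population.  When allele
frequencies differ between the source population and the external cohorts,
the naive cases-versus-expanded-controls trend test is anticonservative: the
false-positive error rate rises well above the nominal level at divergence
as small as F_ST = 0.002 and reaches several times the nominal level by
F_ST = 0.1.

`gwexpand` implements a correction built from genome-wide genotype data
alone: identity-by-state relationships, classical multidimensional scaling,
and forward selection of phenotype-associated axes of genetic variation,
which are then carried as covariates in a logistic trend test.

## The statistical procedure

**IBS.** For samples *i*, *j* genotyped at N_ij shared SNPs with dosages
G_ik in {0, 1, 2},

    IBS_ij = 1 − Σ_k |G_ik − G_jk| / (2 N_ij),

the genome-wide mean fraction of shared alleles, in [0, 1] with 1 meaning
identical genotypes.  SNPs missing in either sample are excluded from both
numerator and N_ij for that pair; a pair sharing zero genotyped SNPs is an
error, never silently imputed.  For real genotype panels the SNP set should
first be LD-thinned (`ld_thin`, greedy r² pruning) so that IBS reflects
genome-wide ancestry rather than a few long-LD regions.

**Axes of genetic variation.** Classical (Torgerson) MDS is applied to the
distance matrix D = 1 − IBS: B = −½·J·(D∘D)·J with J the centering
projector, eigendecomposed; axis *t* is the eigenvector of the t-th largest
eigenvalue scaled by √λ_t (principal-coordinate convention).  Axes with
non-positive eigenvalues are dropped.  Any monotone rescaling of an axis
leaves every downstream likelihood-ratio statistic unchanged, so the √λ
scaling is cosmetic but fixed for reproducibility.  Eigenvalue ties are
broken by the deterministic LAPACK output order (arbitrary under exact
ties).

**Forward selection.** With phenotype y_i (1 for cases, 0 for the expanded
control group), axes are tested in decreasing-eigenvalue order with a 1-df
likelihood-ratio test in logistic regression.  Selection is *conditional*:
the null model at step *t* contains the intercept and all previously
retained axes.  An axis is retained when P < 0.05 (configurable).  The
marginal variant — each axis tested against the intercept-only model — is
exposed via `select_axes(..., mode="marginal")` because the procedure is
sometimes read that way; at the default settings the two agree in nearly
every replicate, since MDS axes are mutually orthogonal.

**Trend tests.** Three 1-df likelihood-ratio trend tests of the additive
dosage term β_k:

* `T_CC` — cases vs within-study controls, unadjusted;
* `T_F` — cases vs controls + all external samples, unadjusted;
* `T_Fmds` — as `T_F` with the selected axes as covariates.

When no axis is selected, `T_Fmds` is the *identical* model to `T_F` — the
implementation copies the fit rather than refitting, making the equality
exact.  Dosage counts the minor allele of the combined sample.  Monomorphic
test SNPs give a degenerate result (P = 1, odds ratio undefined) rather
than an exception, so replicate loops never abort; degenerate counts are
reported.

**Logistic fitting.** Plain maximum likelihood by iteratively reweighted
least squares: convergence when the log-likelihood moves < 1e-10, cap 100
iterations.  Quasi-separation is flagged when any covariate moves the
log-odds by more than 15 per standard deviation of that covariate (the
per-SD scaling keeps the flag invariant to axis rescaling, which matters
because MDS scores naturally live on a ~0.01 scale).  Flagged axis fits are
never retained in selection; flagged trend fits are excluded from
odds-ratio summaries.  No penalized fallback is used — the estimator stays
the plain MLE.

## The simulation framework

The generator reproduces the study design the operating characteristics
were derived under, and its defaults are those conditions:

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 100 / 100 | source-population case-control sample |
| external_cohort_sizes | (100, 100, 100) | three external cohorts, unphenotyped |
| n_null_snps | 10,000 | unlinked structure-panel SNPs |
| maf_range | [0.05, 0.5] | uniform source MAF of null SNPs |
| fst | per cohort | Balding–Nichols divergence from the source |
| prevalence K | 0.001 | disease prevalence |
| het_grr γ | 1.0 (null) / 1.5 (power) | heterozygote genotype relative risk |
| risk_allele_freq q | 0.2 | disease-SNP frequency in the source |
| t_max_axes / alpha_select | 3 / 0.05 | forward-selection scope and threshold |

Null-panel genotypes are HWE draws at the source frequency (cases and
controls alike — the panel is unlinked to disease).  Each external cohort's
frequency at each SNP is an independent Beta(q(1−F)/F, (1−q)(1−F)/F) draw
(mean q, variance F·q(1−q)); F = 0 short-circuits to q exactly since the
Beta parameters are undefined there.  Draws arbitrarily close to 0 or 1
are kept — external cohorts may be near-monomorphic and downstream code
tolerates it.

At the disease SNP, case genotypes follow P(G|case) ∝ HWE(G)·f0·γ^G and
control genotypes P(G|unaffected) ∝ HWE(G)·(1−f0·γ^G), with f0 solved from
K = f0·[(1−q)² + 2q(1−q)γ + q²γ²]; configurations with f0·γ² > 1 are
rejected.  Controls are explicitly unaffected rather than population
samples (at K = 0.001 the difference is negligible but the ascertainment
is made explicit).  External samples are unselected for phenotype: their
disease-SNP genotypes are plain HWE at the cohort's diverged frequency.
The disease SNP is never part of the IBS panel — including the tested SNP
would contaminate its own correction.  The disease-SNP frequency used in
null (γ = 1) runs is 0.2, matching the power runs; it is configurable.

Replicate RNG streams derive from `SeedSequence(base_seed, spawn_key=(i,))`,
so replicates are independent, individually reproducible, and
order-insensitive.

**What the generator does not emulate:** linkage disequilibrium between
SNPs (the panel is unlinked by design), genotyping error and batch effects
between cohorts, admixture or continuous clines (divergence is a star
topology of discrete cohorts), pleiotropy between the case disease and the
diseases of external cohorts, and missing genotype calls.  Passing tests
therefore validate the statistical machinery under idealized structure;
real-data analyses additionally face LD (use `ld_thin`), platform
differences, and axis interpretability caveats (axes may capture extended
LD regions such as the MHC, or batch effects, rather than ancestry).

## Numerical choices

* Pairwise Manhattan sums for IBS are computed through a two-bit genotype
  encoding and one BLAS rank-k update in float32; all intermediate products
  are small integers, exactly representable, so the fast path is exact.
* MDS uses a partial symmetric eigensolver for the top t_max eigenpairs;
  positive-eigenvalue threshold 1e-9 relative to λ₁.
* LRT statistics are floored at 0; an alternative fit whose likelihood
  falls below its null by more than 1e-6 raises (optimizer-failure signal)
  rather than reporting a negative statistic.
* Empirical odds-ratio percentiles use linear (type-7) interpolation; the
  mean odds ratio is the arithmetic mean of exp(β̂) over non-flagged
  replicates.
* Degenerate replicates count as non-rejections and are tallied — never
  silently redrawn, which would bias null calibration.

## The analytic power calculator

`analytic_trend_power` computes the expected case/control genotype
distributions from (q, γ, K), forms the trend-test non-centrality
ncp = (μ_case − μ_ctrl)² / (σ²·(1/n₁ + 1/n₀)) with σ² the count-weighted
pooled dosage variance, and returns the upper tail of a noncentral χ²₁ past
the central (1−α) quantile.  It is validated against the package's own
simulator (agreement within two Monte-Carlo standard errors at matched
parameters) and reproduces the diminishing power returns of raising the
control:case ratio.  The exact mirror symmetry q→1−q, γ→1/γ holds at equal
group sizes; under unequal sizes the count-weighted pooling breaks it
slightly, which is a property of the standard construction, not an error.

## Problem sizes used in checks

Monte-Carlo reference values were established at 5,000 replicates per
condition.  The packaged acceptance runs use 1,000 replicates per condition
(`scripts/acceptance.py`, ~12 min single-threaded) and the test suite uses
300 (tolerance three binomial standard errors at the replicate count used,
which is the reproducibility the 5,000-replicate references support at
reduced counts).  The 100,000-SNP structure-panel comparison is run as a
paired directional check at 200 replicates: the 10k panel is the first
10,000 SNPs of each replicate's 100k panel, so the false-positive-rate
difference is differenced within replicates, removing most replicate-level
noise.

## Known limitations

* The IBS definition is mean allele sharing; weighted IBS variants
  (frequency-standardized) are not implemented.  The simulation-scale
  results are insensitive to this choice.
* No EIGENSTRAT-style per-SNP ancestry regression, genomic control,
  mixed models, outlier removal, or projection of new samples onto fixed
  axes.
* Real-data mode expects biallelic SNPs; multi-allelic and non-SNP VCF
  records are skipped (counted and logged), and no imputation is done.
* With very many axes and no selection, power would degrade; the selection
  procedure exists precisely so that large axis pools can be screened
  safely (fewer than ~10% of replicates use any axis beyond the third even
  when ten are screened).
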