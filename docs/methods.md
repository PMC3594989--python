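# Methods

This note records the models implemented in `gxetools`, the numerical
choices behind them, what the simulator does and does not emulate, and
the design decisions taken where several reasonable options existed.

## The two-way table and the fixed-effects model sequence

All analyses start from a genotype × environment table of adjusted
means μ_ij (I genotypes, J environments), the product of a first-stage
per-trial analysis that is out of scope here. Optional per-cell weights
are carried by the data model but default to 1 (unweighted second
stage); deriving weights from plot data is likewise out of scope.

Effects are parameterized sum-to-zero throughout, so G_i and E_j are
deviations from the grand mean and the Finlay–Wilkinson slopes satisfy
mean(b′_i) = 1 on balanced data. The model sequence and its exact
degrees-of-freedom accounting:

| model | interaction term | DF |
|---|---|---|
| additive | — (residual (I−1)(J−1)) | E: J−1, G: I−1 |
| Finlay–Wilkinson | b_i·Ê_j | slopes: I−1, residual (I−1)(J−2) |
| AMMI (K axes) | Σ b_ik z_jk | axis k: I+J−1−2k (Gollob), residual by difference |
| GGE (K axes) | Σ b_ik z_jk absorbing G | axis k: I+J−1−2k |
| factorial regression | Σ b_ik Z_jk | I−1 per covariate, residual (I−1)(J−1−K) |

Ê_j is the environment mean deviation; b′_i comes from the closed-form
per-genotype regression on Ê (balanced tables only; unbalanced input
must be imputed first — see below). AMMI is the SVD of the
double-centered table, GGE of the environment-centered table; per-axis
sums of squares equal squared singular values, and the SVD sign
ambiguity is fixed by making each axis's largest-|loading|
environmental score positive, so exports are round-trip stable.

Every F statistic in an ANOVA table is the term's mean square over
*that table's own* residual mean square. Published versions of these
tables sometimes reuse one model's residual across several tables;
testing against the fitted model's residual is the internally
consistent choice and is what the package does.

Axis testing uses Gollob degrees of freedom with F against the
residual; permutation-based axis tests are not implemented. Biplot
coordinates scale the singular values with exponent γ (default ½,
symmetric); the inner product of genotype and environment points
reproduces the rank-2 reconstruction by construction.

Missing cells: models needing a complete matrix refuse to run and point
to `impute_low_rank`, an EM-style scheme (additive fit → fill → rank-K
SVD reconstruction → iterate to 1e-8 relative change, default K = 2).
Imputation is a convenience, not an inference method: SEs downstream do
not account for it.

## REML mixed models

With genotypes random, the J observations of a genotype form a vector
y_i ~ N(μ + E, Σ) and GEI appears as structure in Σ:

- `cs` (compound symmetry): Σ = σ²_G·11′ + σ²_ε·I — one genetic and one
  residual variance, constant correlation σ²_G/(σ²_G+σ²_ε);
- `cs_het`: Σ = σ²_G·11′ + diag(σ²_εj) — constant covariance,
  heterogeneous variances and hence correlations;
- `grouped`: environments partitioned into groups with an unstructured
  group-level genetic covariance Σ_c expanded to J × J, plus
  diag(σ²_εj). A singleton group's variance is confounded with its
  residual and is pinned (default 1.0) rather than estimated;
- `unstructured`: free Σ.

For a balanced table the restricted deviance profile is, up to a
data-independent constant,

    dev(Σ) = (I−1)·log det Σ + tr(Σ⁻¹ W),   W = Σ_i (y_i − ȳ)(y_i − ȳ)′.

Only deviance *differences* between fits on the same data are
meaningful; the reported deviance omits the constant, so absolute
values are not comparable across software. The unstructured optimum is
the closed form W/(I−1); the other structures are fitted by L-BFGS-B
over an unconstrained parameterization (log variances; for the grouped
structure a Cholesky factor of Σ_c whose pinned rows are rescaled to
hit the pinned diagonal, which keeps every iterate positive
semi-definite). Starting values are moment estimators; gradient
tolerance 1e-8, at most 200 iterations. Variances are floored at 1e-10
and flagged as boundary estimates; deviance tests against a boundary
null are conservative and warn accordingly.

Standard errors come from the observed information: a central-difference
Hessian of the deviance on the natural (variance/covariance) scale,
with covariance 2·H⁻¹. For the unstructured model the Wishart
asymptotics var(s_ab) = (s_aa·s_bb + s²_ab)/(I−1) are used directly.
Variance-parameter counting for AIC (= deviance + 2·n_params) includes
only estimated parameters: 2, 1+J, (free Σ_c entries)+J, J(J+1)/2.

Fixed-effect (environment) testing is a Wald quadratic form of J−1
contrasts of the environment means against Σ̂/I, referred to χ²_{J−1};
no F-type small-sample approximation is offered. Deviance tests require
the structures to nest (cs ⊂ cs_het ⊂ grouped ⊂ unstructured) and use
χ² with DF equal to the parameter-count difference.

## Genetic predictors

A hidden Markov model per chromosome: hidden states are the genotype at
a locus indexed by the number of paternal (M₁) alleles, transitions come
from the recombination fraction between adjacent loci, and emissions
are indicators of compatibility with the observed code (A/H/B point
mass; C = not-A and D = not-B put mass on the compatible pair; missing
is uninformative). Population types: F2 uses the 3-state transition
built as the tensor product of two independent meioses; backcross (to
the maternal parent, so paternal homozygotes are impossible) and
doubled haploids are 2-state chains in r; RILs by selfing are 2-state
chains in the fixed-line recombination R = 2r/(1+2r), ignoring residual
heterozygosity. Initial distributions are the Mendelian expectations
(¼, ½, ¼ for F2; ½, ½ otherwise).

The default map function is Haldane, r = (1 − e^{−2d/100})/2, which is
the one consistent with the no-interference Markov assumption of both
the HMM and the simulator; Kosambi is offered but is approximate inside
an HMM. Forward–backward runs scaled (normalized per locus), which is
stable for hundreds of loci; posteriors at off-marker positions combine
the filtered forward state at the left flanking marker and the backward
likelihood at the right one through the two partial transitions, and the
implementation agrees with brute-force enumeration to 1e-10 on small
chromosomes for all four population types. Positions are interpreted on
the map's own cM scale with no re-anchoring. The evaluation grid places
points every `step` cM per chromosome and by default merges the marker
positions themselves (deduplicated within 1e-6 cM); predictors at
observed codominant markers are then exact allele counts.

Predictors follow the linear maps X_add = 2·P(M₁M₁) + P(M₁m₁) ∈ [0,2]
and X_dom = P(M₁m₁) ∈ [0,1] (identically 0 for DH/RIL).

## QTL mapping pipeline

Step 1 selects a variance structure for the no-QTL model (deviance/AIC).
During the scans both the structure *and its estimated parameters* are
held fixed at that fit — the standard two-stage approximation. This
matters: a deliberately misspecified scan covariance (e.g. compound
symmetry on strongly heterogeneous data) badly inflates the Wald tests,
which is exactly why structure selection precedes scanning.

With Σ fixed, every Wald statistic is computed as the difference of
generalized-least-squares objective minima between nested fixed models.
This formulation makes sequential tests exactly additive and
non-negative: the environment-specific additive test has J DF,
dominance is tested sequentially after the additive term (J DF), and
the main-effect/QEI partition tests α^Q first (1 DF) and α^QEI_j
conditional on it (J−1 DF), with α_j = α^Q + α^QEI_j holding exactly
for the reported estimates. When the regressor matrix is shared across
environments (all env-specific terms), the GLS normal equations have
Kronecker form and the estimates reduce to per-environment OLS, which
keeps a genome scan at a few hundred positions essentially instant.

Simple interval mapping (SIM) is the cofactor-free special case of
composite interval mapping (CIM) — literally the same code path, so the
two agree bit-for-bit with an empty cofactor list. Restricted CIM
(default) excludes all cofactors on the chromosome being tested; a
window rule (exclude within w cM) is available since window size has no
canonical recommendation. Cofactors come from the SIM profile: local
maxima of −log₁₀P above the threshold, kept greedily best-first with a
default 30 cM minimum separation within a chromosome. Monomorphic or
collinear positions are skipped and recorded in the result, never
silently dropped.

Multiple testing: Bonferroni (α/n over tested positions) or the Li–Ji
effective number of tests, n* = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] over
the eigenvalues of the correlation matrix of the tested predictor
columns, with cutoff α/n*. In null simulations at the default study
scale the per-test P values are uniform and Bonferroni controls the
genome-wide error with room to spare, while Li–Ji is mildly
anti-conservative (empirical genome-wide rate ≈ 0.065 at nominal 0.05
with the unstructured step-1 model) — a known property of
eigenvalue-based effective-test counts under the smooth, strong local
correlation of an HMM predictor grid.

The final multi-QTL model enters all CIM candidates with
environment-specific effects and removes the least significant QTL
(conditional Wald given all others) while its P exceeds `drop_alpha`
(default 0.05), refitting each round and always retaining at least one
QTL. Per-cell significance uses the ±2·SE confidence rule. Dominance is
scanned only on request, mirroring the practice of dropping it
genome-wide when a preliminary scan shows none.

The covariate model for one QTL re-expresses its effect as
α_j = α* + β·Z_j + a_j with a_j ~ N(0, σ²_a), giving each genotype the
covariance Σ + σ²_a·x_i²·I. σ²_a is profiled by bounded scalar REML
(including the log-det information adjustment) with the other variance
parameters fixed; the covariate should be centered so α* is the effect
in the average environment (an uncentered covariate only shifts α*, and
the code warns rather than recentering silently).

## The simulator

`simulate_cross` draws genotypes as a Markov chain along each
chromosome using the same transition matrices as the HMM (Haldane, no
crossover interference) — F2 as two independent meioses, DH as a
doubled gamete, RIL as a fixed-line chain in R. `degrade_markers`
independently turns scores missing or collapses them to dominant codes
where compatible. `simulate_phenotypes` builds
μ + E_j + Σ_q X_add·α_jq + Σ_q X_dom·δ_jq + G_i + ε_ij with
G_i ~ N(0, σ²_G) and residual vectors from a scalar, diagonal or full
residual covariance; QTL effects are given per environment or as a
linear law α + β·Z_j, which makes crossover patterns one line of code.
A single master seed spawns independent sub-streams for cross,
degradation and phenotypes (NumPy `SeedSequence`), so each stage is
reproducible in isolation and across platforms.

Default magnitudes are chosen to match the published scale of maize
stress trials: genetic variance ~0.1–0.3, residual variances ~0.14–1.4
(ton·ha⁻¹)², allele-substitution effects ~0.1–0.5 ton·ha⁻¹ on 8
environments. The `maize_stress_spec` preset (211 F2 individuals, 10
chromosomes, 132 markers, 8 environments, one crossover QTL, one
constant QTL) reproduces the *shape* of such an experiment for
demonstrations and calibration runs; it is synthetic and is never a
reconstruction of any real data set. What the simulator does not
emulate: field/spatial effects and first-stage adjustment, segregation
distortion, genotyping error in the emissions, selection, epistasis,
and crossover interference. Passing tests therefore certify the
statistical machinery under the stated generating model, not robustness
to those features of real data.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to make Monte-Carlo noise
small relative to the tolerances while keeping the default suite quick:
parameter recovery at I = 500 over 50 seeds per structure (±3 SE,
≥ 90% of individual parameter recoveries — the joint all-parameter
event is not a calibrated 90% criterion for the 36-parameter
unstructured model); null scan calibration over 200 runs at the
211 × 8, 10-chromosome study scale with a 10 cM grid; power and
localization of a 0.4-SD QTL over 100 seeds at n = 200 with a 5 cM
grid; crossover-QEI detection over 50 seeds.

## Known limitations

- REML assumes a balanced (complete) table; unbalanced data must be
  imputed or reduced first, and the alternating-regression extension of
  Finlay–Wilkinson to unbalanced tables is not implemented.
- Wald tests treat Σ̂ as known; at small I they are slightly liberal.
- No factor-analytic covariance, no plot-level single-stage models, no
  pedigree/kinship random effects, no multi-parent or association
  populations, no epistasis, no mixture-model interval mapping.
- Li–Ji thresholds approximately — not exactly — control the
  genome-wide error (see above); Bonferroni is the conservative option.
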