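# Methods

This note documents the models implemented in `popassoc`, the numerical
choices behind them, what the simulators do and do not emulate, and known
limitations.  Notation: n individuals, m biallelic loci, genotypes
x_ij ∈ {0, 1, 2} counting a reference allele; kinship φ_jk and coancestry
θ_jk are probabilities of identity by descent relative to an ancestral
population T, with self-kinship (1 + f_j)/2 for inbreeding f_j and
θ_jj = f_j.

## Admixture simulator

Subpopulation S_u (u = 1..K) sits at coordinate u and carries total
inbreeding f_u = u·τ, so differentiation increases linearly along the
geography.  Individual j at coordinate c_j (evenly spread over
[0.5, K + 0.5]) has admixture proportions

    q_ju ∝ exp(−(c_j − u)² / (2σ²)),   normalized per individual.

The Gaussian kernel realizes the "random walk with spread σ" idea; since a
random-walk construction does not pin down a unique kernel, the
Gaussian-density form — the construction used by the established
admixture-simulation packages in this area — was adopted and is treated as
part of the model definition.  σ = 0 is reserved for hard
assignment to the nearest subpopulation.

Coancestry induced by independent intermediate subpopulations is
θ_jk = Σ_u q_ju q_ku f_u.  The generalized F_ST is the uniform-weight mean
of the diagonal.  Two calibration targets define the model: F_ST itself
(default 0.1) and the ratio of mean off-diagonal coancestry to F_ST
(default 0.5).  Because f_u is linear in τ, the ratio is τ-free, and it is
monotone increasing in σ (checked as a test property); σ is therefore
found by Brent root-bracketing on log σ (xtol 1e−12, so refits are
bit-reproducible) and τ then scales F_ST in closed form.  Fits that would
need f_K > 1 or an unattainable ratio raise an error reporting the
attainable range.

Genotypes: p_i^T ~ Uniform(0.01, 0.5) by default (the sampler is
pluggable); subpopulation frequencies are Balding–Nichols draws, i.e. Beta
with mean p and variance p(1−p)f, with the continuous limits handled
exactly (f = 0 returns p; f = 1 is a Bernoulli(p) point mass on {0, 1});
π = p_S Qᵀ; x ~ Binomial(2, π).  Loci fixed across all individuals are
redrawn wholesale from p_i^T onward (cap 1000 rounds).  Note that this
exclusion truncates the genotype distribution and visibly distorts moments
only at very small n; moment-recovery tests therefore use n ≥ 30.

## Pedigree simulator

Founders are the admixture model's individuals ordered by coordinate,
locally unrelated and outbred.  Each next generation: random sex
assignment; males drawn in random order and paired with the nearest
available female (ties: lowest index) whose *local* (pedigree) kinship is
below the cutoff, in a single pass; children per family
n_min + Poisson(n/n_f − n_min), rebalanced by incrementing/decrementing
random (eligible) families until the generation has exactly n children;
children sorted by mean parental coordinate, which preserves the admixture
gradient.  The pairing cutoff defaults to 1/4³ = 0.015625, excluding
second cousins and closer.

Local kinship is maintained by the classical recursion
φ(c, x) = ½[φ(father, x) + φ(mother, x)],
φ(c, c) = ½[1 + φ(father, mother)], seeded with ½I; seeding instead with a
founder coancestry matrix yields total kinship combining ancestry and
pedigree (verified against a 10⁵-replicate allele-dropping oracle).

A scale constraint worth knowing: mean local kinship grows roughly like
g/(4n) over g generations, so populations with n below ≈500 collapse (no
eligible pairs remain) before 20 generations under the default cutoff.
Tests and examples therefore use n = 500 for the full 20-generation
setting, or fewer generations at smaller n.

Genotype dropping transmits one allele per parent per locus
(Bernoulli(dosage/2) thinning), independently across loci — no linkage.
Drift through the pedigree can fix loci that were polymorphic in the
founders; `filter_loci` removes them before estimation, as the kinship
estimators require polymorphic input.

## Subpopulation trees

Each non-root node w has edge inbreeding f_w^{edge}; the additive edge is
δ_w = f_w^{edge}(1 − f^T_{parent}) and f^T_w = f^T_{parent} + δ_w, so
coancestry between leaves u, v is Σ_w δ_w I_w(u,v) over common ancestors —
monotone in MRCA depth.  Simulation evolves frequencies down the tree by
per-edge Balding–Nichols draws; loci with sample MAF below a floor
(default 0.01) are redrawn from the root distribution.

Fitting inverts this in two steps.  Topology: WPGMA hierarchical
clustering on d(u,v) = max(ϑ̂) − ϑ̂_uv, written in-package (≈30 lines)
rather than delegated so that ties merge the lexicographically smallest
cluster pair and fits are deterministic; on exact tree-generated input the
true topology is recovered.  Edge lengths: non-negative least squares
(scipy) on the common-ancestor indicator design over all unordered leaf
pairs including u = v, plus an all-ones intercept column δ₀ that absorbs
small estimation biases.  δ₀ is constrained non-negative like every other
coefficient (it is conceptually an extra shared edge above the root); it
participates when converting δ back to edge inbreeding but is ignored when
simulating from the fitted tree.  Subpopulation-level coancestry estimates
average individual coancestry over blocks, including the diagonal self
terms (on the coancestry scale, where the diagonal is f̂_j = 2φ̂_jj − 1).

## Kinship estimators

*Standard*: Φ̂ = X_Sᵀ X_S/m with x standardized per locus by the estimated
frequency; rows sum to exactly zero because standardized genotypes are
centered — the estimator measures relatedness against the sample mean, not
T, which is its well-known bias (about −0.05 on the default admixture
model, reproduced as a test).

*Bias-corrected*: A_jk = mean_i (x_ij − 1)(x_ik − 1) − 1 estimates
4v̄(φ_jk − 1) with v̄ the mean allele variance, so Φ̂ = 1 − A/A_min is
unbiased once A_min estimates the same quantity for unrelated pairs.
A_min defaults to the mean A over the bottom 1% of off-diagonal values,
then is refined (3 rounds) by re-averaging over all pairs whose current
kinship estimate is below 0.01 — the refinement removes the noise-selection
bias a pure bottom-quantile anchor has in weakly structured samples.  With
subpopulation labels, A_min is the minimum between-label block mean
instead.  The estimator is validated by truth recovery (mean bias within
±0.005 and RMSE < 0.02 on the admixture model at m = 50,000), not by a
closed-form identity, and — like any most-unrelated-pair calibration — it
measures relatedness relative to the least-related pairs present: if even
those pairs share ancestry, that share is absorbed into the reference.

*KING-robust local kinship*:
φ̂ = (N_het,het − 2 N_opposite-hom) / (N_het(j) + N_het(k)) over loci
complete for the pair; invariant to allele relabeling; negative between
members of differentiated subpopulations by design; NaN with a warning for
pairs without heterozygous loci.  Relative filtering greedily removes the
individual in the most pairs at or above the cutoff (default
2^(−11/2) ≈ 0.02209709, the conventional 4th-degree threshold), ties to
the lowest index, until no pair remains.

## Trait simulation

Variance is partitioned as h² (genetic) + Σ_i σ_ηi² (environment groups) +
σ_ε², with σ_ε² = 1 − h² − Σσ_ηi² required non-negative.  The default
causal-set size is m₁ = round(n h²/8) (banker's rounding, minimum 1),
drawn uniformly from loci with sample MAF ≥ 0.01.  FES initial
coefficients are proportional to 1/√(2v_i) with fair random signs (any
positive constant is equivalent after rescaling); RC draws β ~ N(0, 1).
Both are rescaled by h/σ₀ with σ₀² = Σ 2v_i β_i², making the genetic
variance exactly h² for known ancestral frequencies.  The intercept is
α = −Σ 2p_i β_i (known p) or the product-of-sums form
−(2/m₁)(Σp̂_i)(Σβ_i) with v̂_i = p̂_i(1−p̂_i)/(1−φ̄) when frequencies are
estimated, where φ̄ is the mean bias-corrected kinship over all n² pairs;
the estimated-frequency path is all-or-nothing per run.  Environment
coefficients are drawn fresh per replicate and not re-standardized, so
realized environment variance fluctuates.

Calibration caveat (tested): conditioning the causal draw on realized
sample MAF selects loci whose genotype variance exceeds its ancestral
expectation, inflating realized heritability by roughly 4–7% (more under
FES, whose weights concentrate on rare loci).  With the floor disabled the
calibration is exact to Monte-Carlo error.

## Association models

*PCA*: per-locus OLS of y on [1, x_i, U_r, Z] via one QR residualization
of y and all loci on the covariates (Frisch–Waugh–Lovell), then a
two-sided t-test with n − (r + #covariates + 2) degrees of freedom.  PCs
default to the top eigenvectors of the standard kinship estimate computed
after a MAF ≥ 0.1 locus filter (the convention of the standard PCA
association tooling); estimated PCs are orthogonal to the ones vector
because standardized genotypes are centered.  Eigenvector signs are fixed
deterministically (largest-magnitude entry positive).  Loci collinear with
the covariates yield NaN with a warning; a rank-deficient covariate design
is an error.

*LMM*: null model y ~ N(Xb, 2σ_s²Φ + σ_ε²I) fitted by REML once per trait
(never per locus).  After rotating by the eigenvectors of 2Φ (tiny
negative eigenvalues from estimated matrices clipped to 0), the restricted
likelihood is profiled to a scalar function of the variance ratio
γ = σ_s²/σ_ε², optimized by bounded Brent search on log γ over [−30, 30]
(xatol 1e−8) with the γ = 0 boundary evaluated explicitly.  Each locus is
then scored with (xᵀPy)²/(xᵀPx) against χ²₁, where P projects out the
fixed effects under the null covariance; the whole locus sweep is a few
matrix products in the rotated basis, and an `LmmWorkspace` amortizes the
eigendecomposition and genotype rotation across a sweep over r.  The LMM
kinship defaults to the standard estimator on the analysis loci (parity
with standard mixed-model association tools); the bias-corrected estimator
is accepted as an option.  No genomic-control rescaling is ever applied.

An identifiability fact that shapes the tests: under the pure admixture
model, Φ ≈ 0.5I + (rank-K smooth term), so V = σ_ε²I + σ_s²(2Φ) separates
the two components only through ~K informative directions.  Per-replicate
REML estimates of the split are then extremely noisy and boundary-censored
— demonstrably so even on exactly Gaussian draws (a dense-likelihood grid
reproduces the same argmax) — although the score test, which depends on V
as a whole, remains calibrated.  Heritability-recovery properties are
therefore asserted on family-structured kinship (sibship blocks, admixed
pedigrees), where the eigenvalue spectrum is rich and the split is
identified; recovery there is within 0.8 ± 0.05.

## Evaluation metrics

SRMSD_p compares sorted null p-values to the uniform quantiles
(i − ½)/m₀, signed by sgn(½ − median p) with sgn(0) := +1; its range is
±1/√3 ≈ ±0.577 (attained by all-zero / all-one p-values); |SRMSD_p| < 0.01
is used as the calibration rule throughout.  AUC_PR integrates the
precision-recall curve with the Davis–Goadrich interpolation — linear in
(TP, FP) counts between operating points, hence the correct nonlinear path
in precision — with tied scores entering together and the curve anchored
at (TP, FP) = (0, 0); each segment has a closed-form integral (the
implementation is checked against fine-step numerical integration and a
frozen 6-point hand example).  A perfect ranking scores 1; a random one
scores m₁/m in expectation.  The genomic inflation factor
λ = median(χ²(p))/0.4549 is provided as an auxiliary diagnostic and is
co-monotone with SRMSD_p on one-parameter families p = u^a.

## Experiment driver

`run_replicates` draws fresh genotypes and traits per replicate (seeds
`seed + replicate_index`), runs both models over the r grid, and records
SRMSD_p (null loci only), AUC_PR (scores −log₁₀ p), and λ; failures are
recorded as missing rather than aborting.  `compare_models` picks the best
r per method by mean metric, flags calibration, and compares PCA at its
best r against the LMM at r = 0 with a paired one-tailed Wilcoxon
signed-rank test (exact when ≤ 25 pairs with no zero differences, normal
approximation otherwise), declaring a tie unless p < α/n_tests.

Default problem sizes are chosen so the full study runs in minutes on one
CPU: n = 500, m = 20,000, 10 replicates, r ∈ {0..5} for the calibration
study; these preserve the qualitative regimes of the full-scale design
(n = 1000, m = 100,000, 50 replicates, r to 90), namely: (a) admixture
only — both models calibrate, PCA needing a few PCs; (b) small n — AUC_PR
collapses for both models as r approaches n (the overfitting regime shows
in power rather than in the t-test's p-values, which remain df-protected);
(c) admixed families — PCA is anti-conservative at every r while the LMM
without PCs stays calibrated and classifies better.

One scale-sensitive quantity deserves note: the smallest r at which PCA
attains mean |SRMSD_p| < 0.01 on the admixture model.  The residual
confounding at r = 2 sits near the 0.01 threshold; in this implementation
it falls just below it (≈0.004 at n = 500 and ≈0.005 at n = 1000,
m = 100,000), so the smallest calibrated r evaluates to 2 rather than 3.
The threshold is absolute while the confounding magnitude depends on the
exact admixture-proportion construction, so this integer is not a robust
invariant of the design.

## Known limitations

- Loci are unlinked by construction; no LD, recombination maps, or
  LD-aware causal placement.
- Quantitative traits only; no case-control/liability models, dominance,
  or epistasis.
- 1D geography only; no admixture edges/reticulation in trees; no
  migration or overlapping generations in pedigrees.
- The bias-corrected kinship estimator's reference is the sample's
  most-unrelated pairs; true coancestry shared by *all* pairs is not
  recoverable from genotypes alone.
- Simulated data contain no missing genotypes; the I/O layer and KING
  estimator handle missingness (pairwise-complete), but the standardized
  moment estimators simply drop incomplete loci.
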