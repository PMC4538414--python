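# Methods

## The problem

Narrow-sense heritability h² is the share of phenotypic variance
attributable to additive genetic variance.  Two parameterizations of the
phenotypic covariance make it estimable:

* **Family-based**: the covariance between relatives j and j′ is
  σ_a²·2φ(j,j′), twice the pedigree kinship coefficient.  The matrix of
  these expected relationships is the familial relationship matrix (FRM).
* **Population-based**: pairwise relatedness is estimated from genome-wide
  SNPs as the genetic relationship matrix (GRM), and the same linear mixed
  model y = Xβ + ε, ε ~ MVN(0, σ_a²K + σ²I) is fitted with K the GRM.

The package implements both, plus the two diagnostics that explain why the
two roads give different answers on real cohorts: (i) shared-environment
variance components (sibship, marital, and the MZ/DZ twin bound ρ_c), and
(ii) a simulation study of the GRM estimator's bias and variance as a
function of the genotypic correlation r between sampled pair members.

## Model fitting

All variance-component models are fitted by restricted maximum likelihood
with average-information (AI) updates: one EM-style first step, then Newton
steps using the AI matrix ½·y′PK_iPK_jPy as the curvature estimate, with
step-halving whenever a proposal fails to increase the restricted
likelihood and projection of non-negative components onto a small positive
floor (10⁻⁶ of the phenotypic variance; a parameter resting there at
convergence is flagged as a boundary estimate).  Convergence requires
|Δ log L| < 10⁻⁸ and max |Δθ|/(|θ|+1) < 10⁻⁶ within 200 iterations;
non-convergence is reported in the fit object, never silently.  Full ML is
available through the same driver (`method="ML"`); REML is the default
because it corrects the fixed-effect degrees of freedom.

Three interchangeable linear-algebra backends produce identical quantities
(they are cross-checked to machine precision in the test suite):

* **dense** — generic O(n³) per iteration; used for small problems and as
  the reference implementation;
* **eigen** — for one non-identity component plus the identity (the GRM
  case): a single eigendecomposition of K turns every iteration into
  O(n·p²) diagonal algebra;
* **blocked** — when all components share a block-diagonal partition
  (families, twin pairs), blocks are grouped by size and processed with
  batched dense kernels, making cost linear in the number of families.
  This is what makes 2,000-family and 600-twin-pair fits take well under a
  second.

Starting values split the ordinary-least-squares residual variance equally
across components.  Standard errors are square roots of the diagonal of the
inverse AI matrix; heritability σ_a²/Σσ_k² carries a delta-method standard
error through the same inverse.

## The twin model

MZ and DZ twin pairs give the covariance σ_Y²·V with V = I + r_MZ·A +
r_DZ·B, where A and B are MZ/DZ co-twin indicators.  Under an
additive/common-environment/dominance decomposition, r_MZ =
(σ_c²+σ_a²+σ_d²)/σ_Y² and r_DZ = (σ_c²+0.5σ_a²+0.25σ_d²)/σ_Y², so

    ρ_c = 2·r_DZ − r_MZ = (σ_c² − 0.5σ_d²)/σ_Y²,

which equals the common-environment share when σ_d² = 0 and is a lower
bound for it otherwise (epistasis ignored).  The three parameters are not
separable into σ_a², σ_c², σ_d² individually in this design, and no such
decomposition is attempted.

Optimization runs on (log σ_Y², atanh r_MZ, atanh r_DZ), which keeps the
correlations inside (−1, 1) without ad-hoc clipping; the gradient and AI
matrix are chain-ruled from the linear-coefficient parameterization
(σ_Y², σ_Y²r_MZ, σ_Y²r_DZ).  No lower bound beyond −1 is imposed on the
correlations.  A transformed correlation that hits the cap |r| = 1−10⁻⁶ is
reported as a boundary fit (this happens when co-twin values are exactly
duplicated).  If a design has no DZ (or MZ) pairs the corresponding
parameter is dropped and listed in `TwinFit.dropped`; singletons are
permitted and contribute only through σ_Y².

The Fisher information Ψ over (σ², r_MZ, r_DZ) is evaluated on the natural
scale at the optimum from the trace identities

    Ψ = [ (n−p)/2σ⁴        tr(PA)/2σ²     tr(PB)/2σ²
          ·                tr(PAPA)/2     tr(PAPB)/2
          ·                ·              tr(PBPB)/2 ],

with P the REML projection built from V.  The variance of ρ_c is
(0,−1,2)·Ψ⁻¹·(0,−1,2)ᵗ and the 95% interval uses the normal multiplier
1.96.  The test suite verifies Ψ against minus the finite-difference
Hessian of the *expected* restricted log-likelihood
E[ℓ_R(θ)] = −½[log|Σ(θ)| + log|X′Σ(θ)⁻¹X| + tr(P(θ)Σ(θ₀))], whose curvature
at θ₀ is exactly the Fisher information; the observed-data Hessian differs
from it by O_p(n^(−1/2)) sampling terms and is not a valid high-precision
oracle.

## Quality control and relationship matrices

SNP filters: Hardy-Weinberg exact test p < 10⁻⁵, call rate < 95%, MAF <
1%; sample filters: call rate < 95%, heterozygosity > 30%.  The HWE test is
the exact conditional-on-allele-counts test with the two-sided
"sum of probabilities ≤ observed" rule — the GWAS-QC standard — verified
exhaustively against a brute-force enumeration for all tables with up to 50
alleles.  A SNP failing several rules is attributed to the first failing
rule in the fixed order HWE, call rate, MAF, so reports are deterministic.
MAF and heterozygosity use non-missing calls only.

GRM: entry (j,k) averages (x_j−2p)(x_k−2p)/2p(1−p) over jointly observed
SNPs, with allele frequencies estimated from **all** individuals (related
ones included).  Two diagonal dialects are carried — "simple" (same formula
with j = k) and "gcta" (1 + [x²−(1+2p)x+2p²]/2p(1−p)) — because the GREML
literature uses the latter while the former makes the duplicate-row
identity exact; tests pin the simple dialect, and the choice is a
documented option.  Monomorphic SNPs must be removed upstream (frequency 0
or 1 raises an error naming the SNP).

FRM: twice the kinship coefficient from the standard parents-first
recursion, exact for inbred pedigrees (diagonal 1 + inbreeding
coefficient), block-diagonal by family and stored sparsely for large
pedigrees.  MZ co-twins cannot be represented in a kinship matrix as
distinct individuals, so FRM/GRM analyses keep one randomly selected
member per MZ pair (seeded selection).

Relatedness cutoff: individuals are greedily removed — highest count of
above-cutoff partners first, ties broken by lower call rate then by later
sample order — until no retained pair exceeds the cutoff (default 0.025).
Greedy maximum-degree removal is not guaranteed to be the maximum retained
set, but it is deterministic and satisfies its postcondition by
construction, which the tests verify.

## Familial correlations

Traits are residualized on age, age², sex by OLS; correlations are computed
per pair type: mother–father and parent–offspring as interclass Pearson
correlations over pairs, sibling as the intraclass convention including
both orderings of each pair.  Each pair has equal weight by default; a
family-weighting option divides a pair's weight by the number of pairs its
family contributes.  Intervals are Fisher-z with the number of distinct
pairs as effective sample size — an approximation that ignores the sharing
of individuals across pairs, acceptable for the diagnostic use these
tables serve.  A pair type with fewer than three pairs is reported as
unavailable rather than raising.

## Synthetic data: what it emulates and what it does not

**Related genotype pairs.**  Biallelic SNPs in Hardy-Weinberg and linkage
equilibrium; within a pair, each allele slot of the second member is an
identical-by-descent copy of the first member's matching slot with
probability r, independently.  This gives genotype correlation exactly r
and kinship r/2 (r = 1/2 emulates full sibs or parent-offspring).  The
per-slot copy probability is deliberately r, not r/2: copying with r/2
would halve the genotype correlation and contradict the construction's
target.  Monomorphic realizations are dropped after genotype generation
(they carry no relationship information) and the dropped ids logged.
Non-causal SNPs are redrawn per replicate; a fixed-panel variant only needs
passing the same frequency vector.

**Causal architecture.**  n_causal = 100 SNPs by default, each assigned an
equal share of the genetic variance: β_l = sqrt(h²σ²/(2·n_causal·
p_l(1−p_l)·(1−h²))), so Σ 2β_l²p_l(1−p_l) = h²σ²/(1−h²) holds to 10⁻¹⁰
(validated on construction).  Effects are positive by default — the sign is
irrelevant under independent HWE genotypes — with an optional
sign-randomization flag.  Causal frequencies come from U(0,0.1) (rare) or
U(0.1,0.4) (common) laws; non-causal from U(0,0.4).

**Twin and family cohorts** are phenotype-only draws from the implied
multivariate normal (the twin model is phenotype-only; explicit genotypes
would add nothing).  Note that in the nuclear-family design the marginal
variance differs by member class — parents carry the marital variance,
sibs the sibship variance — so pair correlations must be normalized by the
class-specific variances, which the tests do.

Not emulated: linkage disequilibrium, ascertainment/case enrichment,
genotyping error, imputation, X-chromosome dosages, population
substructure, assortative mating, generation-varying polygenic variance.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative models, not robustness to these real-data features.

## The relatedness sweep

For each grid cell (r, h², causal coverage, causal MAF law) the sweep
simulates pairs, generates traits, builds the GRM from all genotyped SNPs —
no relatedness cutoff, matching how the experiment isolates the effect of
r — fits REML, and records the heritability estimate.  The reference line
is the variance share actually tagged by the genotyped SNPs:
coverage·h²σ²/(1−h²) / (h²σ²/(1−h²)+σ²), i.e. h² at full coverage and
h²·coverage·(scaled) below it otherwise.  When only half the causal SNPs
are genotyped, the untagged half is recovered through relatedness, so the
estimate rises above the reference line in proportion to r; at full
coverage the estimate is centered on h² for every r, while its spread
shrinks as r grows.

Default scale is 500 pairs × 5,000 SNPs × 20 replicates per cell, which
keeps a full two-coverage, four-r sweep in the low minutes on one core
while leaving the mean estimates within ±0.05 of their targets;
`SweepGrid.paper_scale()` (or `paper_scale: true` in the YAML config)
restores 5,000 pairs × 100,000 SNPs and the full r grid 1/2 … 1/128, 0.
Replicate seeds derive from SeedSequence(master, cell index, replicate), so
any cell is reproducible in isolation and the whole sweep bit-identically.
Estimates are not clipped post hoc; the optimizer's boundary handling
governs and boundary hits are flagged.  The interquartile-range ordering
across r is a second-moment property and needs more replicates than the
means: the dedicated spread check runs its slice at 100 replicates per
cell, and is phrased as a rank test (negative Spearman trend of IQR in r
plus a strict extremes comparison) because adjacent small-r cells differ by
less than Monte-Carlo resolution at this scale.

## Known limitations

* The greedy cutoff filter approximates the maximum unrelated set.
* Fisher-z intervals ignore correlation between pairs sharing individuals.
* The twin model assumes a common σ_Y² for MZ, DZ, and singleton groups
  (no MZ/DZ heteroscedasticity).
* ρ_c is a lower bound: dominance pushes it below the true
  common-environment share, and it can be negative when 2r_DZ < r_MZ.
* ML standard errors use the AI matrix at the optimum, which is an
  estimate of (not identical to) the observed information.
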