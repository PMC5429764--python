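# Methods

## The genetic model

Phenotypes of near-homozygous recombinant inbred lines (RILs) scored in
multiple environments are modelled with a saturated mixed linear model. For
line *k* in environment *h*,

    y_hk = μ + Σ_i a_i x_ik + Σ_{i<j} aa_ij x_ik x_jk
         + e_h + Σ_i ae_hi x_ik + Σ_{i<j} aae_hij x_ik x_jk + ε_hk

where x_ik ∈ {+1, −1} codes the paternal (QQ) and maternal (qq) homozygote,
a_i is the additive effect of locus *i* (half the expected difference between
homozygote classes), aa_ij an additive-by-additive epistatic effect entering
through the code product, e_h the environment main effect, and ae_hi / aae_hij
per-environment deviations of the genetic effects (they sum to zero over
environments). μ, a and aa are fixed effects; e, ae, aae and the residual ε
are random. RILs carry essentially no heterozygotes, so the model has no
dominance terms.

## Synthetic RIL population

The generator emulates a biparental F13 RIL population bred by single seed
descent (SSD): 138 lines by default, genotyped on a 12-chromosome map and
phenotyped in two environments. Two engines are provided:

- **meiosis** (default, and the reference): starting from the F1, each
  selfing generation draws two gametes per line under Haldane's map function
  (crossovers independent between marker intervals, recombination
  r = (1 − e^(−2d/100))/2 for d cM). After 12 selfing rounds, residual
  heterozygotes — expected at frequency (1/2)^12 ≈ 2.4 × 10⁻⁴ — are resolved
  by a fair coin and logged.
- **mosaic**: draws terminal chromosome mosaics directly using the
  RIL-adjusted recombination fraction R = 2r/(1 + 2r), the closed form for
  selfing RILs. It reproduces the marginal and pairwise-adjacent code
  distribution and is used for fast fixtures; the meiosis engine is its
  oracle in the tests.

Haldane (no interference) was chosen because it makes the engine analytically
checkable: the tests verify R = 2r/(1+2r) and the F13 heterozygosity against
their closed forms at n = 20,000.

### Trait presets

Presets for the four rice yield traits (grain yield GYD, panicles per plant
NP, filled grains per panicle NFGP, 1000-grain weight GW) plant the published
effect architecture: per-locus additive effects on their reported
chromosomes, one additive-by-environment pair for GYD (∓0.65/±0.64 on
rs8203251), and one epistatic pair each for NP (aa = +0.29) and NFGP
(aa = +3.55). Loci are placed at evenly spread positions along their
chromosome (the source reports only chromosome numbers, not genetic
positions).

The within-environment phenotypic variance V_P is never reported directly,
so each preset back-solves it from the constraint that the planted genetic
variance — Σa² + Σaa² + mean_h Σae_h², with Var(x) = 1 — accounts for the
published total heritability; the residual SD is the square root of the
remainder (e.g. GYD: V_P ≈ 21.6, residual SD ≈ 3.51). This makes every
published per-component h² reproducible from the preset to within rounding.
Environment main effects come from the published two-location means, split
symmetrically around the grand mean (e.g. GYD: ±2.585); the sign convention
is E1 = Hangzhou, E2 = Lingshui, D = mean(E1) − mean(E2).

What the generator does *not* emulate: segregation distortion, selection
during SSD, crossover interference, genotyping error and missing data
(beyond optional masking), linkage disequilibrium decay measured in bp, or
polygenic background beyond the planted loci. Passing tests therefore show
the pipeline's behaviour under the stated model, not robustness to these
real-data features.

## Trait statistics and conditioning

Summaries use the sample SD (n−1), CV% = 100·SD/mean, and
D = mean(E1) − mean(E2) with Welch's two-sample comparison for its stars
(with two locations a studentized-range test is equivalent up to scaling).
Correlations are Pearson, per environment, with stars at 0.05/0.01/0.005.

Genotypic values are predicted from the two-way model y_hk = m + env_h + g_k
+ ε with random line effects, using balanced moment estimators (the
line × environment interaction mean square estimates σ²_ε) and shrinkage
λ_k = σ²_g/(σ²_g + σ²_ε/H_k); the closed form is exactly testable and the
design is balanced, so full REML machinery is unnecessary.

The conditional trait T1|T2 is built per environment as
y1 − b_h (y2 − mean_h(y2)) with b_h = Cov_h(y1, y2)/Var_h(y2). The defining
contract — zero within-environment covariance with the given trait — is
exact by construction, conditioning is idempotent, and conditioning on self
yields constants. Whether the original mixed-model software conditions on
observed phenotypes or on predicted genetic effect vectors is not
recoverable; both modes are exposed (`mode="phenotype"`, the default, and
`mode="genotypic"`, which regresses on the given trait's predicted genotypic
values).

## Candidate screening

The screen is a desk-scale reduction of generalized multifactor
dimensionality reduction (GMDR): trait values are reduced to residuals
around environment means; each genotype class of a marker (or each of the
four cells of a pair) is labelled high/low by the sign of its mean training
residual; the score is the k-fold (default 5) cross-validated fraction of
held-out observations whose residual sign matches their class label, with
half credit for empty/ambiguous cells and zero residuals. Folds partition
lines, so a line's two environment records stay together. The score is
invariant to affine transforms of the trait and deterministic given the fold
seed. The top-k terms per chromosome (default min(400, markers per
chromosome)) plus the members of the globally top-k pairs become mapping
candidates.

## Mapping

**Scans.** The single-locus test is a 2-df F-test of the additive column
[x; x] and its environment-interaction contrast [x; −x] against the
environment-only null on the stacked two-environment data; with balanced
environments and centred codes the two columns are exactly orthogonal, so
the scan is closed-form and vectorised. The pair test adds the product term
and its interaction contrast to a model already carrying both marginal
terms. Collinear pairs and monomorphic markers are skipped. −log10(p) is
capped at 300 (perfect fits report F = ∞).

**Experiment-wise threshold.** Line identities are permuted jointly across
environments (each line's records move together, preserving the environment
structure while breaking genotype–phenotype links); each permutation rescans
all candidates and records the maximum F; the threshold is the empirical
(1−α) upper order statistic (`method="higher"`, the conservative
Churchill–Doerge convention). Default 2,000 permutations; the calibration
experiments use 200. When a screened pair set is supplied, pair statistics
enter the same maximum, making the threshold global over both scans.

**Stepwise selection.** Forward steps add the term with the largest
conditional F among those exceeding the threshold (ties break toward smaller
positions); backward steps drop any term whose conditional F falls below it;
the loop runs to a fixed point with a 50-round guard. Duplicated columns
cannot enter twice (rank-deficient additions contribute no F).

**Gibbs sampler.** The selected model is estimated by Gibbs sampling with
flat priors on fixed effects and inverse-gamma(10⁻⁶, 10⁻⁶) priors (a
near-improper scaled inverse-χ²) on the variances of the environment,
ae, aae and residual components. Sweeps use precomputed Gram matrices, so
each iteration's cost is independent of the data size. Defaults: 20,000
iterations, 2,000 burn-in, thinning 10. Because the per-environment random
columns of a term sum to its fixed-effect column, only the sum of the fixed
effect and the environment-mean of its random interaction is identified;
that sum is reported as the main effect, and interaction deviations are
centred per draw. Convergence is flagged when the split-chain diagnostic of
any reported effect exceeds 1.1. The near-zero prior scale pins fixed
effects to machine accuracy on noiseless data while remaining weakly
informative otherwise.

**Heritability.** V_P is the pooled within-environment phenotypic variance
(environment means removed, denominator N − H). Components:
h²(a) = 100·a²·Var(x)/V_P, h²(aa) likewise with the product's variance, and
h²(ae) = 100·mean_h(ae_h²)·Var(x)/V_P — the *mean*, not sum, over
environments, which is the only convention consistent with the published
per-row values. The total is the sum over detected components. A term's
interaction component counts as detected when its 2-df conditional F in the
final least-squares model has p < 0.05.

## Comparison and reporting

Unconditional-vs-conditional status is a pure function of the two
significance sets: *retained* (same term, same component set),
*retained_component_changed*, *absent_under_conditioning*, and
*novel_conditional*. Effect-size fluctuation never changes a status — only
term identity and component set matter. Conditional traits are re-screened
from scratch rather than inheriting the unconditional candidates, since
conditioning is expected to reveal loci invisible marginally. The network
export lists QTSs as nodes (with an environment-specific flag when ae/aae is
present) and epistatic pairs as edges.

The pipeline driver derives every stage seed deterministically (CRC-based)
from the single config seed, so a rerun of the same config is byte-identical
in all result tables.

## Experiment sizes and numerical choices

The calibration experiment uses 200 null datasets of 138 lines × 100
unlinked markers with 200 permutations each; the recovery experiment uses 50
replicates of the GYD preset on a 12-chromosome × 5-marker map (37.5 cM
spacing), screening the top 2 per chromosome into 24 candidates, 200
permutations and 20,000 Gibbs iterations. The sparse map keeps linked
proxies from competing with the causal marker during stepwise entry while
preserving a genuine genome-wide multiplicity burden; these sizes are the
package's chosen desk scale for its own test suite.

Numerical details: rank-deficient blocks are handled by least-squares
pseudo-inverses (a zero-rank addition scores F = 0); residual sums of
squares are clipped at zero against cancellation; imputation ties go to the
left flank; marker sorting is numeric-aware on chromosome labels;
quantile thresholds use the upper order statistic.

## Known limitations

- Scans and the sampler assume exactly two environments (the study design);
  summaries, correlations, conditioning and the simulator are generic.
- Selection power at n = 138 for loci explaining ~5% of variance is
  intrinsically limited (~75–85% at the experiment-wise threshold); recovery
  statements are therefore conditional on selection.
- The GMDR reduction uses sign-of-mean-residual labelling with equal fold
  weighting; the original GPU implementation's exact score function is not
  public.
- No kinship or population-structure correction is attempted: a biparental
  RIL population has uniform relatedness by construction.
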