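# Methods

This note records the statistical model the package implements, the
numerical choices inside the solver, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Genotype handling

Genotypes are stored as counts of an arbitrarily chosen allele per locus
(0/1/2) with a dedicated missing sentinel; missingness is never conflated
with the homozygous-reference code. Locus summaries (allele frequency p,
genotype-class frequencies p₀/p₁/p₂, MAF, call rate) are computed over
non-missing calls only. QC keeps loci with MAF ≥ 0.05 and call rate ≥ 0.97
by default, both thresholds inclusive. Missing calls are then imputed by
sampling from {0,1,2} with the observed genotype-class frequencies of that
locus, from a single seeded generator recorded in the run manifest.

All frequencies feeding the kernels are recomputed from the analysis sample
*after* QC and imputation, pooled over both reciprocal crosses. Whether
frequencies should be taken before or after imputation is not determined by
any external convention we know of; the difference is O(missing rate) ≈
0.4% and the post-imputation choice keeps every kernel consistent with the
exact matrix it is built from. Reference-frequency injection is supported
but off by default. Monomorphic or contrast-free loci yield all-zero
contrast columns (with a warning) rather than being dropped, so the HWE
scaling denominators refer to the same locus panel as the contrasts.

Individual genomic homozygosity is the fraction of homozygous loci in the
QC'd, imputed panel. It is invariant to which allele is counted at each
locus.

## Relationship matrices

Both parameterizations share the additive contrast h_a = x − 2p; they
differ in dominance contrasts and in scaling:

| kernel | HWE | NOIA |
|---|---|---|
| additive | H_aH_aᵀ / 2Σp_jq_j | H_aH_aᵀ / (tr(H_aH_aᵀ)/n) |
| dominance contrast | (−2p², 2pq, −2q²) | (−2p₁p₂, 4p₀p₂, −2p₀p₁)/(p₀+p₂−(p₀−p₂)²) |
| dominance | H_dH_dᵀ / 4Σp_j²q_j² | H_dH_dᵀ / (tr(H_dH_dᵀ)/n) |
| epistatic (aa) | G#G, k = 1 | (G#G) / (tr(G#G)/n) |

The NOIA dominance contrast is orthogonal to the additive contrast under
the *observed* genotype-class frequencies, so additive and dominance
variance estimates do not shift when the other term enters the model even
off Hardy–Weinberg equilibrium. On a sample in exact HWE proportions the
two dominance kernels coincide. Because the additive contrasts are shared,
G_HWE is a scalar multiple of G_NOIA, and any model without a dominance
term has identical REML likelihood under the two parameterizations (the
component absorbs the scalar) — a property the test suite asserts.

Additive-by-dominance and dominance-by-dominance kernels (Hadamard products
of G and D, scaled the same way) are available as optional model extensions
(`ADME+ad+dd`) but excluded from the standard eight-model family and from
selection.

Variance components estimated under differently scaled kernels refer to
different reference populations. For reporting, each component is
multiplied by its own kernel's factor `mean(diag V) − mean(V)` (1 for
identity-covariance terms). For NOIA additive and dominance kernels this
factor is exactly 1 (unit trace mean by construction; zero grand mean
because the contrast columns sum to zero). For the NOIA epistatic kernel
the grand mean of G#G is the mean of squared relationships and is strictly
positive, so its factor is slightly below 1 (≈0.99 in our simulated
populations); we apply the per-kernel factor there too rather than assuming
it away. The correction is applied at reporting time, never baked into the
stored kernels.

The pedigree numerator matrix **A** (tabular method, founders non-inbred)
is provided for comparison with the genomic kernels only.

## REML engine

The restricted log-likelihood convention is
−2logL = log|V| + log|XᵀV⁻¹X| + yᵀPy, omitting the n·log2π constant;
only differences between models fitted to the same records are ever
interpreted. Fixed effects use full-rank treatment coding (first level as
reference); rank deficiency is detected by a pivoted-QR check that names
the confounded columns. Individuals missing the trait, a fixed-effect
level, or a genotype are dropped per trait.

Maximization uses average-information (AI) updates with step-halving,
guarded by an EM-REML fallback (θ ← θ + θ²(yᵀPK Py − tr(PK))/n) whenever
the AI step leaves the feasible region or decreases the likelihood. The
first iteration is always EM. Components are clamped at a floor of
10⁻¹⁰·var(y) rather than pinned: a term parked at the floor is excluded
from the AI solve while its gradient points outward (the full AI system is
ill-conditioned at the boundary and stalls the other components) but
rejoins the updates the moment its gradient turns inward, so an early bad
step cannot freeze a component at zero. Convergence requires |ΔlogL| < 1e−8
and a maximum relative component change < 1e−6, plus no floor component
with an inward-pointing gradient. At convergence, floor components are
reported as 0 and flagged as boundary terms. Starting values split var(y)
equally across all terms; within the model suite, sub-models warm-start
from the full-model estimates. A kernel diagonal jitter of 1e−8 is applied
inside the solver only. A constant response is flagged degenerate with all
components 0. Dense algebra throughout — the target is n ≈ 10³, where one
Cholesky-based iteration costs ~0.5 s on one CPU and fits converge in
5–15 iterations.

BLUPs are û_k = σ²_k K_k Py for kernel terms and per-level effects
σ²_k Z_kᵀ Py for grouping terms; terms with a zero component predict zero.
Standard errors of variance ratios use the first-order delta method with
the inverse AI matrix as the component covariance, boundary components held
fixed at zero, and Legarra factors propagated through the covariance.
Ratio SEs are scale-free. Exact reproduction of ASReml's internal SEs is
not attempted; the delta-method analogue is reported.

## Model family, mixture tests, selection

The eight models add dominance (D), additive-by-additive epistasis (E) and
a maternal term (M, identity covariance over dams) to the additive baseline,
all sharing the fixed effects and (by default) the genomic-homozygosity
covariate; the covariate can be disabled to study its impact on the other
components. The LRT of each sub-model against the full ADME model uses
q = number of omitted variance components as its degrees of freedom, with
the boundary-corrected null Σᵢ C(q,i)/2^q · χ²ᵢ (χ²₀ = point mass at 0).
Critical values are computed by Brent root-finding on the mixture tail; the
exact roots at (α = 0.05, 0.01, 0.001) are 2.706/5.412/9.549 (q=1),
4.231/7.290/11.763 (q=2), 5.434/8.746/13.474 (q=3).

Model selection defaults to a drop-one rule: a component is retained exactly
when dropping it alone from the full model is rejected by the df-1 mixture
LRT, and the best model is the additive baseline plus the retained letters.
We prefer this over the superficially natural "most parsimonious model not
rejected against ADME" rule because the joint df-2 test of two components
can be non-significant even when each single drop is clearly rejected,
making the parsimony rule discard individually indispensable terms; the
parsimony rule remains available (`selection="parsimonious"`). Significance
stars follow the usual \*, \*\*, \*\*\* convention at 0.05/0.01/0.001.

A helper computes the expected excess variance within full-sib families
over the parental additive contribution, ¼σ²_D + ⅛σ²_Eaa + ⅛σ²_Ead +
⅛σ²_Edd — useful for translating kernel-based estimates into the
within-family variance a pedigree analysis would see.

## Inbreeding depression

b is the fixed-effect solution of the homozygosity covariate (trait units
per unit homozygosity). The relative depression b_R = −b / mean uses the
raw phenotypic mean of the analysed records, before fixed-effect
adjustment. The homozygosity quantiles q05/q95 use linear interpolation
between order statistics (no convention is standard enough to assume
otherwise; the interpolated quantile is the default in the scientific
Python stack), and the tail-to-tail performance difference is |b|·(q95−q05).

## Synthetic data

The generator emulates a reciprocal partial-factorial mating design: two
founder groups A and B, with per-locus allele frequencies drawn
independently per group from Beta(5,5) laws (independent draws make the
groups diverge locus by locus even under a common law); sires of A × dams
of B and sires of B × dams of A; a round-robin factorial in which every
parent contributes to ≥ 2 full-sib families, so offspring have both full-
and half-sibs; family sizes from a negative binomial truncated at 1
(study scale: mean 15.1, SD 11.2); offspring genotypes gene-dropped from
stored founder haplotypes, locus by locus. Gene dropping from divergent
groups produces genuine excess heterozygosity — the departure from HWE
that separates the NOIA and HWE kernels — which i.i.d. genotype sampling
would not.

Phenotypes follow the fitted decomposition: additive values Wα from
centered dosages; directional dominance as a common heterozygote effect
δ/m per locus, so the expected phenotype declines by exactly δ per unit
homozygosity while contributing essentially no dominance *variance* — the
infinitesimal-dominance regime in which inbreeding depression coexists
with σ²_D ≈ 0; optional non-directional dominance deviations; additive-by-
additive interactions on a configurable number of locus pairs; one
maternal effect per dam; categorical fixed effects (cross, batch, day,
filleter); a normal residual. Every effect vector is rescaled so its
realized offspring variance equals its target exactly — recovery tests
then measure estimation error, not simulation sampling error. The
intercept is set so the realized trait mean equals its target, and the
default δ equals the trait mean, giving a relative depression b_R ≈ 1.

Two presets: a desk scale (8 parents per role and group, 32 families,
~300 offspring, 800 loci) for unit tests, and a study scale (19 per role,
76 families, ~1150 offspring, 2000 loci; h² = 0.10, m² = 0.09,
e²aa = 0.15, σ²_D = 0) for end-to-end validation. The study-scale suite
fit completes in well under a minute per replicate on one CPU.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data:

* no linkage or LD: loci segregate independently. Realized relationships
  consequently vary less around their expectations than in real genomes,
  and the Fisher information for the epistatic component is roughly half
  of what the real study design delivered (SE(e²aa) ≈ 0.16 here vs ≈ 0.09
  there). Detection power for e²aa = 0.15 at this scale is therefore low
  (~20%), and validation of the epistatic machinery rests on the recovery
  bands and on the analytic/oracle tests rather than on significance
  frequencies;
* founders are unrelated and non-inbred within groups (no nucleus-breeding
  history);
* fixed-effect levels are assigned at random rather than by rearing
  structure, and there is no genotype-by-environment interaction;
* no selection, no sex effects, one generation only.

## Known limitations

Dense O(n³) algebra limits fits to a few thousand individuals. Single
trait only. The AI-based component covariance is a local approximation and
understates uncertainty for components near the boundary; ratio SEs
inherit that. GCTA-format GRM files are written in single precision, so
round-trips are exact only to ~1e−7.
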