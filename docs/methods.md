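# Methods

## Quantitative-genetic model

At a biallelic locus with minor-allele (A₁) frequency p and q = 1 − p, the
genotypic values of A₁A₁/A₁A₂/A₂A₂ are +a, d, −a. Breeding values are
2qα, (q−p)α, −2pα with the substitution effect α = a + d(q − p); dominance
deviations are −2q²d, 2pqd, −2p²d. Summing independent loci gives the
animal-level variances

    σ²_A = Σ_k 2 p_k q_k α_k²        σ²_D = Σ_k (2 p_k q_k d_k)²,

and, when per-marker effects share common variances σ²_a, σ²_d,

    σ²_A = Σ2pq·σ²_a + Σ2pq(q−p)²·σ²_d ,   σ²_D = Σ4p²q²·σ²_d ,

which the package inverts in closed form (`animal_to_marker_variance`) to
move REML animal-level estimates onto the marker scale for BLUP-SNP.

## Relationship matrices

* **A** by the recursive tabular method; founders unrelated, non-inbred.
* **G\*** = W_aW_a′/2Σpq with W_a the allele counts centered at 2p;
  **D\*** = W_dW_d′/4Σp²q² with the dominance coding above. Allele
  frequencies default to the observed post-QC frequencies of the
  individuals in the matrix (base-population frequencies may be supplied).
* **G\*** is mapped affinely (the unique intercept+slope solution) so its
  mean diagonal and mean off-diagonal equal **A**'s, then blended
  **G** = 0.95 **G\*** + 0.05 **A**; **D** = 0.95 **D\*** + 0.05 **I**. The
  blend guarantees eigenvalues ≥ 0.05·λ_min(partner), which keeps every
  downstream Cholesky factorisation safe.
* Matrices are dense; at the target scale (n ≈ 2000) memory is trivial.

## Genotype editing

Loci failing call rate (< 0.9), minor-allele frequency (< 0.005) or a 1-df
χ² goodness-of-fit test against Hardy–Weinberg proportions (P < 10⁻⁵) are
dropped; thresholds are inclusive for keeping, the report attributes each
exclusion to the first failing filter (call rate → MAF → HWE), and the
filters are conjunctive so the retained set is order-independent. Surviving
missing calls are mean-imputed with dosage 2p, which contributes exactly
zero to both centered design matrices. Monomorphic loci pass the HWE test
by convention (the MAF filter removes them). An exact HWE test is a noted
extension; at the cohort sizes targeted here the χ² approximation is
adequate for a 10⁻⁵ threshold.

## REML

Average-information REML on the observed-data scale: V = Σᵢ σᵢ²Vᵢ with
V_E = diag(1/EOP). Score and AI matrix use P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹
(X = 1). AI proposals are step-halved until they stay in the parameter
space and do not increase −2logL; otherwise the monotone EM update
σᵢ² ← σᵢ² + (σᵢ⁴/n)(y′PVᵢPy − tr(PVᵢ)) is taken, and a likelihood decrease
on an EM step raises an error rather than being silently accepted.
Convergence: maximum relative parameter change < 10⁻⁸ (default), cap 200
iterations with a flagged non-converged fit. Variances are floored at
10⁻¹⁰·var(y). The reported −2logL includes every term
(log|V| + log|X′V⁻¹X| + y′Py + (n−1)log2π) with the same fixed-effect
structure across MA/MG/MGD, so differences are valid LRT statistics; the
additive constant matters only if compared across software. Components can
be pinned (`fixed={"sigma_D2": 0}`), which reproduces the reduced model
exactly on the same likelihood scale.

Because the null σ²_D = 0 is on the boundary, the LRT P-value halves the
χ²₁ tail; non-positive statistics (possible through convergence tolerance)
report P = 1.

## Gibbs samplers

Animal level (MGD): blockwise conditionals — μ, then u | rest and v | rest
from their multivariate-normal conditionals (one Cholesky of
K⁻¹/σ² + F⁻¹/σ²_E each), then variances from scaled inverse-χ²
conditionals with flat improper priors (df = n − 2). Marker level
(MGD-SNP): single-site updates of every additive then every dominance
effect, then variances; with variances fixed this is BLUP-SNP and the
posterior means of the effects converge to the ridge solutions. Chains are
deterministic given the seed; the dominance ratio σ²_D/(σ²_A+σ²_D) is
recorded per retained sample so its posterior SD needs no delta method.
Desk-scale defaults are 20 000 iterations / 2 000 burn-in / thin 10;
convergence is always checked with the Geweke z (first 10% vs last 50% of
the retained chain, spectral-density variances via a Bartlett window of
width √length) and never assumed — short SNP-level chains in particular
mix slowly.

## Prediction and cross-validation

At fixed components, predictions for held-out individuals are joint-normal
conditional means: û = σ²_A K[·, t] V_tt⁻¹ (y_t − μ̂) with μ̂ by GLS on the
training records, and v̂ analogously through D; ĝ = û + v̂. Validation
phenotypes never enter the equations (asserted by a permutation canary in
the tests). K-fold assignment is a uniform random partition with sizes
differing by at most one. Accuracy is the unweighted Pearson correlation
r(YD, prediction) and bias the unweighted least-squares slope of YD on the
prediction, per fold; fold means are reported with SE = sd/√K. An
EOP-weighted variant of both statistics is available behind a flag; the
unweighted form is the default and the one used in all reported numbers.
μ is re-estimated within each training set and validation YD are used raw.

## Planned matings

BLUP-SNP effects at marker variances converted from animal-level REML
components feed, for each bull×cow pair, the expected total genetic value
(probability-weighted genotypic values over the offspring genotype
distribution — equivalently an average over the four equiprobable gamete
combinations) and the expected breeding value, which reduces exactly to
the parent average of û. Allocation is a globally sorted greedy pass: all
pairs by score descending (ties by bull then cow index), a pair accepted
when the cow is unmated and the bull below the cap. The published
description of per-cow selection under a cap does not pin down an
algorithm once the cap binds; the global greedy is deterministic,
near-optimal and produces the qualitative usage pattern of a few saturated
bulls plus a tail. An optimal assignment solver would be a drop-in
extension. Gains Δ_G, Δ_U are means of selected matings minus the mean
over all possible matings, absolute and relative to the SD over all
matings; percentage comparisons between selection criteria are computed
from the SD-relative values (the convention under which the published
worked examples reproduce; the absolute-value convention differs slightly
and is not used).

## Synthetic cohorts

The generator emulates a single-generation genotyped cow cohort: founder
sires and dams with independent HWE genotypes at MAF ~ U(0.05, 0.5)
(post-QC spectrum), offspring by gene dropping, many paternal half-sib
families, and a configurable fraction of offspring with a full sib
(default 3%), realized exactly by repeat matings of selected dams. Only
the offspring generation is phenotyped, so validation animals never have
descendants in training. QTL effects (a subset of loci) are drawn normal
and rescaled — the dominance vector by one scalar, the additive vector by
the closed-form root of the induced quadratic — so the implied σ²_A, σ²_D
hit their targets exactly; defaults 200/100/150 put dominance at one third
of the genetic variance. Residuals are N(0, σ²_E/EOP) with EOP ~ U(1, 3)
(use EOP ≡ 1 for conformation-like traits without repeated records).

Deliberately not modelled: linkage and LD (no downstream formula needs
them), selection over generations, missing-data patterns beyond what QC
tests require, and the construction of yield deviations from raw records
(YD are consumed as given). Passing tests therefore demonstrate correctness
of the estimators under the assumed covariance structures, not robustness
to LD, selection or phenotype pre-processing artefacts in real data.

## Problem sizes in tests and the reproduction script

Variance-component recovery runs on ten cohorts of 1000 phenotyped cows ×
5000 loci (500 QTL), the size at which REML estimates are expected within
3 SE of truth across replicates. The dominance null result in
cross-validation is replicated at 25 000 loci: the package's own choice,
because the off-diagonal SD of **D** is then ≈ 0.007 — the dispersion
observed on real dense-chip data — so dominance deviations of non-sibs are
as unpredictable as in the study design being emulated. At a few thousand
loci **D** is several times more dispersed and dominance becomes
artificially predictable, which would misrepresent that design. The
mating demonstration uses 1000 cows × 2000 loci; with dominance at a third
of the genetic variance concentrated in 300 QTL, the g-over-u superiority
is much larger than on real dense data, where cancellation across hundreds
of thousands of loci shrinks it — the demonstration shows the machinery
and the direction of the trade-off, not a calibrated magnitude.

Gibbs samplers are validated against REML (concordance within Monte-Carlo
error) and against each other (animal vs marker level) on 200-cow cohorts;
running the full 10-replicate recovery with Gibbs at n=1000 would cost
hours on one CPU for no additional inferential content.

## Known limitations

* Dominance parameterisation assumes Hardy–Weinberg proportions and no
  inbreeding adjustment of **D**; no single-step (pedigree+genomic) matrix.
* Independence of u and v is assumed (classical partition); directional
  dominance / inbreeding depression and dependent priors between a and d
  are out of scope.
* REML standard errors are not reported from the AI matrix; uncertainty
  statements use the Gibbs posterior.
* The greedy allocator is near-optimal, not provably optimal, once the
  capacity constraint binds.
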