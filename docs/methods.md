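# Methods

This note records the models, estimators, defaults and numerical choices
behind `semgwas`, and what the synthetic-data tests do and do not
establish about real data.

## Marker QC, kinship and structure

Dosages are minor-allele counts in {0, 1, 2}; missing calls are allowed.
QC keeps markers with call rate ≥ 0.95 and MAF ≥ 0.05 (both
configurable). The MAF rule is applied as *exclude markers below the
threshold* — the standard reading of a "MAF < 5%" QC parameter, keeping
the informative markers. Missing dosages are mean-imputed to `2pⱼ`
before centering (the centered cell is exactly 0), which preserves
column means and is the usual choice for kinship construction; no
model-based imputation is attempted. Allele frequencies are sample
frequencies of the post-QC panel.

The kinship matrix is the centered-dosage form
`G = WW′ / 2Σⱼ pⱼ(1−pⱼ)`; under Hardy–Weinberg sampling its diagonal
averages to 1 as markers accumulate, which the tests assert at
m = 5,000. Structure principal components are the left singular vectors
of the column-centered (not row-centered) `W`, so their variance
fractions equal the eigenvalues of `G` normalized by its trace. The
component count is the smallest k reaching a cumulative-variance target
(default 0.80), with an override to force a fixed k: on a real,
LD-structured panel ~23 components can reach 80%, while on the unlinked
synthetic panels the eigenvalue spectrum is much flatter and k is
correspondingly larger — the target, not the count, is the invariant.

## Stage-1 adjustment

Per trait, the randomized-block model `y = Xu + Zg + Wr + e` is fitted
with the intercept and block contrasts fixed and genotypic effects
random with identity covariance, `g ~ N(0, Iσ²_g)`. Identity rather than
`G` is used at this stage (the kinship enters in stage 2); a caller who
wants a kinship-aware stage 1 can pass adjusted values from any other
tool, since downstream stages only need one value per genotype. Variance
components are REML estimates obtained by profiling the restricted
likelihood down to the single ratio γ = σ²_g/σ²_e and optimizing log γ
on [−12, 12] with a bounded scalar search (xatol 1e−10); a ratio at the
lower bound (< 2e−5) raises a boundary warning and proceeds. BLUPs and
residuals come from the mixed-model equations at the REML estimates, and
the adjusted phenotype `y* = Zĝ + ê` — the data minus fitted fixed
effects — is averaged over plots to one record per genotype, matching
what the multi-trait stage consumes. The REML path is verified against a
brute-force profile-likelihood grid (step 1e−3 on log ratio) on small
layouts.

## Multi-trait GBLUP

The Gibbs sampler targets `y*ₖ = 1bₖ + gₖ + eₖ` with
`vec(g) ~ N(0, Σ_g ⊗ G)` and `vec(e) ~ N(0, Σ_e ⊗ I)`, flat prior on b
and a shared inverse-Wishart prior `W⁻¹(S, ν)` on both covariance
matrices. Defaults: `S = I_t · 0.5·var(y*)` and `ν = t + 2` — proper and
weakly informative, with the prior scale tied to the data spread;
traits are not standardized before the fit. Both are configurable, as is
the schedule (default 10,000 iterations / 2,000 burn-in / thin 10;
retained draws = ⌊(iterations − burn-in)/thin⌋). The update order is
fixed (b, g, Σ_g, Σ_e) and a single PCG64 stream drives every draw, so a
seed reproduces the chain byte-for-byte.

Numerics: `G` is eigendecomposed once (jitter 1e−6 added when the
smallest eigenvalue is below 1e−8 of the largest); each sweep
additionally rotates the trait axis by the generalized eigenvectors of
(Σ_g, Σ_e), after which every cell of the rotated `g` has a scalar
normal full conditional. This is exact — a contract test checks the
conditional mean against the naive Kronecker mixed-model-equation solve
at small n. Inverse-Wishart draws use the Bartlett decomposition
(cross-checked against the closed-form mean and, in one dimension,
against the scaled-inverse-chi-square by a KS test). Missing y* cells
are rejected rather than imputed. Degenerate posterior draws with zero
total variance are excluded from summaries with a warning count.

HPD intervals are the empirical shortest windows: over the sorted draws,
the contiguous window of ⌈prob·n⌉ points with minimal width (verified
against exhaustive window search). An effect is flagged significant when
its 95% HPD excludes zero. The Geweke diagnostic compares the first 10%
and last 50% window means, with each window's variance taken from a
Bartlett-windowed spectral-density estimate at frequency zero (lag
window ⌊√n⌋); zero-variance windows return NaN rather than a silent 0.
Autocorrelations use the standard biased estimator.

## Trait network

The network score is the decomposable Gaussian BIC,
`Σ_nodes loglik(node | parents, MLE) − (d/2)·ln n` with d counting one
coefficient per parent plus intercept and variance per node (higher is
better). Hill climbing applies the best improving add/delete/reverse
move per step with acyclicity enforced on every candidate; a gain must
exceed 1e−10 to count as an improvement, and exact ties between moves
are broken by a node-priority order, lexicographic by default. Restart 0
starts from the empty graph and later restarts from random DAGs; on
4-node instances the search with ≥ 10 restarts attains the exhaustive
543-DAG optimum in every test case.

Gaussian BIC is score-equivalent, so the orientation of an arc whose
reversal lies in the same equivalence class is an *exact* tie. If the
bootstrap always broke that tie the same way, direction support would
collapse to 100/0 and the equivalence class would be invisible. Each
bootstrap replicate therefore draws a fresh node-priority permutation
(the headline network keeps the deterministic lexicographic order); a
two-node equivalent pair then shows direction ≈ 50%, and genuinely
oriented arcs still accumulate directional support. Rows are put in a
canonical sorted order before resampling so the tallies depend only on
the data values and the seed. Bootstrap networks use 1 restart each for
budget; strength is the percentage of replicates containing the arc in
either direction, direction the percentage of those with the given
orientation, and arcs are kept at strength ≥ 80 and direction
strictly > 50 (both thresholds configurable). Direction near 50 marks
an orientation-uncertain arc and should be read as an equivalence-class
statement, not a causal claim.

ΔBIC per edge is `score(dag) − score(dag without the edge)` in the
higher-is-better convention, so a positive value means the network
worsens when the edge is dropped; by decomposability only the child's
local score changes.

## Structural coefficients

With the DAG fixed, the system is fully recursive, so equation-by-
equation estimation is consistent: each child trait is regressed on its
parents by GLS under `V = σ²_g G + σ²_e I`, the per-trait variances
fixed at the multi-trait posterior means (two-stage estimation,
mirroring the pipeline order). A full-information system estimator is a
possible extension but was deliberately not used: the equation-wise form
is transparent, testable (it collapses to OLS when the genetic variance
is zero, asserted to 1e−8) and exactly matches the two-stage
construction of the downstream decomposition. Λ is asserted nilpotent
(Λ^t = 0) after every fit. Coefficients are printed with ≥ 5
significant digits because realistic λ values can be ~1e−5.

## Single-SNP scan

Traits are centered and scaled to unit variance; dosage columns are
residualized on the leading PC scores plus intercept (k = 0 leaves them
centered only). The variance components are rescaled by each trait's
sample variance so they refer to the scaled phenotypes. Each SNP is then
tested per trait by GLS under the trait's marginal covariance
`Vₖ = σ²_{g,k} G + σ²_{e,k} I` held fixed across SNPs — the
fixed-covariance economy that makes the scan a single eigendecomposition
plus vectorized cross-products, linear in the number of markers. The
reference distribution for `t = s/se(s)` is standard normal (the usual
large-panel convention; a Student-t reference with caller-chosen df is
available). q-values are Benjamini–Hochberg step-up,
`q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j`, computed per trait across SNPs — matching
per-trait Manhattan significance — with a pooled correction available by
concatenating; the plain step-up rule was chosen over smoothed q-value
estimators because it has no π₀ smoothing parameter to tune. NaN
p-values (zero-variance corrected dosages) propagate to NaN q-values and
do not count toward m.

## Effect decomposition

For each trait, all simple directed paths from every ancestor are
enumerated (deterministic lexicographic order); the indirect effect
through a path is the product of its edge λs times the source trait's
direct effect, and the total is direct plus the path sum. The equivalent
closed form `total = (I − Λ)⁻¹ direct` is always computed alongside and
the two are asserted equal to 1e−10 (relative to the effect scale) —
for a DAG the Neumann series of Λ terminates and enumerates exactly the
simple paths. Arbitrary DAGs are supported, not just the four-trait
chain, so a learned network of any shape decomposes without special
cases. No standard errors are attached to indirect effects.

## Synthetic data

The generator emulates a compact inbred-line panel: marker frequencies
uniform on the MAF range, dosages Binomial(2, p) independently across
individuals and markers (Hardy–Weinberg, linkage equilibrium), optional
missingness. Phenotypes solve `y = Λy + z` with
`z = Σ_qtl wβ + u + e`, `u ~ N(0, Σ_g ⊗ G)`, `e ~ N(0, Σ_e ⊗ I)`; QTL
effects enter the exogenous term on centered dosages so the generating
direct effects coincide with the structural model's definition — this
alignment is what makes decomposition recovery a meaningful test. Plot
records add per-block effects and plot noise around the genotype-level
values.

The `soy96` preset fixes the study-scale conditions: n = 96,
m = 4,070, 3 blocks, traits NP/NG/HGW/PT with means (53.47, 111.40,
14.57, 6.41) and SDs (11.72, 22.54, 3.04, 0.87) in their field units
(pods·plant⁻¹, grains·plant⁻¹, g·100 grains⁻¹, mm), heritabilities
(0.89, 0.79, 0.39, 0.45), the genomic/residual correlation structure of
the emulated panel, chain coefficients (0.00006, −0.05450, 0.00697),
and five planted QTLs spread across chromosomes at ~0.3 trait-SD per
allele — a modest QTL on a polygenic background. `chain_config` is the
unit-scale counterpart for recovery studies (exogenous variances 1,
configurable chain λs and heritabilities).

What the simulations do *not* contain: linkage disequilibrium,
selection, genotype-by-environment interaction, spatial field trends,
or non-Gaussian trait distributions. Passing recovery tests therefore
shows the estimators are correct under their own assumptions — it does
not certify behavior under LD-induced confounding (where structure
correction matters far more) or model misspecification.

## Problem sizes and tolerances in the automated checks

Recovery and calibration checks run at deliberately modest sizes chosen
to exercise the estimators while keeping a full run in minutes:
heritability recovery at n = 200, m = 500, 20 replicates per h² level
with a 10,000/2,000/10 chain (posterior-mean h² shows a genuine small
upward skew near h² = 0.2, from the bounded right-skewed posterior at
this n; the band is ±0.15 on the replicate average); λ recovery at
n = 300 over 50 replicates (±0.1, sign agreement ≥ 95%); network
recovery at n = 500 with strong chain coefficients and B = 500 bootstrap
replicates (strength ≥ 80% for true edges; note the finite-sample BIC
optimum occasionally carries one extra edge beyond the true chain — the
exact-skeleton indicator is reported alongside a true-edges-present
indicator for this reason); scan calibration over 1,000 null SNPs
(empirical size in [0.03, 0.07] at α = 0.05) and 100 replicates of a
planted QTL explaining ~20% of trait variance (top-hit rate ≥ 90%).

## Known limitations

- One chain, single-seed diagnostics (Geweke, ACF); no multi-chain
  R-hat.
- No missing-phenotype support in the multi-trait sampler.
- Stage-1 model has homogeneous residual variances across blocks and no
  spatial terms.
- Structure correction residualizes the dosages only (phenotypes are
  adjusted separately in stage 1); no per-SNP variance-component
  re-estimation.
- Bootstrap direction percentages inherit the score-equivalence
  ambiguity of Gaussian networks; edges whose orientation matters
  should be confirmed by design, not by direction support alone.
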