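# Methods

This note records the models, conventions and numerical choices behind
`sibgwas`, and what the synthetic populations do and do not emulate.

## Relationship matrices

**Pedigree A.** Numerator relationship matrix by the tabular recursion:
individuals are processed in an order where parents precede offspring;
`A_ij = (A_{j,sire(i)} + A_{j,dam(i)})/2` and `A_ii = 1 + A_{sire,dam}/2`.
Unknown parents contribute zero. The recursion is validated against
gene-dropping (average realized identity-by-descent over replicates).

**Genomic G.** VanRaden's first method with observed sample allele
frequencies: `G = M M' / (2 Σ p_i q_i)`, `M` the dosage matrix with column
`i` centered by `2 p_i` (entries `2q_i`, `q_i − p_i`, `−2p_i`). Two
consequences worth knowing:

- Because the frequencies are the sample's own, `M`'s columns sum to zero,
  the ones vector lies in `G`'s null space, and `G` is singular by
  construction. Anything that inverts `G` must either blend
  (`(1−ε)G + εI`, default ε = 0.01) or use the pseudoinverse.
- In a family-structured sample the mean diagonal of `G` falls below 1
  (≈ 0.87 in the default design), because sample frequencies absorb
  between-family drift.

**Heritability convention.** Because of the second point, `REMLFit.h2` is
reported as `σa² k̄ / (σa² k̄ + σe²)` with `k̄ = tr(K)/n`: the realized
fraction of phenotypic variance attributable to the additive term. For a
kinship with unit mean diagonal this is the familiar `σa²/(σa²+σe²)`; for a
raw sample-frequency `G` the naive ratio would overstate the variance
fraction by `1/k̄` (≈ 12% relative here), which parameter-recovery
simulations confirm.

## REML

The restricted likelihood of `y = Xβ + a + e` is profiled over
`δ = σe²/σa²` after one eigendecomposition of `S K S` (`S` the projection
orthogonal to `X`), exactly as in EMMA: with eigenvalues `λ_s` and rotated
data `η_s`, `σ̂a²(δ) = Σ η_s²/(λ_s+δ) / (n−q)` in closed form. The profile
is evaluated on 100 log-spaced points in `[10⁻⁵, 10⁵]` and refined by
bounded scalar minimization (tolerance 10⁻⁸ in log δ). The reported
log-likelihood uses the convention
`logRL = −½[(n−q) log 2π + log|V| + log|X'V⁻¹X| + r'V⁻¹r]`, under which the
intercept-only null model has the closed form
`−½[(n−1)(log 2πσ̂² + 1) + log n]`, so `R²_LR` differences are internally
consistent. The eigen route is tested against a direct-inversion oracle.

Standard errors of `h²` come from the expected (Fisher) information of the
variance components at the optimum plus the delta method — finite-difference
observed information is ill-conditioned when `σ̂a²` sits at the boundary
(null traits), where the expected information remains finite. `K = I` with
an intercept-only model is flagged as unidentifiable rather than silently
fitted.

Missing phenotypes are dropped per trait, consistently from `K`'s rows and
columns.

## Association scans

The EMMAX approximation: variance components from the no-SNP null model are
held fixed; each SNP is tested by GLS after whitening with the Cholesky
factor of `V̂ = σ̂a²K + σ̂e²I`, with a two-sided t-test on
`n − (1 + n_PCs + 1)` degrees of freedom. Monomorphic SNPs yield missing
rows. PC covariates are chosen by forward BIC
(`−2 logL + k log n`, `k` = fixed-effect count, ML likelihood at the REML
variance estimates so fixed parts of different size are comparable; ties go
to fewer PCs).

Likelihood-ratio contributions in the scan module use the profile GLS
likelihood at the null variance components, so a SNP's `R²_LR` is its
partial R² in the whitened space and the joint fit of several SNPs is never
below the best single SNP. Joint `R²_LR` prunes genome-wide significant
SNPs greedily per linkage group: keep the largest |t|, drop neighbours
within 5 Mb, repeat.

**Known approximation limits.** Re-estimating the variance components for
every SNP (the `exact_scan` oracle) agrees with EMMAX only when no single
SNP absorbs appreciable genetic variance. In small family-structured
samples (n of a few hundred, a handful of founders) the restricted
likelihood is nearly flat in δ, and a SNP whose allele frequencies align
with family structure can shift the per-SNP REML fit enough to move
−log10 p by several tenths at that SNP. This is a property of the
approximation, not of the implementation; deviations concentrate at
strongly associated or structure-tagging SNPs and do not disappear at
n ≈ 1,000. Scan calibration is therefore checked differently: on polygenic
no-QTL traits the empirical per-SNP type-I error at α = 0.05 is ≈ 0.049.
On pure-noise traits (no heritability at all) the scan is mildly
conservative (≈ 0.035) because REML overfits a spurious `σa²` onto `G`.

## All-SNP effects and genetic correlations

Allele substitution effects are back-solved from GBLUP breeding values,
`α̂ = (2Σ p_i q_i)⁻¹ M' G⁻ â`. With the unblended singular `G` the
pseudoinverse makes the identity exact: `M α̂` reproduces `â` to numerical
precision and `α̂` equals ridge-regression (RR-BLUP) effects with shrinkage
`σe²/(σa²/(2Σpq))` — asserted to 10⁻⁸ relative in the tests. When a
blended `G` must be used, the aggregation error `max|Mα̂ − â|/max|â|` is
reported on the result rather than hidden.

Per-individual breeding values are decomposed by linkage group using
centered dosages (partial BVs are mean-zero and sum exactly to `Mα̂`).
Genetic correlations are the product-moment correlations of these partial
BVs across individuals (per LG) and of total BVs (genome level) — a
BLUP-correlation proxy, not a multi-trait REML estimate. G-based breeding
values are used for the genome-level correlation.

## LD

Default estimator: squared product-moment correlation of dosage vectors
(composite), appropriate for unphased data; `D²/(p_A p_a p_B p_b)` on
phased haplotypes. Decay profiles use half-open physical-distance bins of
within-linkage-group pairs; empty bins are reported as missing, never
dropped.

## Power

For the regression of phenotype on allele count, the non-centrality is
composed from the marker-QTL LD coefficient `D = r√(p(1−p)q(1−q))`, the
allelic effect `a = √(v_Q/(2q(1−q)))` and
`σ_b = √((1−v_m)/(2np(1−p)))`, giving
`δ_t = b/σ_b = √(n v_m/(1−v_m))` with `v_m = r² v_Q`; a small-sample
gamma-function factor `Γ(v/2)√(2/v)/Γ((v−1)/2)` (→1 for large `v`)
multiplies `δ_t`. Note the allele frequencies cancel exactly: with the QTL
parameterized as a variance fraction, power at `p=q=0.2` equals power at
`p=q=0.5`. Any claim that rarer alleles raise power requires a model in
which the QTL effect, not its variance, is held fixed; the package does not
fabricate such dependence.

**Relatedness.** The correction ratio `R = 1 − r²h²(1−h²)` enters on the
non-centrality scale as either `δ_t·R` (the default, matching the printed
definition of `R` as the NCP ratio) or `δ_t·√R` (`ncp_ratio_power=0.5`).
The Monte-Carlo validator decides between them: simulating full-sib or
half-sib pairs and testing with the mixed-model-style GLS (whitening by the
known within-pair phenotypic correlation `r h²`), the exact NCP ratio per
pair is `√((1−r²h²)/(1−r²h⁴))`, whose expansion is precisely `√R`. The
`δ·√R` variant therefore matches simulation to Monte-Carlo precision
(pooled bias ≲ 0.01 in power at 5,000-replicate resolution), while `δ·R`
is conservative by a few points at `r = 0.5`. Interpreted on the χ² scale,
`R` is the ratio of squared non-centralities, which reconciles the two. A
naive unweighted regression on related pairs, by contrast, loses almost no
mean non-centrality — the t statistic becomes overdispersed instead — so
the choice of test matters more than the correction itself.

**Sidedness.** Power is the non-central-t tail beyond the central critical
value; the default is a one-sided test at `α` (identical to counting only
the upper tail beyond the two-sided `2α` critical value, which is how the
tail expression is written). This convention is the one the Monte-Carlo
validator reproduces; at the reference setting (n = 1,120, r² = 0.25,
v_Q = 0.02) it gives 0.766, versus 0.659 for a two-sided 5% test.

The validator realizes `rel_r ∈ {0, 0.25, 0.5}` as unrelated individuals,
half-sib pairs and full-sib pairs, with marker/QTL haplotypes segregating
from simulated parents (so founder LD is preserved in transmission) and the
polygenic background following the parent-average plus Mendelian-sampling
decomposition. Other values of `rel_r` are rejected rather than
approximated.

## Synthetic populations

Founder haplotypes use a first-order copying process along each linkage
group: allele `j+1` copies allele `j` with probability `exp(−d/L)`
(`d` the bp gap, `L` the correlation length, default 500 kb), else is a
fresh Bernoulli draw from a base frequency in [0.1, 0.9]. `L = 0` gives
independent sites; `d = 0` an exact copy. The default is calibrated so the
offspring population's mean r² in the 400–600 kb band is ≈ 0.25–0.29 —
the long-range LD of a few-founder family design. Meiosis is Haldane:
Poisson crossover counts from the map length (500,000 bp/cM), uniform
placement, no interference. Pollen contamination replaces the paternal
gamete with one from a frequency-shifted donor pool while the recorded
pedigree keeps the design father; contaminated offspring separate from
their nominal families in genotype PCA.

Traits are sums of QTL effects at (or between) markers, per-linkage-group
small-effect polygenic terms (effects at every k-th SNP, k configurable),
and Gaussian noise scaled against the realized genetic variance so the
realized h² matches its target up to sampling error. Pleiotropy is
expressed by repeating a QTL position across traits with per-trait effects;
binary disorder scores are thresholded liabilities and are analyzed
linearly downstream, like the quantitative traits. The generator does not
model dominance, epistasis, genotyping error beyond missingness, selection,
or environment-by-year structure — so passing tests say nothing about those
features of real data.

## Problem sizes used in the test suite

Chosen to exercise the documented study conditions while staying tractable
on a single CPU: heritability recovery uses 50 populations of ~1,200
individuals × 2,500 SNPs; the power grid uses 5,000 Monte-Carlo replicates
per (QTL-variance, relatedness) cell at n = 1,120; the GBLUP↔RR-BLUP
identity n ≈ 300, m = 500; the EMMAX-vs-exact comparison n ≈ 200, m = 500;
scan calibration 50 polygenic null traits × 2,500 SNPs at n ≈ 500; the
pedigree-contamination comparison 50 replicates of four-family populations.
The full suite runs in roughly three minutes.

## Known limitations

- The EMMAX single-SNP approximation deviates from exact per-SNP REML at
  structure-tagging SNPs in small family samples (see above).
- `R²_LR` values from REML fits with different fixed parts are not
  comparable; the scan module therefore switches to profile GLS likelihoods
  for fixed-effect increments.
- The analytic power formula ignores the sampling variability of the
  marker variance (conditional non-centrality jitter), worth ≈ 0.005–0.01
  in power near its inflection point.
- LD r² is computed pooled across families by default; within-family
  disequilibrium differs and is available only by subsetting individuals.
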