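# Methods

## Model and test

`triotau` tests for association between a region of m rare variants (RVs)
and q traits measured on n father–mother–child trios, H0: no association,
against a general alternative, without assuming a trait model.  Traits may
be quantitative, binary, ordinal, or any mixture.

Write T_i = (DT_i, MT_i, OT_i) for the 3q trait values of family i and
G_i for its three m-vectors of genotypic scores (minor-allele counts in
{0,1,2}).  Two families are compared through a pair of kernels:

* **Trait kernel** F(T_i, T_j): a 3q-vector stacking per-member, per-trait
  differences.  Quantitative and binary traits use the plain difference
  t_i − t_j; ordinal traits use sign(t_i − t_j).  (Binary traits could
  equivalently use the sign; the identity difference is used so that binary
  and quantitative traits share one kernel.)  F is antisymmetric:
  F_ij = −F_ji, F_ii = 0.
* **Genotype kernel** K(G_i, G_j): the sum over the three members and m
  loci of log(n_{g_i,l} / n_{g_j,l}), where n_{g,l} is the count, among the
  n individuals of that member role, of genotype category g at locus l.
  Log-ratio count weights up-weight families sitting in rare genotype
  categories, which is what aggregates weak rare-variant signals.

The statistic is the generalized Kendall's τ U-statistic
U = C(n,2)^{-1} Σ_{i<j} F_ij · K(G_i, G_j).  Antisymmetry of F collapses the
pairwise sum to the O(nmq) form

    U = 2/(n−1) Σ_l Σ_i F̄_i · log(n_{DG_il} n_{MG_il} n_{OG_il}),

with centered scores F̄_i = (1/n) Σ_j F_ij.  Both forms are implemented;
`u_statistic_direct` is the brute-force oracle and the equality is tested to
1e-10 relative tolerance over random cohorts spanning all trait-kind mixes.

Conditional on the traits T, under H0 and Hardy–Weinberg equilibrium (HWE)
at each locus with minor allele frequency (MAF) p_l:

    E(U|T)   = 2/(n−1) Σ_i F̄_i Σ_l E[log(n_D n_M n_O)|T]
    Var(U|T) = (2/(n−1))² (Σ_i F̄_i F̄_iᵀ) Σ_l Var[log(n_D n_M n_O)|T]

with closed forms in p_l for the per-locus mean and variance of the
log-count weight (mean: 3[log n + 2(1−p)log(1−p) + 2p log p + 2p(1−p)log 2];
variance: a six-term polynomial–log combination).  Both closed forms are
derived under the device of replacing the random category counts by their
asymptotic values n·P_HWE(g), with parents independent HWE and the child
generated by Mendelian transmission.  `trio_moment_oracle` re-derives both
moments by exact enumeration of the 27 (father, mother, child) genotype
cells; the closed forms agree with the enumeration to ~1e-13 over the whole
MAF range, so the package ships a single code path.

The test statistic is the quadratic form

    χ² = (U − E(U|T))ᵀ Var⁻(U|T) (U − E(U|T)),

referred to a chi-square distribution with df = rank(Var(U|T)).  The
pseudoinverse and rank come from a symmetric eigendecomposition with
relative eigenvalue cutoff 1e-10 (configurable).  With a shared MAF vector
E(U|T) is exactly zero because Σ_i F̄_i = 0; it is nevertheless computed
from the formula (and asserted to vanish) rather than hard-coded.

Degenerate inputs: a covariance of numerical rank 0 (constant traits)
raises; loci monomorphic among founders are removed before testing, with a
log message; cohorts with missing values are rejected at construction
(readers offer `drop_incomplete` to drop whole trios instead — silent
imputation would change the null distribution).

The 3q block order is fixed as (father, mother, child) × (trait 1..q).
The choice is conventional: the quadratic form is invariant under any
simultaneous permutation of U, E(U|T) and Var(U|T), which a test asserts.

## MAF source for the moment formulas

The moment formulas need p_l.  In real-data mode the package estimates it
from founders only, p̂_l = (father + mother scores)/(4n), avoiding
double-counting transmitted alleles.  In simulation studies the same
founder-based estimate is the default (`moment_maf="estimated"`), with the
generating values available via `moment_maf="true"` (per-family block
values under stratification).

The estimated source is the default for a substantive reason.  Under
population stratification, family blocks differ in allele frequencies, and
blocks with higher MAF have both systematically lower log-count weights and
(under the alternative) higher trait values; this between-block association
adds to the within-block signal.  If each family's own subpopulation
frequencies are plugged into the expectation term, that term subtracts the
between-block component exactly and the documented behaviour of the test
under stratification — extra power relative to a homogeneous population of
the same size — disappears.  A data analyst does not know block membership;
estimating one pooled p̂_l per locus is both the realistic procedure and the
one that expresses the method's stratification behaviour.  Measured at
m=20, β1=0.8: power 0.95 (stratified) vs 0.92 (homogeneous) with estimated
MAFs, but 0.89 vs 0.90 with per-family true MAFs.

## Simulation framework

The generator emulates a rare-variant region study on trios:

* **MAFs**: p_l ~ U(0.03, 0.05) independently per locus (defaults), redrawn
  each replicate (configurable to draw-once).  Stratified design: three
  family blocks of 30/30/40 with p_l from (0.03, 0.037), (0.037, 0.044),
  (0.044, 0.05).
* **Genotypes**: parent scores Binomial(2, p_l) (exactly HWE); each child
  allele is transmitted from the corresponding parent (minor with
  probability score/2), so children are Mendelian-consistent and marginally
  HWE — verified by a goodness-of-fit test on 1e5 children.
* **Traits**: T^(k) = μ + γ_kᵀ G + ε per individual, with γ_k = β_k · L for
  a 0/1 causal indicator L (12 of 20 or 20 of 40 causal in the builtin
  designs), μ = 0, β2 = β1/2, and ε ~ N(0, Σ), Σ = [[1, 0.25], [0.25, 1]].
  Each individual draws an independent ε: family members are correlated
  only through shared genotypes.  (A shared family-level ε was evaluated
  and rejected — it destroys most of the power of the design and is
  inconsistent with the reference operating characteristics.)
* **Discretization schemes** (cuts are empirical percentiles of the pooled
  3n values of that trait within the replicate, linear-interpolation
  quantiles; values strictly below a cut take the lower category):
  `binary-binary` — cuts at 30% and 50%; `ordinal-ordinal` — 3 categories
  (50%, 67%) and 4 categories (33%, 54%, 75%); `mixed` — binary at 40% and
  3-category ordinal (50%, 67%); `continuous` — no cuts.  In the mixed
  scheme trait 1 is the binary one (the convention matters only under the
  alternative, where trait 1 carries β1).
* **Replication**: each study runs n_reps replicates (builtin presets:
  1000) of simulate → test at α = 0.05, reporting the rejection proportion
  with the normal-approximation binomial interval rate ± 1.96·√(r(1−r)/n).
  Replicate r uses the deterministic substream SeedSequence(seed,
  spawn_key=(0, r)), so studies are exactly reproducible and
  parallelizable.

Builtin presets cover: null type-I-error designs (n=200 trios, three
schemes, m ∈ {20, 40}); power grids β1 ∈ {0.2, 0.4, 0.6, 0.8} at n=200 and
n=120; and the n=100 stratified-vs-homogeneous comparison with mixed traits.

## What the generator does not emulate

Real trio data differ in ways the generator ignores: linkage disequilibrium
between loci (loci here are independent; the test itself assumes
approximate independence, and `pairwise_ld_r2` exists to check it on real
data), genotyping error and Mendelian inconsistencies (an optional
warn-only audit is provided), missingness, covariates, ascertainment of
families through affected children, and non-normal trait errors.  Passing
the replication suite therefore shows correctness of the implementation
under the stated model, not robustness to these features.

## Known limitations

* **Finite-sample conservativeness at rare MAFs.**  The closed-form
  Var(U|T) replaces category counts by n·P_HWE(g).  With n=100–200 trios
  and p ∈ (0.03, 0.05), the expected minor-homozygote count is 0.1–0.5,
  while an observed count is at least 1; direct Monte-Carlo measurement of
  the true conditional variance (traits fixed, genotypes resimulated) gives
  88–97% of the closed form at these sizes.  The test is therefore mildly
  conservative at desk scale: null rejection at α=0.05 runs ≈0.035–0.050,
  and power sits a few points below what a perfectly calibrated statistic
  would give.  The effect vanishes asymptotically: at n=1000, or with
  common variants (p ≈ 0.2–0.3) at n=200, measured type-I error is
  0.044–0.046.
* The chi-square reference is asymptotic in n; very small cohorts (tens of
  trios) will be further from nominal.
* Only trio pedigrees are supported; larger families must be decomposed to
  trios upstream.
* No covariate adjustment; dependent loci should be screened with the LD
  check first.

## Problem sizes in the shipped checks

The test suite runs the full 1000-replicate studies for the six null
designs (n=200) and the sixteen power cells (n=100), plus a four-point
power grid at n=200 — about 30k replicates in under a minute, since each
replicate is O(nm) for simulation and O(nmq) for the statistic.  Unit and
property tests use cohorts of 3–8 families so the brute-force pairwise
oracle stays exact and instant.  The end-to-end file-format check scans a
synthetic 593-locus, 100-trio dataset in 40-locus windows.
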