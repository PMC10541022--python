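# triotau

Nonparametric association testing between **multiple traits** and a region
of **rare variants** using **nuclear-family trio** data.

Rare variants (minor allele frequency below ~5%) carry too little
per-locus signal for single-marker tests, and complex diseases are usually
recorded as several phenotypes of mixed type — quantitative measurements,
binary statuses, ordinal severities.  `triotau` implements a
region-level test that handles all of this at once: it needs no trait
model, accepts any mixture of trait types, pools evidence across the loci
of a region, and, because it is built on family trios, is robust to
population stratification.  It is aimed at statistical geneticists running
family-based rare-variant association scans, and at methodologists who
want a reproducible simulation framework for this class of tests.

## The statistic

For trios i = 1..n with trait vectors T_i (father, mother, child × q
traits) and genotypic scores G_i at m loci, the test uses a generalized
Kendall's τ U-statistic

$$U = \binom{n}{2}^{-1} \sum_{i<j} F(T_i,T_j)\, K(G_i,G_j),$$

where F stacks per-member trait differences (plain differences for
quantitative/binary traits, sign differences for ordinal ones) and
K sums per-member, per-locus log-ratios of genotype-category counts,
$K_l(g_i, g_j) = \log(n_{g_i,l} / n_{g_j,l})$.  Antisymmetry of F reduces U
to a single sum over families weighted by
$\log(n_{DG_{il}} n_{MG_{il}} n_{OG_{il}})$.  Conditional on the traits,
under the null and Hardy–Weinberg equilibrium, U has closed-form mean and
covariance in the per-locus minor allele frequencies, and

$$\chi^2 = (U - E(U|T))^{\top}\, \mathrm{Var}^{-}(U|T)\, (U - E(U|T))$$

is referred to a χ² distribution with degrees of freedom equal to the rank
of the conditional covariance.  See `docs/methods.md` for the full model,
assumptions, and numerical conventions.

## Worked example

Generate a synthetic 194-trio dataset (a binary and an ordinal trait, 120
rare loci), then scan it in 40-locus regions:

```python
from triotau import TraitSpec, region_scan
from triotau.io import make_fixture, load_cohort

paths = make_fixture(seed=42, n=194, m=120, q=2, scheme="mixed", out_dir="demo")
cohort = load_cohort(paths["ped"], paths["map"], paths["pheno"],
                     TraitSpec(("binary", "ordinal")))
for result in region_scan(cohort, window=40):
    print(result)
```

```
region 1-40: chi2=4.2238 df=6 p=0.6464 (40 loci)
region 41-80: chi2=5.8503 df=6 p=0.4402 (40 loci)
region 81-120: chi2=4.7581 df=6 p=0.5752 (40 loci)
```

Each region reports the quadratic-form statistic, its degrees of freedom
(rank of the conditional covariance — here 6 = 3 family members × 2
traits), and the upper-tail p-value; none of these null-simulated regions
is significant, as expected.  The same scan is available from the shell:

```sh
triotau fixture --seed 42 --n 194 --m 120 --q 2 --scheme mixed --out-dir demo
triotau test --ped demo/fixture.ped --map demo/fixture.map \
             --pheno demo/fixture.pheno.tsv \
             --trait-types binary,ordinal --window 40
```

Replication studies run from named presets; for example the stratified
power design (100 trios in three blocks with different MAF ranges, mixed
traits, effect sizes β₁=0.8, β₂=0.4):

```sh
$ triotau simulate --scenario strat/m20/yes/b0.8 --seed 1 --reps 200
scenario	beta1	beta2	rejection_rate	ci_lo	ci_hi	n_reps	seed
strat/m20/yes/b0.8	0.8	0.4	0.9450	0.9134	0.9766	200	1
```

i.e. the test rejects in 94.5% of replicates at α = 0.05 under this
alternative.  `triotau simulate --list` shows all presets.

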