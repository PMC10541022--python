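"""Monte-Carlo study machinery: trio simulation, trait schemes, replication.

A study scenario describes a population of trio families: per-locus minor
allele frequencies drawn uniformly from an interval (optionally in several
family blocks with different intervals, modelling population
stratification), parent genotypes under Hardy-Weinberg equilibrium, children
by Mendelian transmission, and per-individual traits from the linear model

    T^(k) = mu + gamma_k' G + eps,    gamma_k = beta_k * L,

where L is the 0/1 causal-locus indicator and the error vector of each
individual is multivariate normal with covariance Sigma.  Continuous traits
are optionally discretized into binary/ordinal categories at pooled sample
percentiles (the three named schemes below).  A study runs many independent
replicates of (simulate, test at level alpha) and reports the rejection
proportion with a binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cohort import TraitSpec, TrioCohort
from .statistic import (
    MomentInputs,
    association_test,
)

#: Named discretization schemes: trait kinds and percentile cuts per trait.
#: binary-binary  -- two binary traits cut at the 30% and 50% percentiles;
#: ordinal-ordinal -- a 3-category trait (50%, 67%) and a 4-category trait
#:                    (33%, 54%, 75%);
#: mixed          -- a binary trait (40%) and a 3-category ordinal (50%, 67%);
#: continuous     -- both traits left quantitative.
SCHEMES = {
    "binary-binary": (("binary", "binary"), ((30.0,), (50.0,))),
    "ordinal-ordinal": (("ordinal", "ordinal"), ((50.0, 67.0), (33.0, 54.0, 75.0))),
    "mixed": (("binary", "ordinal"), ((40.0,), (50.0, 67.0))),
    "continuous": (("quantitative", "quantitative"), (None, None)),
}

#: Default MAF interval for the homogeneous design.
DEFAULT_MAF_INTERVAL = (0.03, 0.05)

#: Stratified design: three family blocks with disjoint MAF sub-intervals.
STRATIFIED_BLOCKS = (
    (30, (0.03, 0.037)),
    (30, (0.037, 0.044)),
    (40, (0.044, 0.05)),
)

#: Causal-locus indicators (12 of 20, 20 of 40 causal).
CAUSAL_M20 = (1, 1, 0, 0, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 0)
CAUSAL_M40 = (
    1, 1, 0, 0, 1, 1, 1, 1, 1, 0,
    0, 0, 1, 1, 1, 1, 0, 1, 0, 0,
    1, 0, 1, 0, 1, 1, 1, 0, 0, 0,
    0, 0, 0, 0, 0, 1, 1, 0, 0, 1,
)


@dataclass
class SimulationConfig:
    """Full description of one study scenario.

    Parameters
    ----------
    n_families
        Number of trio families.
    m_loci
        Number of rare-variant loci in the tested region.
    maf_blocks
        Sequence of ``(family_count, (low, high))`` pairs; per-locus MAFs of
        each block are drawn uniformly from its interval.  A single block is
        the homogeneous design.  Counts must sum to ``n_families``.
    causal_indicator
        0/1 vector L of length ``m_loci``.
    beta1, beta2
        Effect sizes of the two traits (gamma_k = beta_k * L).
    mu
        Trait intercept.
    sigma
        q x q error covariance (default: unit variances, 0.25 correlation).
    scheme
        One of ``SCHEMES`` or ``"custom"`` (then supply ``trait_kinds`` and
        ``cut_percentiles`` explicitly).
    cut_percentiles
        Per-trait percentile cut lists (None for a quantitative trait).
    alpha
        Test level per replicate.
    n_reps
        Number of replicates.
    seed
        Base seed; every replicate uses a deterministic substream.
    redraw_mafs
        Draw fresh per-locus MAFs every replicate (default) or once per study.
    betas
        Optional explicit effect-size tuple, overriding (beta1, beta2) when
        the scenario has q != 2 traits.
    moment_maf
        MAF source for the conditional moment formulas: ``"estimated"``
        (default; founder-based estimates per replicate, the same procedure
        as real-data mode) or ``"true"`` (the generating values, per-family
        under stratification).  The estimated source is the default because
        the test's documented behaviour under population stratification --
        extra power from frequency heterogeneity -- is only expressed when
        the moments do not condition on each family's own subpopulation
        frequencies.
    """

    n_families: int
    m_loci: int
    maf_blocks: Sequence[tuple[int, tuple[float, float]]] = (
        (0, DEFAULT_MAF_INTERVAL),
    )
    causal_indicator: Sequence[int] | None = None
    beta1: float = 0.0
    beta2: float = 0.0
    mu: float = 0.0
    sigma: np.ndarray | None = None
    scheme: str = "mixed"
    trait_kinds: tuple[str, ...] | None = None
    cut_percentiles: tuple[tuple[float, ...] | None, ...] | None = None
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0
    redraw_mafs: bool = True
    betas: tuple[float, ...] | None = None
    moment_maf: str = "estimated"
    name: str = ""

    def __post_init__(self) -> None:
        if self.causal_indicator is None:
            self.causal_indicator = (0,) * self.m_loci
        self.causal_indicator = np.asarray(self.causal_indicator, dtype=float)
        if self.causal_indicator.size != self.m_loci:
            raise ValueError("causal indicator length must equal m_loci")
        if not np.isin(self.causal_indicator, (0, 1)).all():
            raise ValueError("causal indicator must be 0/1")
        blocks = []
        for count, (lo, hi) in self.maf_blocks:
            if count == 0 and len(self.maf_blocks) == 1:
                count = self.n_families  # single-block shorthand
            if not (0 < lo < hi < 1):
                raise ValueError(f"bad MAF interval ({lo}, {hi})")
            blocks.append((int(count), (float(lo), float(hi))))
        self.maf_blocks = tuple(blocks)
        if sum(c for c, _ in self.maf_blocks) != self.n_families:
            raise ValueError("maf_blocks family counts must sum to n_families")
        if self.scheme != "custom":
            if self.scheme not in SCHEMES:
                raise ValueError(f"unknown scheme {self.scheme!r}")
            kinds, cuts = SCHEMES[self.scheme]
            self.trait_kinds = kinds
            self.cut_percentiles = cuts
        if self.trait_kinds is None or self.cut_percentiles is None:
            raise ValueError("custom scheme needs trait_kinds and cut_percentiles")
        self.trait_kinds = tuple(self.trait_kinds)
        q = len(self.trait_kinds)
        if len(self.cut_percentiles) != q:
            raise ValueError("one percentile list per trait required")
        for cuts in self.cut_percentiles:
            if cuts is None:
                continue
            arr = np.asarray(cuts, dtype=float)
            if arr.size and not (np.all(np.diff(arr) > 0) and arr.min() > 0 and arr.max() < 100):
                raise ValueError("percentile cuts must be strictly increasing in (0, 100)")
        if self.betas is None:
            if q != 2:
                raise ValueError("supply explicit betas for q != 2 traits")
            self.betas = (self.beta1, self.beta2)
        self.betas = tuple(float(b) for b in self.betas)
        if len(self.betas) != q:
            raise ValueError("betas length must equal the number of traits")
        if self.sigma is None:
            self.sigma = np.eye(q) + 0.25 * (np.ones((q, q)) - np.eye(q))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (q, q) or not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be a symmetric q x q matrix")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("sigma must be positive definite")
        if self.moment_maf not in ("estimated", "true"):
            raise ValueError("moment_maf must be 'estimated' or 'true'")

    @property
    def q(self) -> int:
        return len(self.trait_kinds)


@dataclass
class StudyResult:
    """Rejection summary of one replication study."""

    rejection_rate: float
    n_reps: int
    monte_carlo_ci: tuple[float, float]
    per_rep_pvalues: np.ndarray | None = None
    name: str = ""


def binomial_ci(rate: float, n_reps: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% interval rate +/- z sqrt(rate(1-rate)/n)."""
    half = z * np.sqrt(rate * (1 - rate) / n_reps)
    return (rate - half, rate + half)


def draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-block, per-locus MAFs uniformly from each block's interval.

    Returns an array of shape (n_blocks, m_loci); a single block reproduces
    the homogeneous design.
    """
    out = np.empty((len(config.maf_blocks), config.m_loci))
    for b, (_, (lo, hi)) in enumerate(config.maf_blocks):
        out[b] = rng.uniform(lo, hi, size=config.m_loci)
    return out


def simulate_trio_genotypes(
    n: int, maf: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate n trios at the given per-locus MAFs.

    Parents are i.i.d. HWE: the minor-allele count at locus l is
    Binomial(2, p_l).  Each child receives one allele from each parent,
    minor with probability (parent count)/2, so children are
    Mendelian-consistent by construction and marginally HWE as well.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf >= 1):
        raise ValueError("MAFs must lie in (0, 1)")
    m = maf.size
    fathers = rng.binomial(2, maf, size=(n, m))
    mothers = rng.binomial(2, maf, size=(n, m))
    from_father = rng.random((n, m)) < fathers / 2.0
    from_mother = rng.random((n, m)) < mothers / 2.0
    children = from_father.astype(np.int64) + from_mother.astype(np.int64)
    return fathers, mothers, children


def simulate_quantitative_traits(
    genotypes: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous traits T^(k) = mu + gamma_k' G + eps for all three roles.

    Each individual's own genotype vector enters the mean; every individual
    draws an independent error vector from N(0, Sigma), so family members are
    correlated only through shared genotypes.
    """
    gamma = config.causal_indicator[:, None] * np.asarray(config.betas)[None, :]
    chol = np.linalg.cholesky(config.sigma)
    out = []
    for g in genotypes:
        eps = rng.standard_normal((g.shape[0], config.q)) @ chol.T
        out.append(config.mu + g @ gamma + eps)
    return tuple(out)


def discretize_traits(
    values: np.ndarray, cut_percentiles: Sequence[float] | None
) -> np.ndarray:
    """Cut a pooled continuous sample into ordered categories 0, 1, 2, ...

    Cut points are the empirical percentiles (linear-interpolation quantiles)
    of ``values`` itself; a value strictly below the first cut maps to
    category 0, values at or above a cut move up one category.  With a single
    cut this yields a binary 0/1 trait.  ``None`` returns the values
    unchanged (quantitative trait).
    """
    values = np.asarray(values, dtype=float)
    if cut_percentiles is None:
        return values
    if np.ptp(values) == 0:
        raise ValueError("constant trait vector: percentile cuts are degenerate")
    cuts = np.quantile(values, np.asarray(cut_percentiles, dtype=float) / 100.0)
    return np.searchsorted(cuts, values, side="right").astype(float)


def _simulate_cohort(
    config: SimulationConfig,
    rng: np.random.Generator,
    mafs: np.ndarray | None = None,
) -> tuple[TrioCohort, MomentInputs]:
    """One replicate's cohort plus the true MAFs for the moment formulas.

    With several blocks the moment inputs carry each family's own block MAFs
    (the per-family structure of the moment sums); with one block a shared
    m-vector is used.
    """
    if mafs is None:
        mafs = draw_mafs(config, rng)
    g_parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    fam_maf_rows = []
    for (count, _), block_maf in zip(config.maf_blocks, mafs):
        g_parts.append(simulate_trio_genotypes(count, block_maf, rng))
        fam_maf_rows.append(np.tile(block_maf, (count, 1)))
    gf = np.vstack([p[0] for p in g_parts])
    gm = np.vstack([p[1] for p in g_parts])
    gc = np.vstack([p[2] for p in g_parts])
    tf, tm, tc = simulate_quantitative_traits((gf, gm, gc), config, rng)
    n = config.n_families
    for k in range(config.q):
        pooled = np.concatenate([tf[:, k], tm[:, k], tc[:, k]])
        cats = discretize_traits(pooled, config.cut_percentiles[k])
        tf[:, k], tm[:, k], tc[:, k] = cats[:n], cats[n : 2 * n], cats[2 * n :]
    cohort = TrioCohort(gf, gm, gc, tf, tm, tc, TraitSpec(config.trait_kinds))
    if len(config.maf_blocks) == 1:
        maf_inputs = MomentInputs(mafs[0], n, source="provided")
    else:
        maf_inputs = MomentInputs(np.vstack(fam_maf_rows), n, source="provided")
    return cohort, maf_inputs


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Deterministic independent substream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, rep)))


def run_study(config: SimulationConfig, keep_pvalues: bool = True) -> StudyResult:
    """Estimate the rejection rate of the test over ``config.n_reps`` replicates.

    Each replicate simulates a fresh cohort, discretizes traits per the
    scheme, runs the chi-square test (moment MAFs per ``config.moment_maf``),
    and rejects at level alpha.  Replicates use deterministic substreams of the
    base seed, so studies are exactly reproducible (and parallelizable).
    """
    fixed_mafs = None
    if not config.redraw_mafs:
        maf_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, 0))
        )
        fixed_mafs = draw_mafs(config, maf_rng)
    pvalues = np.empty(config.n_reps)
    for rep in range(config.n_reps):
        rng = _replicate_rng(config.seed, rep)
        cohort, maf_inputs = _simulate_cohort(config, rng, mafs=fixed_mafs)
        maf = None if config.moment_maf == "estimated" else maf_inputs
        result = association_test(cohort, maf=maf)
        pvalues[rep] = result.p_value
    rate = float(np.mean(pvalues < config.alpha))
    return StudyResult(
        rejection_rate=rate,
        n_reps=config.n_reps,
        monte_carlo_ci=binomial_ci(rate, config.n_reps),
        per_rep_pvalues=pvalues if keep_pvalues else None,
        name=config.name,
    )


def builtin_scenarios() -> dict[str, SimulationConfig]:
    """Named presets for the reference study designs.

    Keys::

        type1/scheme{1,2,3}/m{20,40}          null, n=200, 1000 reps
        power/scheme{1,2,3}/m{20,40}/b{beta1} n=200 power grid
        strat/m{20,40}/{no,yes}/b{beta1}      n=100 mixed traits,
                                              homogeneous vs stratified MAFs
        n120/scheme{1,2,3}/m{20,40}/b{beta1}  reduced-sample power grid

    beta2 is always beta1 / 2.  All presets use seed 0; rebuild with
    ``dataclasses.replace(cfg, seed=...)`` for independent runs.
    """
    scheme_names = {1: "binary-binary", 2: "ordinal-ordinal", 3: "mixed"}
    causal = {20: CAUSAL_M20, 40: CAUSAL_M40}
    presets: dict[str, SimulationConfig] = {}

    def add(name: str, **kw) -> None:
        presets[name] = SimulationConfig(name=name, **kw)

    for s, scheme in scheme_names.items():
        for m in (20, 40):
            add(
                f"type1/scheme{s}/m{m}",
                n_families=200, m_loci=m, causal_indicator=causal[m],
                beta1=0.0, beta2=0.0, scheme=scheme,
            )
            for b1 in (0.2, 0.4, 0.6, 0.8):
                add(
                    f"power/scheme{s}/m{m}/b{b1:.1f}",
                    n_families=200, m_loci=m, causal_indicator=causal[m],
                    beta1=b1, beta2=b1 / 2, scheme=scheme,
                )
                add(
                    f"n120/scheme{s}/m{m}/b{b1:.1f}",
                    n_families=120, m_loci=m, causal_indicator=causal[m],
                    beta1=b1, beta2=b1 / 2, scheme=scheme,
                )
    for m in (20, 40):
        for b1 in (0.2, 0.4, 0.6, 0.8):
            add(
                f"strat/m{m}/no/b{b1:.1f}",
                n_families=100, m_loci=m, causal_indicator=causal[m],
                beta1=b1, beta2=b1 / 2, scheme="mixed",
            )
            add(
                f"strat/m{m}/yes/b{b1:.1f}",
                n_families=100, m_loci=m, causal_indicator=causal[m],
                maf_blocks=STRATIFIED_BLOCKS,
                beta1=b1, beta2=b1 / 2, scheme="mixed",
            )
    return presets


def scenario(name: str, seed: int | None = None, n_reps: int | None = None) -> SimulationConfig:
    """Look up a builtin scenario, optionally overriding seed / replications."""
    presets = builtin_scenarios()
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; see builtin_scenarios()")
    cfg = presets[name]
    kw = {}
    if seed is not None:
        kw["seed"] = seed
    if n_reps is not None:
        kw["n_reps"] = n_reps
    return replace(cfg, **kw) if kw else cfg
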