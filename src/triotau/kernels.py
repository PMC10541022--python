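"""Trait and genotype kernels between trio families.

The association statistic compares every pair of families through two
kernels.  The trait kernel stacks per-member, per-trait differences (plain
differences for quantitative/binary traits, sign differences for ordinal
traits) into a 3q-vector with block order (father, mother, child) x
(trait 1..q).  The genotype kernel is a sum of per-member, per-locus
log-ratios of genotype category counts, which rewards pairs of families whose
genotypes sit in categories of different population frequency.

Because the trait kernel is antisymmetric (F_ij = -F_ji), the pairwise double
sum collapses to a single sum over families of the centered trait scores
F_bar_i = (1/n) sum_j F_ij weighted by per-family log genotype-count weights;
this module provides both ingredients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ROLES, TrioCohort

N_GENOTYPES = 3  # minor-allele counts 0, 1, 2


def trait_difference(kind: str, a: float, b: float) -> float:
    """Per-trait difference kernel f_k(a - b).

    Quantitative and binary traits use the identity difference ``a - b``;
    ordinal traits use ``sign(a - b)`` in {-1, 0, 1}.
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("trait values must be finite")
    if kind in ("quantitative", "binary"):
        return float(a) - float(b)
    if kind == "ordinal":
        return float(np.sign(a - b))
    raise ValueError(f"unknown trait kind {kind!r}")


def pairwise_trait_kernel(cohort: TrioCohort, i: int, j: int) -> np.ndarray:
    """Trait kernel F_ij between families i and j (0-based indices).

    Returns the 3q-vector (father block, mother block, child block), each
    block applying :func:`trait_difference` trait by trait.  Antisymmetric:
    F_ij = -F_ji, F_ii = 0.
    """
    n = cohort.n
    for idx in (i, j):
        if not (0 <= idx < n):
            raise IndexError(f"family index {idx} out of range for n={n}")
    out = np.empty(3 * cohort.q)
    for r, role in enumerate(ROLES):
        t = cohort.traits(role)
        for k, kind in enumerate(cohort.trait_spec.kinds):
            out[r * cohort.q + k] = trait_difference(kind, t[i, k], t[j, k])
    return out


@dataclass
class CenteredTraitScores:
    """The n x 3q matrix of centered trait scores F_bar_i.

    Row i is the average of the pairwise trait kernel of family i against all
    n families (self included, contributing zero).  Antisymmetry of the
    kernel forces every column to sum to zero.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] % 3:
            raise ValueError("scores must be an n x 3q matrix")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def q(self) -> int:
        return self.scores.shape[1] // 3


def _centered_column(values: np.ndarray, kind: str) -> np.ndarray:
    """Centered scores for one member-role/trait column."""
    n = values.shape[0]
    if kind in ("quantitative", "binary"):
        # (1/n) sum_j (t_i - t_j) = t_i - mean(t)
        return values - values.mean()
    # ordinal: (1/n) (#{t_j < t_i} - #{t_j > t_i})
    order = np.sort(values)
    less = np.searchsorted(order, values, side="left")
    greater = n - np.searchsorted(order, values, side="right")
    return (less - greater) / n


def centered_trait_scores(cohort: TrioCohort) -> CenteredTraitScores:
    """Compute F_bar_i = (1/n) sum_j F_ij for every family, in O(n log n)."""
    q = cohort.q
    scores = np.empty((cohort.n, 3 * q))
    for r, role in enumerate(ROLES):
        traits = cohort.traits(role)
        for k, kind in enumerate(cohort.trait_spec.kinds):
            scores[:, r * q + k] = _centered_column(traits[:, k], kind)
    return CenteredTraitScores(scores)


def genotype_category_counts(cohort: TrioCohort) -> np.ndarray:
    """Count genotype categories per member role and locus.

    Returns an integer array of shape (3, m, 3) indexed by
    (role in ROLES order, locus, genotype value); counts over each
    (role, locus) sum to n.
    """
    counts = np.empty((3, cohort.m, N_GENOTYPES), dtype=np.int64)
    for r, role in enumerate(ROLES):
        g = cohort.genotypes(role)
        for val in range(N_GENOTYPES):
            counts[r, :, val] = (g == val).sum(axis=0)
    return counts


def log_count_weights(cohort: TrioCohort, counts: np.ndarray | None = None) -> np.ndarray:
    """Per-family, per-locus genotype weight log(n_DG * n_MG * n_OG).

    Entry (i, l) sums, over the three members of family i, the log of the
    count of that member's own genotype category at locus l.  Counts of
    observed genotypes are at least 1 (each genotype counts itself), so the
    logs are always defined.
    """
    if counts is None:
        counts = genotype_category_counts(cohort)
    log_counts = np.log(np.where(counts > 0, counts, 1))
    cols = np.arange(cohort.m)
    w = np.zeros((cohort.n, cohort.m))
    for r, role in enumerate(ROLES):
        w += log_counts[r][cols[None, :], cohort.genotypes(role)]
    return w
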