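"""Core containers: trait-type declarations and trio cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Valid trait kinds.  Binary and quantitative traits share the identity
#: difference kernel; ordinal traits use the sign of the difference.
TRAIT_KINDS = ("quantitative", "binary", "ordinal")

#: Fixed member-role order used for every 3q-block vector in the package.
ROLES = ("father", "mother", "child")


@dataclass(frozen=True)
class TraitSpec:
    """Declares the kind of each of the q traits under study.

    The kind drives the per-trait difference kernel: quantitative and binary
    traits are compared by their plain difference, ordinal traits by the sign
    of the difference.

    Parameters
    ----------
    kinds
        Ordered sequence of length q; each entry one of ``"quantitative"``,
        ``"binary"``, ``"ordinal"``.
    """

    kinds: tuple[str, ...]

    def __init__(self, kinds) -> None:
        kinds = tuple(kinds)
        if len(kinds) < 1:
            raise ValueError("at least one trait must be declared")
        for k in kinds:
            if k not in TRAIT_KINDS:
                raise ValueError(f"unknown trait kind {k!r}; expected one of {TRAIT_KINDS}")
        object.__setattr__(self, "kinds", kinds)

    @property
    def q(self) -> int:
        return len(self.kinds)


@dataclass
class TrioCohort:
    """Genotypes and traits for n father-mother-child trios.

    Genotypic scores are minor-allele counts in {0, 1, 2} at m loci; each of
    the three members carries q trait values.  The container validates shapes
    and value ranges but does not require Mendelian-consistent children (real
    data contain genotyping errors); use :meth:`check_mendelian` for an
    optional warn-only audit.

    Attributes
    ----------
    father_genotypes, mother_genotypes, child_genotypes
        Integer arrays of shape (n, m) with entries in {0, 1, 2}.
    father_traits, mother_traits, child_traits
        Float arrays of shape (n, q).
    trait_spec
        The :class:`TraitSpec` declaring the kind of each trait column.
    """

    father_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    child_genotypes: np.ndarray
    father_traits: np.ndarray
    mother_traits: np.ndarray
    child_traits: np.ndarray
    trait_spec: TraitSpec

    def __post_init__(self) -> None:
        gmats = []
        for name in ("father_genotypes", "mother_genotypes", "child_genotypes"):
            g = np.asarray(getattr(self, name))
            if g.ndim != 2:
                raise ValueError(f"{name} must be 2-D (families x loci)")
            if g.size and not np.isin(g, (0, 1, 2)).all():
                raise ValueError(f"{name} contains values outside {{0, 1, 2}}")
            g = g.astype(np.int64, copy=False)
            setattr(self, name, g)
            gmats.append(g)
        if not (gmats[0].shape == gmats[1].shape == gmats[2].shape):
            raise ValueError("genotype matrices must share one (n, m) shape")
        n, _ = gmats[0].shape
        if n < 2:
            raise ValueError("a cohort needs at least two families")
        tmats = []
        for name in ("father_traits", "mother_traits", "child_traits"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.ndim != 2:
                raise ValueError(f"{name} must be 2-D (families x traits)")
            if not np.isfinite(t).all():
                raise ValueError(
                    f"{name} contains missing or non-finite values; "
                    "drop incomplete families before building the cohort"
                )
            setattr(self, name, t)
            tmats.append(t)
        if not (tmats[0].shape == tmats[1].shape == tmats[2].shape):
            raise ValueError("trait matrices must share one (n, q) shape")
        if tmats[0].shape[0] != n:
            raise ValueError("trait and genotype matrices disagree on family count")
        if tmats[0].shape[1] != self.trait_spec.q:
            raise ValueError("trait matrix width does not match the trait spec")
        for k, kind in enumerate(self.trait_spec.kinds):
            if kind in ("binary", "ordinal"):
                for t in tmats:
                    col = t[:, k]
                    if not np.all(col == np.round(col)):
                        raise ValueError(
                            f"trait {k} is declared {kind} but has non-integer values"
                        )

    @property
    def n(self) -> int:
        """Number of trio families."""
        return self.father_genotypes.shape[0]

    @property
    def m(self) -> int:
        """Number of loci."""
        return self.father_genotypes.shape[1]

    @property
    def q(self) -> int:
        """Number of traits per individual."""
        return self.trait_spec.q

    def genotypes(self, role: str) -> np.ndarray:
        return getattr(self, f"{role}_genotypes")

    def traits(self, role: str) -> np.ndarray:
        return getattr(self, f"{role}_traits")

    def subset_loci(self, index) -> "TrioCohort":
        """Return a cohort restricted to the given locus index/mask."""
        return TrioCohort(
            self.father_genotypes[:, index],
            self.mother_genotypes[:, index],
            self.child_genotypes[:, index],
            self.father_traits,
            self.mother_traits,
            self.child_traits,
            self.trait_spec,
        )

    def check_mendelian(self) -> np.ndarray:
        """Audit child genotypes for Mendelian consistency (warn-only).

        Returns a boolean (n, m) mask of inconsistent family/locus cells.
        The test statistic is computable regardless; the check exists because
        transmission errors usually indicate genotyping problems.
        """
        f, m, c = self.father_genotypes, self.mother_genotypes, self.child_genotypes
        lo = np.floor(f / 2) + np.floor(m / 2)  # min transmissible minor alleles
        hi = np.ceil(f / 2) + np.ceil(m / 2)
        bad = (c < lo) | (c > hi)
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning("%d family-locus cells are Mendelian-inconsistent", n_bad)
        return bad
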