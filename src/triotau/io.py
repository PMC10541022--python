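"""Readers and writers: PLINK-style PED/MAP trios, phenotype tables, results.

The on-disk formats are deliberately plain text.  Genotypes arrive as a
PED/MAP pair (six leading PED columns, two allele characters per locus,
missing allele "0"); the minor allele at each locus is determined from
founder allele frequencies, ties broken toward the smaller allele, and
genotypes are converted to minor-allele counts.  Phenotypes arrive as a TSV
with ``family_id``, ``individual_id`` and one column per trait.  Region test
results leave as a TSV mirroring the usual region / chi2 / df / p-value
table layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TraitSpec, TrioCohort
from .statistic import TestResult

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"


@dataclass
class PedigreeRecord:
    """One PED row after allele-to-count conversion."""

    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: str
    genotypes: np.ndarray  # minor-allele counts, NaN for missing

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass
class LocusMap:
    """MAP metadata (positions are metadata only; the test is position-free)."""

    chromosome: list[str]
    locus_id: list[str]
    position: list[int]

    @property
    def m(self) -> int:
        return len(self.locus_id)


def read_map(map_path) -> LocusMap:
    chrom, ids, pos = [], [], []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed MAP line: {line!r}")
        chrom.append(parts[0])
        ids.append(parts[1])
        pos.append(int(parts[-1]))
    return LocusMap(chrom, ids, pos)


def read_ped_map(ped_path, map_path) -> tuple[list[PedigreeRecord], LocusMap]:
    """Parse a PED/MAP pair into pedigree records with minor-allele counts.

    The minor allele per locus is the rarer allele among founders (ties go
    to the lexicographically smaller allele, logged); missing alleles ("0")
    become NaN counts handled downstream by :func:`assemble_trios`.
    """
    locus_map = read_map(map_path)
    m = locus_map.m
    raw: list[tuple[list[str], list[str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"PED line {ln}: expected {6 + 2 * m} fields for {m} loci, "
                f"got {len(parts)}"
            )
        raw.append((parts[:6], parts[6:]))

    # founder allele frequencies decide the minor allele per locus
    minor: list[str] = []
    for l in range(m):
        counts: dict[str, int] = {}
        for meta, alleles in raw:
            if not (meta[2] == "0" and meta[3] == "0"):
                continue
            for a in (alleles[2 * l], alleles[2 * l + 1]):
                if a != MISSING_ALLELE:
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            raise ValueError(f"locus {locus_map.locus_id[l]}: no founder alleles")
        if len(counts) > 2:
            raise ValueError(
                f"locus {locus_map.locus_id[l]}: more than two alleles {sorted(counts)}"
            )
        if len(counts) == 1:
            # only one allele observed: it is the major allele; the (unseen)
            # minor allele has count 0 for every individual
            minor.append(None)
            continue
        alleles_sorted = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if alleles_sorted[0][1] == alleles_sorted[1][1]:
            logger.info(
                "locus %s: allele frequency tie, minor set to %r",
                locus_map.locus_id[l], alleles_sorted[0][0],
            )
        minor.append(alleles_sorted[0][0])

    records = []
    for meta, alleles in raw:
        g = np.empty(m)
        for l in range(m):
            a1, a2 = alleles[2 * l], alleles[2 * l + 1]
            if MISSING_ALLELE in (a1, a2):
                g[l] = np.nan
            else:
                g[l] = (a1 == minor[l]) + (a2 == minor[l])
        records.append(PedigreeRecord(meta[0], meta[1], meta[2], meta[3], meta[4], g))
    return records, locus_map


def read_phenotypes(path, trait_spec: TraitSpec, trait_columns=None) -> pd.DataFrame:
    """Read the phenotype TSV, validate trait types, and index by IDs.

    The file needs a header with ``family_id`` and ``individual_id``;
    remaining columns (or ``trait_columns``, in order) are the q traits.
    Binary columns must be 0/1 integers, ordinal columns integers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str})
    for col in ("family_id", "individual_id"):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks required column {col!r}")
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c not in ("family_id", "individual_id")]
    if len(trait_columns) != trait_spec.q:
        raise ValueError(
            f"expected {trait_spec.q} trait columns, found {len(trait_columns)}"
        )
    for col, kind in zip(trait_columns, trait_spec.kinds):
        vals = df[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if kind in ("binary", "ordinal") and not np.all(finite == np.round(finite)):
            raise ValueError(f"trait column {col!r} declared {kind} but not integer")
        if kind == "binary" and finite.size and not np.isin(finite, (0, 1)).all():
            raise ValueError(f"trait column {col!r} declared binary but not 0/1")
    return df.set_index(["family_id", "individual_id"])[list(trait_columns)]


def assemble_trios(
    records: list[PedigreeRecord],
    phenotypes: pd.DataFrame,
    trait_spec: TraitSpec,
    drop_incomplete: bool = False,
    allow_multiple_children: bool = False,
) -> TrioCohort:
    """Join pedigree records and phenotypes into a :class:`TrioCohort`.

    Each family must contain two founders and a child referencing both.  A
    family with several children is an error unless ``allow_multiple_children``
    is set, in which case each child forms its own trio with the shared
    parents.  Families with missing genotypes or phenotypes raise unless
    ``drop_incomplete`` is set (dropped with a logged warning).
    """
    by_family: dict[str, list[PedigreeRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family_id, []).append(rec)

    extra = set(map(tuple, phenotypes.index)) - {
        (r.family_id, r.individual_id) for r in records
    }
    if extra:
        logger.warning("ignoring %d phenotype rows without genotypes", len(extra))

    def pheno(rec: PedigreeRecord) -> np.ndarray:
        key = (rec.family_id, rec.individual_id)
        if key not in phenotypes.index:
            raise KeyError(f"no phenotype row for individual {key}")
        return phenotypes.loc[key].to_numpy(dtype=float)

    gf, gm, gc, tf, tm, tc = [], [], [], [], [], []
    n_dropped = 0
    for fid in by_family:  # file order
        members = by_family[fid]
        founders = {r.individual_id: r for r in members if r.is_founder}
        children = [r for r in members if not r.is_founder]
        if not children:
            raise ValueError(f"family {fid}: no child record")
        if len(children) > 1 and not allow_multiple_children:
            raise ValueError(
                f"family {fid}: {len(children)} children; pass "
                "allow_multiple_children to treat each as its own trio"
            )
        for child in children:
            father = founders.get(child.father_id)
            mother = founders.get(child.mother_id)
            if father is None or mother is None:
                raise ValueError(
                    f"family {fid}: child {child.individual_id} references "
                    "missing parent(s)"
                )
            trio = (father, mother, child)
            try:
                traits = [pheno(r) for r in trio]
            except KeyError:
                if drop_incomplete:
                    n_dropped += 1
                    continue
                raise
            genos = [r.genotypes for r in trio]
            if any(np.isnan(g).any() for g in genos) or any(
                ~np.isfinite(t).all() for t in traits
            ):
                if drop_incomplete:
                    n_dropped += 1
                    continue
                raise ValueError(
                    f"family {fid}: missing genotype/trait values; pass "
                    "drop_incomplete to drop such trios"
                )
            gf.append(genos[0]); gm.append(genos[1]); gc.append(genos[2])
            tf.append(traits[0]); tm.append(traits[1]); tc.append(traits[2])
    if n_dropped:
        logger.warning("dropped %d incomplete trio(s)", n_dropped)
    if len(gf) < 2:
        raise ValueError("fewer than two complete trios; cannot test")
    return TrioCohort(
        np.asarray(gf), np.asarray(gm), np.asarray(gc),
        np.asarray(tf), np.asarray(tm), np.asarray(tc), trait_spec,
    )


def load_cohort(
    ped_path, map_path, pheno_path, trait_spec: TraitSpec, **kwargs
) -> TrioCohort:
    """Convenience: read PED/MAP + phenotypes and assemble the trio cohort."""
    records, _ = read_ped_map(ped_path, map_path)
    phenotypes = read_phenotypes(pheno_path, trait_spec)
    return assemble_trios(records, phenotypes, trait_spec, **kwargs)


def write_results(results: list[TestResult], path) -> None:
    """Write region test results as a TSV (chi2 and p to 4 decimals).

    Regions are written in genomic (start-locus) order regardless of the
    order they were computed in.
    """
    if not results:
        raise ValueError("no results to write")
    ordered = sorted(results, key=lambda r: (r.region or (0, 0)))
    with open(path, "w") as fh:
        fh.write("region\tchi2\tdf\tp_value\tn_loci\n")
        for res in ordered:
            reg = f"{res.region[0]}-{res.region[1]}" if res.region else "all"
            fh.write(
                f"{reg}\t{res.chi2:.4f}\t{res.df}\t{res.p_value:.4f}\t{res.n_loci_used}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic fixture generation

_FIXTURE_ALLELES = ("A", "C")  # (major, minor) as written


def write_cohort(cohort: TrioCohort, out_dir, prefix: str = "fixture") -> dict[str, Path]:
    """Serialize a cohort as PED/MAP/phenotype files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ped_path = out_dir / f"{prefix}.ped"
    map_path = out_dir / f"{prefix}.map"
    pheno_path = out_dir / f"{prefix}.pheno.tsv"
    major, minor = _FIXTURE_ALLELES

    def alleles(g: int) -> str:
        return {0: f"{major} {major}", 1: f"{major} {minor}", 2: f"{minor} {minor}"}[int(g)]

    with open(map_path, "w") as fh:
        for l in range(cohort.m):
            fh.write(f"1\trv{l + 1}\t0\t{(l + 1) * 1000}\n")
    with open(ped_path, "w") as fh, open(pheno_path, "w") as ph:
        ph.write(
            "family_id\tindividual_id\t"
            + "\t".join(f"trait{k + 1}" for k in range(cohort.q))
            + "\n"
        )
        for i in range(cohort.n):
            fid = f"F{i + 1}"
            members = (
                (f"{fid}_D", "0", "0", "1", cohort.father_genotypes[i], cohort.father_traits[i]),
                (f"{fid}_M", "0", "0", "2", cohort.mother_genotypes[i], cohort.mother_traits[i]),
                (f"{fid}_O", f"{fid}_D", f"{fid}_M", "1", cohort.child_genotypes[i], cohort.child_traits[i]),
            )
            for iid, pid, mid, sex, geno, traits in members:
                gstr = " ".join(alleles(g) for g in geno)
                fh.write(f"{fid} {iid} {pid} {mid} {sex} 0 {gstr}\n")
                tstr = "\t".join(repr(float(t)) for t in traits)
                ph.write(f"{fid}\t{iid}\t{tstr}\n")
    return {"ped": ped_path, "map": map_path, "pheno": pheno_path}


def make_fixture(
    seed: int, n: int, m: int, q: int, scheme: str, out_dir, prefix: str = "fixture"
) -> dict[str, Path]:
    """Generate a deterministic synthetic trio dataset on disk.

    A stand-in for restricted real trio data: simulates ``n`` trios at ``m``
    rare loci (MAF uniform in (0.03, 0.05)), builds ``q`` traits by cycling
    the scheme's trait kinds, and serializes through :func:`write_cohort` so
    end-to-end command-line runs need no external download.
    """
    from .simulate import SCHEMES, SimulationConfig, _simulate_cohort

    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    base_kinds, base_cuts = SCHEMES[scheme]
    pool = list(zip(base_kinds, base_cuts))
    if scheme == "mixed":
        pool.append(("quantitative", None))  # mixed fixtures cycle all kinds
    kinds = tuple(pool[k % len(pool)][0] for k in range(q))
    cuts = tuple(pool[k % len(pool)][1] for k in range(q))
    config = SimulationConfig(
        n_families=n,
        m_loci=m,
        scheme="custom",
        trait_kinds=kinds,
        cut_percentiles=cuts,
        betas=(0.0,) * q,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, 0)))
    cohort, _ = _simulate_cohort(config, rng)
    return write_cohort(cohort, out_dir, prefix=prefix)
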