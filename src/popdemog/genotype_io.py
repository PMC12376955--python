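"""Variant-matrix I/O and the RAD-seq filtering steps.

Genotypes are diploid, unphased, biallelic SNP calls stored as the number of
copies of the alternate allele (0, 1, 2) with ``MISSING = -1`` for no-calls.
Sites are grouped into RAD loci (short restriction-site-associated fragments);
the locus identifier is parsed from the VCF ID column (STACKS-style
``locus:column`` or ``locus_column``) and falls back to the CHROM field when
the ID is absent.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "VariantMatrix",
    "PopulationMap",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "read_q_matrix",
    "filter_missingness",
    "thin_one_snp_per_locus",
    "remove_admixed",
    "subset_population",
]


class VcfFormatError(ValueError):
    """Malformed VCF structure (header, columns)."""


class VcfContentError(ValueError):
    """VCF content outside the supported data model (e.g., multiallelic)."""


class EmptyResultError(ValueError):
    """A filter removed every sample or every site."""


@dataclasses.dataclass
class VariantMatrix:
    """Biallelic genotypes for samples x sites with RAD-locus grouping.

    Parameters
    ----------
    sample_ids :
        Sample identifiers, one per row.
    locus_ids :
        Per-site RAD-locus identifier (one per column).
    positions :
        Per-site ``(scaffold, 1-based position)`` pairs, strictly increasing
        within a scaffold.
    genotypes :
        ``(n_samples, n_sites)`` int8 array over ``{0, 1, 2, MISSING}``.
    monomorphic_flags :
        Optional boolean array marking sites that became monomorphic after a
        subsetting step (flagged, never silently removed).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    positions: list[tuple[str, int]]
    genotypes: np.ndarray
    monomorphic_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        ns, nv = self.genotypes.shape
        if ns != len(self.sample_ids):
            raise ValueError("sample_ids length does not match genotype rows")
        if nv != len(self.locus_ids) or nv != len(self.positions):
            raise ValueError("per-site metadata length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes outside {0, 1, 2, MISSING}")
        self._check_positions()

    def _check_positions(self) -> None:
        last: dict[str, int] = {}
        for chrom, pos in self.positions:
            if chrom in last and pos <= last[chrom]:
                raise ValueError(f"positions not strictly increasing on {chrom}")
            last[chrom] = pos

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def loci(self) -> list[str]:
        """Unique locus identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for lid in self.locus_ids:
            seen.setdefault(lid)
        return list(seen)

    def take_sites(self, idx: np.ndarray) -> "VariantMatrix":
        idx = np.asarray(idx)
        return VariantMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            positions=[self.positions[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            monomorphic_flags=None
            if self.monomorphic_flags is None
            else self.monomorphic_flags[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "VariantMatrix":
        idx = np.asarray(idx)
        return VariantMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            positions=list(self.positions),
            genotypes=self.genotypes[idx, :],
            monomorphic_flags=None
            if self.monomorphic_flags is None
            else self.monomorphic_flags.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and self.positions == other.positions
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclasses.dataclass
class PopulationMap:
    """Sample -> population assignment with an optional admixture Q matrix.

    ``q_matrix`` is a DataFrame indexed by sample with one column per
    population label; rows sum to 1 (STRUCTURE-style ancestry proportions).
    """

    assignments: dict[str, str]
    q_matrix: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.q_matrix is not None:
            sums = self.q_matrix.sum(axis=1).to_numpy(float)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("q_matrix rows must sum to 1 (±1e-6)")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == label]

    def validate_against(self, m: VariantMatrix) -> None:
        missing = sorted(set(self.assignments) - set(m.sample_ids))
        if missing:
            raise ValueError(f"mapped samples absent from matrix: {missing}")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _locus_from_id(vcf_id: str | None, chrom: str) -> str:
    if vcf_id is None or vcf_id in (".", ""):
        return chrom
    if ":" in vcf_id:
        return vcf_id.split(":", 1)[0]
    if "_" in vcf_id:
        return vcf_id.rsplit("_", 1)[0]
    return vcf_id


def read_vcf(path: str, strict: bool = True) -> VariantMatrix:
    """Read a VCF v4.x of biallelic SNPs into a :class:`VariantMatrix`.

    Locus identifiers come from the ID column (``locus:col`` / ``locus_col``
    dialects) or from CHROM when the ID is ``.``. ``./.`` genotypes map to
    :data:`MISSING`; phased separators are accepted and treated as unphased.

    With ``strict=True`` a record with more than two alleles raises
    :class:`VcfContentError`; otherwise such records are skipped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if strict:
                raise VcfContentError(
                    f"site {var.CHROM}:{var.POS} has {1 + len(var.ALT)} alleles"
                )
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        columns.append(col)
        locus_ids.append(_locus_from_id(var.ID, var.CHROM))
        positions.append((var.CHROM, var.POS))
    vcf.close()
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return VariantMatrix(samples, locus_ids, positions, geno)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(m: VariantMatrix, path: str) -> None:
    """Write a minimal GT-only VCF v4.2 (ID column = ``locus:column``)."""
    col_within: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popdemog\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(c for c, _ in m.positions):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        for j in range(m.n_sites):
            chrom, pos = m.positions[j]
            lid = m.locus_ids[j]
            col = col_within.get(lid, 0)
            col_within[lid] = col + 1
            gts = "\t".join(_GT_STR[int(g)] for g in m.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{lid}:{col}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_population_map(path: str, q_matrix_path: str | None = None) -> PopulationMap:
    """Read a 2-column TSV (sample, population) and optional Q-matrix TSV.

    The Q matrix TSV has a header of population labels and the sample id as
    first column.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    assignments = dict(zip(df["sample"], df["population"]))
    q = read_q_matrix(q_matrix_path) if q_matrix_path else None
    return PopulationMap(assignments, q)


def read_q_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_population_map(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in pm.assignments.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_missingness(
    m: VariantMatrix,
    locus_presence: float = 0.70,
    max_sample_missing: float = 0.50,
) -> VariantMatrix:
    """Apply the two-stage missingness filter: sites first, then samples.

    Stage 1 keeps sites called in at least ``locus_presence`` of the
    individuals (the POPULATIONS ``-r`` rule).  Stage 2 then removes
    individuals missing more than ``max_sample_missing`` of the remaining RAD
    loci, where a locus counts as missing for a sample only when every one of
    its sites is uncalled (allele dropout removes whole loci).
    """
    if not (0 < locus_presence <= 1):
        raise ValueError("locus_presence must be in (0, 1]")
    if not (0 <= max_sample_missing < 1):
        raise ValueError("max_sample_missing must be in [0, 1)")
    called = m.genotypes != MISSING
    frac_called = called.mean(axis=0)
    keep_sites = np.nonzero(frac_called >= locus_presence)[0]
    if keep_sites.size == 0:
        raise EmptyResultError(
            f"locus_presence={locus_presence} removed all {m.n_sites} sites"
        )
    m2 = m.take_sites(keep_sites)

    loci = m2.loci
    locus_index = {lid: i for i, lid in enumerate(loci)}
    site_locus = np.array([locus_index[lid] for lid in m2.locus_ids])
    called2 = m2.genotypes != MISSING
    # locus called for a sample if any of its sites is called
    locus_called = np.zeros((m2.n_samples, len(loci)), dtype=bool)
    for i in range(len(loci)):
        locus_called[:, i] = called2[:, site_locus == i].any(axis=1)
    miss_frac = 1.0 - locus_called.mean(axis=1)
    keep_samples = np.nonzero(miss_frac <= max_sample_missing)[0]
    if keep_samples.size == 0:
        raise EmptyResultError(
            f"max_sample_missing={max_sample_missing} removed all "
            f"{m2.n_samples} samples"
        )
    return m2.take_samples(keep_samples)


def thin_one_snp_per_locus(m: VariantMatrix, seed: int) -> VariantMatrix:
    """Keep exactly one uniformly chosen SNP per RAD locus (seeded).

    Mirrors the linkage-thinning step applied before structure analyses and
    SFS model fitting; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    by_locus: dict[str, list[int]] = {}
    for j, lid in enumerate(m.locus_ids):
        by_locus.setdefault(lid, []).append(j)
    keep = sorted(
        sites[rng.integers(len(sites))] if len(sites) > 1 else sites[0]
        for sites in by_locus.values()
    )
    return m.take_sites(np.array(keep))


def remove_admixed(pm: PopulationMap, threshold: float = 0.25) -> PopulationMap:
    """Drop samples with admixture proportion strictly above ``threshold``.

    The admixture proportion of a sample is the summed Q-matrix ancestry
    outside its assigned population; ties at the threshold are retained
    (the rule is strictly greater-than).
    """
    if pm.q_matrix is None:
        raise ValueError("remove_admixed requires a Q matrix")
    absent = sorted(set(pm.assignments) - set(pm.q_matrix.index))
    if absent:
        raise ValueError(f"samples absent from q_matrix: {absent}")
    kept: dict[str, str] = {}
    for sample, pop in pm.assignments.items():
        own = float(pm.q_matrix.loc[sample, pop]) if pop in pm.q_matrix.columns else 0.0
        if 1.0 - own > threshold:
            continue
        kept[sample] = pop
    q = pm.q_matrix.loc[[s for s in pm.q_matrix.index if s in kept]]
    return PopulationMap(kept, q)


def subset_population(
    m: VariantMatrix, pm: PopulationMap, label: str
) -> VariantMatrix:
    """Restrict rows to members of one population; flag new monomorphic sites.

    Columns are never removed: sites that become monomorphic after the subset
    are marked in ``monomorphic_flags`` so downstream spectra can account for
    them explicitly.
    """
    members = [s for s in pm.samples_in(label) if s in m.sample_ids]
    if not members:
        raise ValueError(f"population {label!r} has no members in the matrix")
    idx = np.array([m.sample_ids.index(s) for s in members])
    out = m.take_samples(idx)
    g = out.genotypes
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    out.monomorphic_flags = (alt == 0) | (alt == n_alleles)
    return out
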