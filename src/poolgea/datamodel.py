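"""Core domain types for Pool-Seq genome-environment association analysis.

The central observable is a matrix of pooled read counts: for every SNP and
every population, the number of sequencing reads carrying the reference and
the alternate allele.  Population allele frequencies are never observed
directly -- they are estimated from these counts, which is what makes the
hierarchical model downstream necessary.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive (GFF3/TAIR convention);
* the reference allele is the counted allele: ``frequency = ref / coverage``;
* cells with zero coverage are *missing*, not frequency zero;
* SNPs are sorted by (chromosome, position) with chromosomes in a declared
  order (default ``"1"`` .. ``"5"``), never lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_CHROM_ORDER: tuple[str, ...] = ("1", "2", "3", "4", "5")

#: annotation classes recognised by the enrichment machinery
ANNOTATION_CATEGORIES: tuple[str, ...] = (
    "intragenic",
    "intergenic",
    "UTR",
    "intron",
    "synonymous",
    "replacement",
    "other",
)


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


def _as_str_array(x: Sequence) -> np.ndarray:
    return np.asarray(x, dtype=object)


def chromosome_sort_key(chrom: np.ndarray, order: Sequence[str]) -> np.ndarray:
    """Map chromosome names to integer ranks in the declared order.

    Unknown chromosomes sort after the declared ones, alphabetically.
    """
    rank = {c: i for i, c in enumerate(order)}
    extras = sorted({c for c in chrom if c not in rank})
    for j, c in enumerate(extras):
        rank[c] = len(order) + j
    return np.array([rank[c] for c in chrom], dtype=np.int64)


@dataclass
class PoolSeqMatrix:
    """Per-SNP, per-population reference/alternate read counts.

    ``ref_count`` and ``alt_count`` are ``(n_snps, n_pops)`` non-negative
    integer arrays; their sum is the per-cell read coverage.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray
    pop_ids: list[str]
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER

    def __post_init__(self) -> None:
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.pop_ids = list(self.pop_ids)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n, j = self.ref_count.shape
        if self.alt_count.shape != (n, j):
            raise ValidationError("ref_count and alt_count shapes differ")
        if len(self.snp_ids) != n or len(self.chrom) != n or len(self.pos) != n:
            raise ValidationError("per-SNP metadata length mismatch")
        if len(self.pop_ids) != j:
            raise ValidationError(
                f"{len(self.pop_ids)} pop_ids for {j} count columns"
            )
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValidationError("negative read count")
        key = chromosome_sort_key(self.chrom, self.chrom_order)
        packed = key * (self.pos.max(initial=0) + 1) + self.pos
        if n > 1 and (np.diff(packed) <= 0).any():
            raise ValidationError(
                "SNPs must be sorted by (chrom, pos) without duplicates"
            )

    # -- derived quantities ---------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.ref_count.shape[0]

    @property
    def n_pops(self) -> int:
        return self.ref_count.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def frequency(self) -> np.ma.MaskedArray:
        """Reference-allele frequency; zero-coverage cells are masked."""
        cov = self.coverage
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(cov > 0, self.ref_count / np.maximum(cov, 1), np.nan)
        return np.ma.masked_invalid(f)

    # -- manipulation ----------------------------------------------------

    def take(self, idx: np.ndarray) -> "PoolSeqMatrix":
        """Row-subset by SNP index, preserving order of ``idx``."""
        idx = np.asarray(idx)
        return PoolSeqMatrix(
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_count=self.ref_count[idx],
            alt_count=self.alt_count[idx],
            pop_ids=self.pop_ids,
            chrom_order=self.chrom_order,
        )

    @staticmethod
    def sorted_from_arrays(
        snp_ids, chrom, pos, ref_count, alt_count, pop_ids,
        chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER,
    ) -> "PoolSeqMatrix":
        """Build a matrix, sorting rows into genome order first."""
        chrom = _as_str_array(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        key = chromosome_sort_key(chrom, chrom_order)
        order = np.lexsort((pos, key))
        return PoolSeqMatrix(
            snp_ids=_as_str_array(snp_ids)[order],
            chrom=chrom[order],
            pos=pos[order],
            ref_count=np.asarray(ref_count, dtype=np.int64)[order],
            alt_count=np.asarray(alt_count, dtype=np.int64)[order],
            pop_ids=pop_ids,
            chrom_order=chrom_order,
        )


@dataclass
class PopulationSet:
    """Sampled populations: pool sizes and (optional) coordinates.

    ``haploid_pool_size`` is twice the number of diploid plants pooled per
    population; it bounds the number of independent chromosomes a read can
    come from.
    """

    pop_ids: list[str]
    haploid_pool_size: np.ndarray
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pop_ids = list(self.pop_ids)
        self.haploid_pool_size = np.asarray(self.haploid_pool_size, dtype=np.int64)
        if len(self.haploid_pool_size) != len(self.pop_ids):
            raise ValidationError("pool size / pop id length mismatch")
        if (self.haploid_pool_size < 2).any():
            raise ValidationError("haploid pool size must be >= 2")
        for name in ("latitude", "longitude"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.pop_ids):
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)


@dataclass
class CovariateSet:
    """Population-level covariates (e.g. climate variables).

    ``values`` is (n_pops, n_covariates).  When ``standardized`` is set,
    every column has mean 0 and standard deviation 1 (n-1 denominator).
    """

    names: list[str]
    values: np.ndarray
    pop_ids: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValidationError("covariate name / column mismatch")
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if np.abs(mu).max() > 1e-10 or np.abs(sd - 1).max() > 1e-10:
                raise ValidationError("standardized flag set but columns are not")

    @property
    def n_pops(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class AnnotationTable:
    """One functional-annotation category per SNP."""

    snp_ids: np.ndarray
    category: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _as_str_array(self.snp_ids)
        self.category = _as_str_array(self.category)
        if len(self.snp_ids) != len(self.category):
            raise ValidationError("annotation length mismatch")
        bad = set(self.category) - set(ANNOTATION_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown annotation categories: {sorted(bad)}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP id in annotation table")

    def proportions(self) -> dict[str, float]:
        vals, counts = np.unique(self.category.astype(str), return_counts=True)
        return {v: c / len(self.category) for v, c in zip(vals, counts)}


@dataclass
class GeneModels:
    """Gene spans (1-based inclusive) used for candidate-region overlap."""

    gene_id: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    chrom: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    start: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    end: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    strand: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.gene_id = _as_str_array(self.gene_id)
        self.chrom = _as_str_array(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = _as_str_array(self.strand)
        if (self.start > self.end).any():
            raise ValidationError("gene with start > end")

    def __len__(self) -> int:
        return len(self.gene_id)
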