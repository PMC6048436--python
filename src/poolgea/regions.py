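"""Candidate-region calling from top-associated SNPs.

Three steps: take the k SNPs with the highest Bayes factor per covariate,
call regions as maximal runs of at least ``min_snps`` top SNPs whose
successive positions are less than ``max_gap_bp`` apart (strict), then
report every annotated gene whose span intersects a region.  Coordinates
are 1-based inclusive; region length is reported as end - start in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GeneModels, ValidationError
from .model.aux import AuxScanResult


@dataclass
class CandidateRegion:
    covariates: list[str]
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("region end before start")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def select_top_snps(scan: AuxScanResult, k: int) -> np.ndarray:
    """Indices of the k SNPs with the highest Bayes factor.

    Ties are broken by genome order; k may equal the number of SNPs.
    """
    if k > scan.n_snps:
        raise ValidationError(f"k={k} exceeds {scan.n_snps} SNPs")
    order = np.lexsort((np.arange(scan.n_snps), -scan.bf_db))
    return np.sort(order[:k])


def call_regions(
    chrom: np.ndarray,
    pos: np.ndarray,
    snp_ids: np.ndarray,
    covariate: str = "covariate",
    min_snps: int = 3,
    max_gap_bp: int = 10_000,
) -> list[CandidateRegion]:
    """Group top SNPs into candidate regions.

    A region is a maximal run of SNPs on one chromosome with successive
    gaps strictly below ``max_gap_bp``, kept only if it holds at least
    ``min_snps`` SNPs.  The region span is [min pos, max pos] of its
    supporting SNPs.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    snp_ids = np.asarray(snp_ids, dtype=object)
    regions: list[CandidateRegion] = []
    for c in _unique_keep_order(chrom):
        sel = chrom == c
        p = pos[sel]
        ids = snp_ids[sel]
        order = np.argsort(p, kind="stable")
        p, ids = p[order], ids[order]
        run_start = 0
        for i in range(1, len(p) + 1):
            if i == len(p) or p[i] - p[i - 1] >= max_gap_bp:
                if i - run_start >= min_snps:
                    regions.append(
                        CandidateRegion(
                            covariates=[covariate],
                            chrom=str(c),
                            start=int(p[run_start]),
                            end=int(p[i - 1]),
                            snp_ids=list(ids[run_start:i]),
                        )
                    )
                run_start = i
    return regions


def regions_from_scan(
    scan: AuxScanResult,
    k: int = 50,
    min_snps: int = 3,
    max_gap_bp: int = 10_000,
) -> list[CandidateRegion]:
    """Top-k selection and region calling in one step."""
    idx = select_top_snps(scan, k)
    return call_regions(
        scan.chrom[idx],
        scan.pos[idx],
        scan.snp_ids[idx],
        covariate=scan.covariate_name,
        min_snps=min_snps,
        max_gap_bp=max_gap_bp,
    )


def merge_regions_across_variables(
    per_variable: list[list[CandidateRegion]],
) -> list[CandidateRegion]:
    """Merge overlapping regions found for different covariates.

    Any base-pair overlap on the same chromosome merges regions into one
    record whose span is the union and whose covariate list collects all
    supporting variables.  Disjoint regions pass through unchanged.
    """
    flat = [r for regions in per_variable for r in regions]
    flat.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: list[CandidateRegion] = []
    for r in flat:
        if (
            merged
            and merged[-1].chrom == r.chrom
            and r.start <= merged[-1].end
        ):
            last = merged[-1]
            last.end = max(last.end, r.end)
            last.covariates = sorted(set(last.covariates) | set(r.covariates))
            last.snp_ids = list(dict.fromkeys(last.snp_ids + r.snp_ids))
        else:
            merged.append(
                CandidateRegion(
                    covariates=list(r.covariates),
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    snp_ids=list(r.snp_ids),
                    gene_ids=list(r.gene_ids),
                )
            )
    return merged


def annotate_regions(
    regions: list[CandidateRegion], genes: GeneModels
) -> list[CandidateRegion]:
    """Attach every gene whose 1-based inclusive span intersects a region."""
    import warnings

    known_chroms = set(genes.chrom.tolist())
    for r in regions:
        if r.chrom not in known_chroms:
            warnings.warn(
                f"chromosome {r.chrom!r} absent from gene models",
                stacklevel=2,
            )
            r.gene_ids = []
            continue
        hit = (
            (genes.chrom == r.chrom)
            & (genes.start <= r.end)
            & (genes.end >= r.start)
        )
        r.gene_ids = list(genes.gene_id[hit])
    return regions


def _unique_keep_order(values: np.ndarray) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)
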