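"""Post-calling SNP filter cascade for pooled read-count matrices.

Five steps, applied strictly in order (a SNP is removed at the first step
it fails), each targeting a distinct artifact of Pool-Seq data:

1. too many populations without mapped reads (uninformative SNPs);
2. mean relative coverage too high (collapsed paralogs: several gene
   copies mapping to one reference position);
3. allele-frequency standard deviation too low (uninformative,
   quasi-constant sites);
4. mean relative coverage too low (reference-specific regions absent
   from most sampled genomes);
5. monomorphic within too many populations (rare alleles, which bias
   association scans).

Relative coverage is a SNP's coverage divided by the median coverage of
its population; frequency statistics use populations with non-zero
coverage only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import PoolSeqMatrix, ValidationError


@dataclass
class FilterParams:
    """Thresholds of the five-step cascade.

    Defaults follow common Pool-Seq practice for a ~170-population design:
    drop SNPs unmapped in >= 8 populations, mean relative coverage above
    1.5 or below 0.5, frequency standard deviation below 0.004, and
    monomorphic in more than 90% of populations.  When
    ``scale_zero_coverage`` is set, the >= 8-population rule is rescaled
    to the same fraction (8/168) of however many populations are present.
    """

    max_zero_coverage_pops: int = 8
    max_mean_rel_cov: float = 1.5
    min_sd_freq: float = 0.004
    min_mean_rel_cov: float = 0.5
    max_monomorphic_fraction: float = 0.90
    scale_zero_coverage: bool = False
    reference_n_pops: int = 168

    def __post_init__(self) -> None:
        if not 0 < self.min_mean_rel_cov < self.max_mean_rel_cov:
            raise ValidationError(
                "need 0 < min_mean_rel_cov < max_mean_rel_cov"
            )
        for name in ("min_sd_freq", "min_mean_rel_cov", "max_monomorphic_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def zero_coverage_limit(self, n_pops: int) -> int:
        if not self.scale_zero_coverage:
            return self.max_zero_coverage_pops
        frac = self.max_zero_coverage_pops / self.reference_n_pops
        return max(1, int(round(frac * n_pops)))

    @classmethod
    def disabled(cls) -> "FilterParams":
        """Thresholds that let every SNP through (identity cascade)."""
        return cls(
            max_zero_coverage_pops=10**9,
            max_mean_rel_cov=np.inf,
            min_sd_freq=0.0,
            min_mean_rel_cov=1e-300,
            max_monomorphic_fraction=1.0,
        )


@dataclass
class FilterReport:
    """Per-step audit: (step name, SNPs removed, SNPs remaining)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][2]:
            raise ValidationError("remaining count may not increase")
        self.steps.append((name, removed, remaining))

    @property
    def removals(self) -> tuple[int, ...]:
        return tuple(s[1] for s in self.steps)

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_tsv(self) -> str:
        lines = ["step\tn_removed\tn_remaining"]
        lines += [f"{n}\t{r}\t{k}" for n, r, k in self.steps]
        return "\n".join(lines) + "\n"


STEP_NAMES = (
    "zero_coverage_pops",
    "high_mean_rel_cov",
    "low_sd_freq",
    "low_mean_rel_cov",
    "monomorphic_fraction",
)


def relative_coverage(matrix: PoolSeqMatrix) -> np.ndarray:
    """Coverage of each cell divided by its population's median coverage.

    The median is taken over all SNPs of the population.  A population
    whose coverage is zero at every SNP has no meaningful median and is
    reported as an error.
    """
    cov = matrix.coverage.astype(float)
    med = np.median(cov, axis=0)
    dead = np.where(med == 0)[0]
    if dead.size:
        all_zero = [matrix.pop_ids[j] for j in dead if cov[:, j].max() == 0]
        if all_zero:
            raise ValidationError(
                f"population(s) with all-zero coverage: {all_zero}"
            )
        # median zero but some coverage present: fall back to the mean of
        # the covered SNPs so the ratio stays defined
        for j in dead:
            med[j] = cov[cov[:, j] > 0, j].mean()
    return cov / med[None, :]


def apply_filter_cascade(
    matrix: PoolSeqMatrix, params: FilterParams | None = None
) -> tuple[PoolSeqMatrix, FilterReport]:
    """Run the five-step cascade and report removals per step.

    Statistics for each step are computed on the SNPs that survived the
    previous steps (medians included), mirroring a sequential re-filtering
    of a shrinking data set.
    """
    if matrix.n_snps == 0:
        raise ValidationError("empty matrix")
    params = params or FilterParams()
    report = FilterReport()
    current = matrix

    # step 1: populations without mapped reads
    limit = params.zero_coverage_limit(current.n_pops)
    n_zero = (current.coverage == 0).sum(axis=1)
    keep = n_zero < limit
    current = current.take(np.where(keep)[0])
    report.add(STEP_NAMES[0], int((~keep).sum()), current.n_snps)

    # step 2: mean relative coverage above threshold
    rel = relative_coverage(current)
    keep = rel.mean(axis=1) <= params.max_mean_rel_cov
    current = current.take(np.where(keep)[0])
    report.add(STEP_NAMES[1], int((~keep).sum()), current.n_snps)

    # step 3: allele-frequency standard deviation below threshold
    sd = _freq_sd(current)
    keep = sd >= params.min_sd_freq
    current = current.take(np.where(keep)[0])
    report.add(STEP_NAMES[2], int((~keep).sum()), current.n_snps)

    # step 4: mean relative coverage below threshold
    rel = relative_coverage(current)
    keep = rel.mean(axis=1) >= params.min_mean_rel_cov
    current = current.take(np.where(keep)[0])
    report.add(STEP_NAMES[3], int((~keep).sum()), current.n_snps)

    # step 5: monomorphic in more than the allowed fraction of populations
    mono_frac = _monomorphic_fraction(current)
    keep = mono_frac <= params.max_monomorphic_fraction
    current = current.take(np.where(keep)[0])
    report.add(STEP_NAMES[4], int((~keep).sum()), current.n_snps)

    return current, report


def _freq_sd(matrix: PoolSeqMatrix) -> np.ndarray:
    """Per-SNP sd of reference-allele frequency over covered populations.

    Uses the n-1 denominator; SNPs covered in fewer than two populations
    get sd 0 (they carry no frequency variation to measure).
    """
    cov = matrix.coverage
    covered = cov > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(covered, matrix.ref_count / np.maximum(cov, 1), np.nan)
    n = covered.sum(axis=1)
    mean = np.nansum(f, axis=1) / np.maximum(n, 1)
    ss = np.nansum((f - mean[:, None]) ** 2, axis=1)
    sd = np.sqrt(ss / np.maximum(n - 1, 1))
    sd[n < 2] = 0.0
    return sd


def _monomorphic_fraction(matrix: PoolSeqMatrix) -> np.ndarray:
    """Fraction of covered populations where the SNP is fixed (freq 0 or 1)."""
    cov = matrix.coverage
    covered = cov > 0
    fixed = covered & (
        (matrix.ref_count == cov) | (matrix.alt_count == cov)
    )
    n = covered.sum(axis=1)
    return fixed.sum(axis=1) / np.maximum(n, 1)
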