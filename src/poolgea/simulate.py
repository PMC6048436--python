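"""Synthetic Pool-Seq data with the statistical structure the model assumes.

The generator mirrors the inference model itself, so every downstream stage
can be exercised and calibrated without any external data:

* across-population frequencies pi ~ Beta(a, b) with a minor-allele-
  frequency floor (defaults a = 2.78, b = 0.710, floor 0.01, matching the
  shape of real pooled SNP data);
* population frequency vectors drawn from N(pi * 1 + beta * z, pi(1-pi) *
  Omega), clipped to [0, 1] (clipping events are counted, not rejected);
* binomial sampling of pool allele counts at the haploid pool sizes, then
  binomial read sampling at the configured coverages (default constant
  25x, near empirical Pool-Seq means);
* a chosen number of "associated" SNPs whose mean frequency shifts with a
  standardized covariate z at regression coefficient ``beta_effect``
  (default 0.1) on the natural frequency scale.

Covariates are built with a controlled Spearman correlation to the leading
eigenvector of Omega, emulating environmental variables that are partially
confounded with population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    ANNOTATION_CATEGORIES,
    AnnotationTable,
    CovariateSet,
    PoolSeqMatrix,
    PopulationSet,
    ValidationError,
)
from .model.core import OmegaMatrix, omega_from_spec

#: genome-wide annotation-category proportions typical of a compact plant
#: genome (replacement/synonymous/intron/UTR/intergenic/intragenic)
DEFAULT_CATEGORY_PROPORTIONS: dict[str, float] = {
    "replacement": 0.082,
    "synonymous": 0.091,
    "intron": 0.149,
    "UTR": 0.056,
    "intergenic": 0.491,
    "intragenic": 0.115,
}


class ConvergenceError(RuntimeError):
    """An iterative construction failed to reach its target; the best
    achieved value is reported in the message."""


@dataclass
class SimConfig:
    """Parameters of a simulated Pool-Seq dataset."""

    n_pops: int = 32
    n_snps: int = 10_000
    n_assoc: int = 100
    beta_effect: float = 0.1
    beta_shape_a: float = 2.78
    beta_shape_b: float = 0.710
    maf_floor: float = 0.01
    omega_spec: object = "identity"
    pool_sizes: np.ndarray | int = 32
    coverage_model: object = 25          # int (fixed) or vector to resample
    n_chromosomes: int = 5
    snp_spacing_bp: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_assoc <= self.n_snps:
            raise ValidationError("need 0 <= n_assoc <= n_snps")
        if not 0 <= self.maf_floor < 0.5:
            raise ValidationError("maf_floor must be in [0, 0.5)")

    def omega(self) -> OmegaMatrix:
        return omega_from_spec(self.omega_spec, self.n_pops)

    def pool_size_vector(self) -> np.ndarray:
        if np.isscalar(self.pool_sizes):
            return np.full(self.n_pops, int(self.pool_sizes), dtype=np.int64)
        v = np.asarray(self.pool_sizes, dtype=np.int64)
        if len(v) != self.n_pops:
            raise ValidationError("pool_sizes length must equal n_pops")
        return v


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset: which SNPs carry the effect."""

    associated_snp_ids: np.ndarray
    beta_true: np.ndarray
    covariate_target_rho: float | None = None
    achieved_rho: float | None = None
    n_clipped: int = 0
    pi_true: np.ndarray | None = None   # generating across-population freqs

    def truth_mask(self, snp_ids: np.ndarray) -> np.ndarray:
        assoc = set(self.associated_snp_ids.tolist())
        return np.array([s in assoc for s in snp_ids], dtype=bool)


# ---------------------------------------------------------------------------
# covariate with controlled correlation to the leading Omega axis
# ---------------------------------------------------------------------------

def simulate_pc_correlated_covariate(
    omega: OmegaMatrix,
    target_rho: float,
    n_pops: int | None = None,
    seed: int | None = None,
    tolerance: float = 0.02,
    max_iter: int = 200,
) -> tuple[CovariateSet, float]:
    """Simulate a standardized covariate with a target Spearman correlation
    to the first eigenvector of Omega.

    The construction mixes the leading eigenvector with independent
    Gaussian noise, ``z(w) = w * u1 + (1 - w) * g``, and tunes the mixing
    weight by bisection until the empirical Spearman correlation is within
    ``tolerance`` of the target; fresh noise is drawn if a given g cannot
    reach the target.  Returns the covariate (mean 0, sd 1) and the
    achieved correlation.

    For small population counts the rank correlation is discrete with
    grid spacing 12/(J^3 - J); the effective tolerance is widened to that
    spacing when it exceeds the requested one.
    """
    if not 0.0 <= target_rho < 1.0:
        raise ValidationError("target_rho must be in [0, 1)")
    j = omega.n_pops
    if n_pops is not None and n_pops != j:
        raise ValidationError("n_pops does not match omega dimension")
    rng = np.random.default_rng(seed)
    tolerance = max(tolerance, 12.0 / (j**3 - j))
    u1 = omega.eigenvectors[:, 0]
    u1 = (u1 - u1.mean()) / max(u1.std(), 1e-12)

    def rho_of(z: np.ndarray) -> float:
        return float(stats.spearmanr(z, u1).statistic)

    best_z, best_rho = None, np.inf
    for _ in range(max_iter):
        g = rng.standard_normal(j)
        if target_rho == 0.0:
            z = g
            r = rho_of(z)
            if abs(r) <= tolerance:
                return _finish_covariate(z, r)
        else:
            lo, hi = 0.0, 1.0
            z, r = g, rho_of(g)
            for _ in range(60):
                w = 0.5 * (lo + hi)
                z = w * u1 + (1.0 - w) * g
                r = rho_of(z)
                if abs(r - target_rho) <= 0.25 * tolerance:
                    break
                if r < target_rho:
                    lo = w
                else:
                    hi = w
            if abs(r - target_rho) <= tolerance:
                return _finish_covariate(z, r)
        if abs(r - target_rho) < abs(best_rho - target_rho):
            best_z, best_rho = z, r
    raise ConvergenceError(
        f"could not reach Spearman rho {target_rho:.3f} within "
        f"{tolerance:.3f} after {max_iter} attempts; best achieved "
        f"{best_rho:.3f}"
    )


def _finish_covariate(z: np.ndarray, achieved: float) -> tuple[CovariateSet, float]:
    zs = (z - z.mean()) / z.std(ddof=1)
    cov = CovariateSet(names=["covariate"], values=zs[:, None], standardized=True)
    return cov, achieved


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig,
    covariate: CovariateSet | None = None,
    seed: int | None = None,
) -> tuple[PoolSeqMatrix, PopulationSet, SimTruth]:
    """Simulate a Pool-Seq read-count dataset under the inference model.

    Identical ``(config, covariate, seed)`` gives bit-identical output.
    The seed argument overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, j = config.n_snps, config.n_pops
    omega = config.omega()
    if config.n_assoc > 0 and covariate is None:
        raise ValidationError("associated SNPs requested but no covariate given")
    z = None
    if covariate is not None:
        if covariate.n_pops != j:
            raise ValidationError("covariate length must equal n_pops")
        z = covariate.values[:, 0]
        if not covariate.standardized:
            z = (z - z.mean()) / z.std(ddof=1)

    # across-population frequencies: truncated Beta
    pi = _truncated_beta(
        rng, config.beta_shape_a, config.beta_shape_b, config.maf_floor, n
    )

    # population frequencies: MVN around pi (plus effect), clipped to [0,1]
    chol = np.linalg.cholesky(omega.omega)
    g = rng.standard_normal((n, j))
    alpha = pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * (g @ chol.T)
    assoc_idx = np.sort(rng.choice(n, size=config.n_assoc, replace=False))
    if config.n_assoc:
        alpha[assoc_idx] += config.beta_effect * z[None, :]
    n_clipped = int(((alpha < 0) | (alpha > 1)).sum())
    np.clip(alpha, 0.0, 1.0, out=alpha)

    # pool sampling then read sampling
    pool = config.pool_size_vector()
    x = rng.binomial(pool[None, :], alpha)
    coverage = _draw_coverage(rng, config.coverage_model, (n, j))
    ref = rng.binomial(coverage, x / pool[None, :])
    alt = coverage - ref

    snp_ids, chrom, pos = _genome_layout(n, config.n_chromosomes, config.snp_spacing_bp)
    matrix = PoolSeqMatrix(
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        ref_count=ref,
        alt_count=alt,
        pop_ids=[f"pop{i + 1}" for i in range(j)],
    )
    pops = PopulationSet(pop_ids=matrix.pop_ids, haploid_pool_size=pool)
    truth = SimTruth(
        associated_snp_ids=snp_ids[assoc_idx],
        beta_true=np.full(config.n_assoc, config.beta_effect),
        n_clipped=n_clipped,
        pi_true=pi,
    )
    if n_clipped > 0.25 * alpha.size:
        warnings.warn(
            f"{n_clipped} of {alpha.size} simulated frequencies were "
            "clipped at [0, 1]",
            stacklevel=2,
        )
    return matrix, pops, truth


def _truncated_beta(rng, a: float, b: float, maf: float, n: int) -> np.ndarray:
    """Beta(a, b) draws conditioned on min(pi, 1-pi) >= maf."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(a, b, size=max(n - filled, 64))
        ok = draw[(draw >= maf) & (draw <= 1 - maf)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _draw_coverage(rng, model, shape) -> np.ndarray:
    if np.isscalar(model):
        return np.full(shape, int(model), dtype=np.int64)
    vec = np.asarray(model, dtype=np.int64)
    return rng.choice(vec, size=shape, replace=True)


def _genome_layout(n: int, n_chrom: int, spacing: int):
    """Spread n SNPs evenly over chromosomes at fixed bp spacing."""
    per = [n // n_chrom + (1 if k < n % n_chrom else 0) for k in range(n_chrom)]
    chrom = np.concatenate(
        [np.full(c, str(k + 1), dtype=object) for k, c in enumerate(per)]
    ) if n else np.array([], dtype=object)
    pos = np.concatenate(
        [1 + spacing * np.arange(c, dtype=np.int64) for c in per]
    ) if n else np.array([], dtype=np.int64)
    snp_ids = np.array(
        [f"{c}_{p}" for c, p in zip(chrom, pos)], dtype=object
    )
    return snp_ids, chrom, pos


# ---------------------------------------------------------------------------
# annotation fixture
# ---------------------------------------------------------------------------

def simulate_annotation_table(
    snp_ids,
    category_proportions: dict[str, float] | None = None,
    planted_enrichment: tuple[str, np.ndarray, float] | None = None,
    seed: int | None = None,
) -> AnnotationTable:
    """Draw one annotation category per SNP.

    ``planted_enrichment = (category, snp_subset_ids, factor)`` multiplies
    the probability of ``category`` by ``factor`` within the subset
    (renormalizing the rest), to create a known enrichment signal.
    Proportions may sum to less than 1; the remainder goes to ``other``.
    """
    props = dict(category_proportions or DEFAULT_CATEGORY_PROPORTIONS)
    unknown = set(props) - set(ANNOTATION_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown category name(s): {sorted(unknown)}")
    total = sum(props.values())
    if total > 1 + 1e-9:
        raise ValidationError("category proportions sum above 1")
    props.setdefault("other", 0.0)
    props["other"] += max(0.0, 1.0 - total)

    snp_ids = np.asarray(snp_ids, dtype=object)
    rng = np.random.default_rng(seed)
    cats = list(props)
    p = np.array([props[c] for c in cats])
    p = p / p.sum()
    codes = rng.choice(len(cats), size=len(snp_ids), p=p)

    if planted_enrichment is not None:
        cat, subset, factor = planted_enrichment
        if cat not in cats:
            raise ValidationError(f"unknown category name: {cat!r}")
        k = cats.index(cat)
        boosted = p.copy()
        boosted[k] = min(p[k] * factor, 1.0)
        rest = 1.0 - boosted[k]
        others = np.delete(np.arange(len(cats)), k)
        boosted[others] = p[others] / p[others].sum() * rest
        in_subset = np.isin(snp_ids, np.asarray(subset, dtype=object))
        codes[in_subset] = rng.choice(len(cats), size=int(in_subset.sum()), p=boosted)

    category = np.array([cats[c] for c in codes], dtype=object)
    return AnnotationTable(snp_ids=snp_ids, category=category)
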