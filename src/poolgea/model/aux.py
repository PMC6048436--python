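"""AUX-model genome-environment association scan.

Population allele frequencies are regressed on a standardized covariate
under the shared covariance Omega; a binary auxiliary indicator delta_i
switches each SNP's regression coefficient beta_i on or off
(spike-and-slab).  The posterior mean of delta_i is the posterior inclusion
probability (PIP); the support for association is reported as a Bayes
factor in deciban, 10 * log10(posterior odds / prior odds), where the prior
odds come from the posterior mean of the shared inclusion probability P.
Integrating over P makes the scan self-adjusting for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datamodel import CovariateSet, PoolSeqMatrix, PopulationSet, ValidationError
from .core import MCMCSettings, OmegaMatrix
from .sampler import PoolSeqGibbsSampler


@dataclass
class AuxScanResult:
    """Per-SNP association summaries for one covariate."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray          # posterior mean of delta_i * beta_i
    bf_db: np.ndarray         # Bayes factor, deciban
    xtx: np.ndarray
    pip: np.ndarray
    covariate_name: str = "covariate"
    subset_id: np.ndarray | None = None
    max_bf_db: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("chrom", "pos", "beta", "bf_db", "xtx", "pip"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length mismatch")
        if np.any((self.pip < 0) | (self.pip > 1)):
            raise ValidationError("pip must lie in [0, 1]")
        if not np.all(np.isfinite(self.bf_db)):
            raise ValidationError("bf_db must be finite (capping rule)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "snp_id": self.snp_ids,
                "beta": self.beta,
                "bf_db": self.bf_db,
                "xtx": self.xtx,
                "pip": self.pip,
            }
        )


def standardize_covariate(values, name: str = "covariate") -> CovariateSet:
    """Center and scale to unit standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float).ravel()
    if len(np.unique(v)) < 2:
        raise ValidationError("cannot standardize a constant covariate")
    out = (v - v.mean()) / v.std(ddof=1)
    return CovariateSet(names=[name], values=out[:, None], standardized=True)


def _pip_to_bf_db(pip: np.ndarray, p_mean: float, n_samples: int):
    """Posterior-odds / prior-odds conversion with finite-sample capping.

    PIP estimated from S retained draws is clamped to
    [1/(2S), 1 - 1/(2S)] so the deciban scale stays finite; the implied
    maximum reportable value is returned alongside.
    """
    eps = 1.0 / (2.0 * n_samples)
    pip_c = np.clip(pip, eps, 1.0 - eps)
    p = min(max(p_mean, eps), 1.0 - eps)
    post_odds = pip_c / (1.0 - pip_c)
    prior_odds = p / (1.0 - p)
    bf_db = 10.0 * np.log10(post_odds / prior_odds)
    max_db = 10.0 * np.log10(((1 - eps) / eps) / prior_odds)
    return bf_db, max_db


def run_aux_scan(
    matrix: PoolSeqMatrix,
    pops: PopulationSet,
    omega: OmegaMatrix,
    covariate: CovariateSet,
    mcmc_settings: MCMCSettings | None = None,
    seed: int | None = None,
    *,
    covariate_name: str | None = None,
    beta_a: float = 2.78,
    beta_b: float = 0.710,
    maf_floor: float = 0.01,
    beta_bound: float = 0.3,
    force_inclusion: bool = False,
) -> AuxScanResult:
    """Scan every SNP for association with one standardized covariate.

    Omega is held fixed (it comes from a core-model run on the same data,
    or is the generating matrix in simulation studies); the sampler
    estimates (delta_i, beta_i) per SNP and the shared inclusion
    probability P.  With ``force_inclusion`` every delta is pinned to 1,
    giving the standard covariate model (beta estimated for every SNP;
    the Bayes factors are then meaningless and reported at their cap).
    """
    if matrix.pop_ids != pops.pop_ids:
        raise ValidationError("population ids of matrix and PopulationSet differ")
    if omega.n_pops != matrix.n_pops:
        raise ValidationError("omega dimension does not match population count")
    if not covariate.standardized:
        raise ValidationError("covariate must be standardized (mean 0, sd 1)")
    if covariate.n_pops != matrix.n_pops:
        raise ValidationError("covariate length does not match population count")
    name = covariate_name or covariate.names[0]
    z = covariate.column(name) if covariate_name else covariate.values[:, 0]

    settings = mcmc_settings or MCMCSettings()
    sampler = PoolSeqGibbsSampler(
        matrix.ref_count,
        matrix.coverage,
        pops.haploid_pool_size,
        omega=omega.omega,
        covariate=z,
        beta_a=beta_a,
        beta_b=beta_b,
        maf_floor=maf_floor,
        beta_bound=beta_bound,
        force_inclusion=force_inclusion,
        settings=settings,
        seed=seed,
    )
    res = sampler.run()
    bf_db, max_db = _pip_to_bf_db(res.pip, res.p_mean, settings.n_samples)
    xtx = res.xtx
    return AuxScanResult(
        snp_ids=matrix.snp_ids,
        chrom=matrix.chrom,
        pos=matrix.pos,
        beta=res.beta_hat,
        bf_db=bf_db,
        xtx=xtx,
        pip=res.pip,
        covariate_name=name,
        max_bf_db=max_db,
        seed=seed,
    )


def merge_scan_outputs(results: list[AuxScanResult]) -> AuxScanResult:
    """Concatenate per-subset scans into one genome-ordered result.

    Subsets must be disjoint and share the covariate; provenance is kept
    in ``subset_id``.
    """
    if not results:
        raise ValueError("no scan results to merge")
    names = {r.covariate_name for r in results}
    if len(names) > 1:
        raise ValidationError(f"results mix covariates: {sorted(names)}")
    ids = np.concatenate([r.snp_ids for r in results])
    if len(set(ids)) != len(ids):
        raise ValidationError("overlapping SNP ids across subsets")
    chrom = np.concatenate([r.chrom for r in results])
    pos = np.concatenate([r.pos for r in results])
    subset = np.concatenate(
        [np.full(r.n_snps, k, dtype=np.int64) for k, r in enumerate(results)]
    )
    from ..datamodel import DEFAULT_CHROM_ORDER, chromosome_sort_key

    key = chromosome_sort_key(chrom, DEFAULT_CHROM_ORDER)
    order = np.lexsort((pos, key))
    return AuxScanResult(
        snp_ids=ids[order],
        chrom=chrom[order],
        pos=pos[order],
        beta=np.concatenate([r.beta for r in results])[order],
        bf_db=np.concatenate([r.bf_db for r in results])[order],
        xtx=np.concatenate([r.xtx for r in results])[order],
        pip=np.concatenate([r.pip for r in results])[order],
        covariate_name=results[0].covariate_name,
        subset_id=subset[order],
        max_bf_db=results[0].max_bf_db,
    )
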