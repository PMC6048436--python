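"""Core hierarchical model: Omega estimation, FMD distances, SVD, XtX.

The scaled covariance matrix Omega of population allele frequencies is the
model's population-structure correction: it absorbs shared demographic
history (drift, gene flow) so that per-SNP statistics can be judged against
a structure-aware null.  XtX -- the variance of the Omega-standardized
population allele frequencies -- is the resulting differentiation statistic,
with neutral expectation close to the number of populations J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ..datamodel import PoolSeqMatrix, PopulationSet, ValidationError
from .sampler import MCMCSettings, PoolSeqGibbsSampler, SamplerResult


@dataclass
class OmegaMatrix:
    """A J x J symmetric positive-definite scaled covariance matrix.

    Eigenvectors (columns, by decreasing eigenvalue) are the genomic
    principal axes ("PC_genomic"); the first one is the leading axis of
    population structure.
    """

    omega: np.ndarray
    source_subset_id: int | None = None
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.omega, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("omega must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValidationError("omega must be symmetric")
        self.omega = 0.5 * (m + m.T)
        w, v = linalg.eigh(self.omega)
        if w.min() <= 0:
            raise ValidationError("omega must be positive definite")
        order = np.argsort(w)[::-1]
        self.eigenvalues = w[order]
        self.eigenvectors = v[:, order]

    @property
    def n_pops(self) -> int:
        return self.omega.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        lam = linalg.inv(self.omega)
        return 0.5 * (lam + lam.T)

    # -- constructors ---------------------------------------------------

    @classmethod
    def identity(cls, n_pops: int) -> "OmegaMatrix":
        return cls(np.eye(n_pops))

    @classmethod
    def compound_symmetry(cls, n_pops: int, rho: float) -> "OmegaMatrix":
        if not -1.0 / (n_pops - 1) < rho < 1.0:
            raise ValidationError("compound-symmetry rho out of range")
        m = np.full((n_pops, n_pops), rho)
        np.fill_diagonal(m, 1.0)
        return cls(m)

    @classmethod
    def block(cls, block_sizes: list[int], rho: float) -> "OmegaMatrix":
        """Block-diagonal compound symmetry (discrete population groups)."""
        mats = []
        for s in block_sizes:
            m = np.full((s, s), rho)
            np.fill_diagonal(m, 1.0)
            mats.append(m)
        return cls(linalg.block_diag(*mats))

    @classmethod
    def spiked(cls, n_pops: int, pc1_fraction: float) -> "OmegaMatrix":
        """A single dominant structure axis over an isotropic floor.

        ``Omega = a I + b u u^T`` with ``u`` a smooth unit-norm gradient
        across populations, normalized to trace J so total drift variance
        matches the identity case; ``pc1_fraction`` is the share of
        variance carried by the leading axis.
        """
        j = n_pops
        if not 1.0 / j < pc1_fraction < 1.0:
            raise ValidationError("pc1_fraction must be in (1/J, 1)")
        u = np.linspace(-1.0, 1.0, j)
        u = u / np.linalg.norm(u)
        a = j * (1 - pc1_fraction) / (j - 1)
        b = j * pc1_fraction - a
        return cls(a * np.eye(j) + b * np.outer(u, u))


def omega_from_spec(spec, n_pops: int) -> OmegaMatrix:
    """Build an OmegaMatrix from a compact specification.

    Accepted forms: ``"identity"``, ``("cs", rho)``, ``("block", sizes,
    rho)``, ``("spiked", pc1_fraction)``, a raw square array, or an
    OmegaMatrix (passed through).
    """
    if isinstance(spec, OmegaMatrix):
        if spec.n_pops != n_pops:
            raise ValidationError("omega dimension does not match n_pops")
        return spec
    if isinstance(spec, str):
        if spec == "identity":
            return OmegaMatrix.identity(n_pops)
        raise ValidationError(f"unknown omega spec {spec!r}")
    if isinstance(spec, tuple):
        kind = spec[0]
        if kind == "cs":
            return OmegaMatrix.compound_symmetry(n_pops, spec[1])
        if kind == "block":
            om = OmegaMatrix.block(spec[1], spec[2])
            if om.n_pops != n_pops:
                raise ValidationError("block sizes do not sum to n_pops")
            return om
        if kind == "spiked":
            return OmegaMatrix.spiked(n_pops, spec[1])
        raise ValidationError(f"unknown omega spec kind {kind!r}")
    return OmegaMatrix(np.asarray(spec, dtype=float))


@dataclass
class CoreModelPosterior:
    """Posterior summaries from a core-model run."""

    pi_mean: np.ndarray
    alpha_mean: np.ndarray
    m2: np.ndarray                   # (N, J, J) E[abar abar^T | data]
    xtx: np.ndarray
    snp_ids: np.ndarray
    acceptance: dict[str, float]
    ess: float
    settings: MCMCSettings
    seed: int | None
    #: one posterior draw of the XtX quadratic form; unlike the posterior
    #: mean it is chi-square(J)-distributed under a calibrated model
    xtx_single_draw: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return len(self.pi_mean)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def subsample_snps(matrix: PoolSeqMatrix, n_subsets: int) -> list[PoolSeqMatrix]:
    """Partition SNPs into interleaved subsets along the genome.

    Subset k holds the SNPs at genome-order indices k, k + n, k + 2n, ...
    Interleaving keeps every subset representative of the whole genome, so
    each yields an exchangeable estimate of Omega.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if n_subsets > matrix.n_snps:
        raise ValueError(
            f"n_subsets={n_subsets} exceeds the {matrix.n_snps} available SNPs"
        )
    return [
        matrix.take(np.arange(k, matrix.n_snps, n_subsets))
        for k in range(n_subsets)
    ]


def fmd_distance(a, b) -> float:
    """Forstner-Moonen metric between covariance matrices.

    The square root of the sum of squared log generalized eigenvalues of
    (a, b); zero iff a equals b, symmetric in its arguments.
    """
    ma = a.omega if isinstance(a, OmegaMatrix) else np.asarray(a, float)
    mb = b.omega if isinstance(b, OmegaMatrix) else np.asarray(b, float)
    if ma.shape != mb.shape:
        raise ValidationError("FMD distance requires equal dimensions")
    w = linalg.eigh(mb, ma, eigvals_only=True)
    if np.any(w <= 0):
        raise ValidationError("FMD distance requires positive definite inputs")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def omega_svd(omega: OmegaMatrix):
    """Eigenvalues, axes and variance fractions of Omega (decreasing)."""
    frac = omega.eigenvalues / omega.eigenvalues.sum()
    return omega.eigenvalues, omega.eigenvectors, frac


def compute_xtx(posterior: CoreModelPosterior, omega: OmegaMatrix) -> np.ndarray:
    """Posterior-mean XtX per SNP under a given Omega.

    XtX_i = E[ abar_i^T Omega^-1 abar_i | data ] = tr(Omega^-1 M2_i) where
    M2_i is the posterior second moment of the standardized deviations.
    """
    lam = omega.inverse
    if posterior.m2.shape[1] != lam.shape[0]:
        raise ValidationError("posterior and omega dimensions differ")
    return np.einsum("njk,jk->n", posterior.m2, lam)


def estimate_core_model(
    matrix: PoolSeqMatrix,
    pops: PopulationSet,
    mcmc_settings: MCMCSettings | None = None,
    seed: int | None = None,
    *,
    beta_a: float = 2.78,
    beta_b: float = 0.710,
    maf_floor: float = 0.01,
    source_subset_id: int | None = None,
) -> tuple[CoreModelPosterior, OmegaMatrix]:
    """Fit the core model (no covariate) and estimate Omega.

    Returns the posterior summaries (including XtX computed against the
    posterior-mean Omega) and the posterior-mean OmegaMatrix.
    """
    if matrix.n_pops < 3:
        raise ValidationError("core model requires at least 3 populations")
    if matrix.pop_ids != pops.pop_ids:
        raise ValidationError("population ids of matrix and PopulationSet differ")
    sampler = PoolSeqGibbsSampler(
        matrix.ref_count,
        matrix.coverage,
        pops.haploid_pool_size,
        omega=None,
        covariate=None,
        beta_a=beta_a,
        beta_b=beta_b,
        maf_floor=maf_floor,
        settings=mcmc_settings or MCMCSettings(),
        seed=seed,
    )
    res: SamplerResult = sampler.run()
    omega_hat = OmegaMatrix(res.omega_mean, source_subset_id=source_subset_id)
    posterior = CoreModelPosterior(
        pi_mean=res.pi_mean,
        alpha_mean=res.alpha_mean,
        m2=res.m2,
        xtx=np.empty(0),
        snp_ids=matrix.snp_ids,
        acceptance=res.acceptance,
        ess=res.ess,
        settings=res.settings,
        seed=seed,
        xtx_single_draw=res.xtx_single_draw,
    )
    posterior.xtx = compute_xtx(posterior, omega_hat)
    return posterior, omega_hat
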