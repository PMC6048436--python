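"""Metropolis-within-Gibbs sampler for the hierarchical Pool-Seq model.

The generative model, per SNP i and population j (J populations):

    pi_i        ~ Beta(a, b) truncated to [maf, 1 - maf]
    alpha_i     ~ N( pi_i * 1 + delta_i * beta_i * z ,
                     pi_i (1 - pi_i) * Omega )     latent, unbounded
    x_ij        ~ Binomial(n_j, clip(alpha_ij, 0, 1))   pool allele count
    y_ij        ~ Binomial(c_ij, x_ij / n_j)            reference read count

Omega is the scaled covariance of population allele frequencies, n_j the
haploid pool size, c_ij the read coverage, and the optional covariate term
(delta_i, beta_i, z) is the spike-and-slab association component switched
on in "aux" mode.

Alpha is a *latent Gaussian* frequency: only its clipped value enters the
binomial sampling layer, exactly as in the data generator.  Keeping alpha
unbounded makes the inverse-Wishart update of Omega exact and avoids the
attenuation of Omega that a boundary-truncated parametrization suffers
when many frequencies sit at fixation.

Update moves (one sweep):

* ``x``      -- +-1 random walk with table-lookup log ratios; periodically
               replaced by an independence draw from the binomial prior
               given alpha, which reseeds cells with little read
               information (e.g. zero coverage).
* ``alpha``  -- population by population, proposing from the conditional
               Gaussian prior given the other populations, so the
               Metropolis ratio is the pool-binomial likelihood ratio only
               (evaluated at the clipped value).
* ``pi``     -- per-SNP random walk with reflection at the maf bounds;
               proposal widths are tuned during pilot runs to a 25-45%
               acceptance window.
* ``delta, beta`` (aux) -- delta by Gibbs with beta integrated against its
               uniform prior in closed form; beta, when included, from its
               conjugate truncated-normal conditional.
* ``P``      -- conjugate Beta update of the shared inclusion probability.
* ``Omega`` (core) -- conjugate inverse-Wishart update on the standardized
               residuals, prior IW(I, J + 2).

Retained draws accumulate posterior means of pi, alpha, delta, delta*beta
and the per-SNP second-moment matrix of standardized deviations
``abar = (alpha - pi) / sqrt(pi (1 - pi))``, from which XtX is a trace.

Internally all SNP x population arrays are held population-major (J, N)
so that per-population vector operations touch contiguous memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import gammaln, log_ndtr, ndtr, ndtri
from scipy.stats import invwishart

_ALPHA_EPS = 1e-6


def moment_initial_omega(
    f: np.ndarray,
    pool_size: np.ndarray,
    coverage: np.ndarray,
    beta_a: float,
    beta_b: float,
    eig_floor: float = 0.02,
) -> np.ndarray:
    """Method-of-moments starting value for Omega.

    The per-SNP mean frequency pi and the shared drift component along the
    all-ones direction are confounded in the likelihood, so a chain started
    at Omega = I tends to absorb shared drift into pi and never discover
    the ones-direction variance.  The moment estimator separates them using
    the known Beta(a, b) prior variance of pi:

    * structure orthogonal to 1 comes from row-mean-centered standardized
      frequencies (minus binomial sampling noise on the diagonal);
    * the ones-direction variance is the excess variance of SNP row means
      over the Beta prior variance and sampling noise;
    * the cross terms come from the covariance of row means with the
      centered residuals.

    ``f`` is (n_snps, n_pops) observed frequencies.
    """
    n, j = f.shape
    m = f.mean(axis=1)
    s2 = np.clip(m * (1 - m), 1e-4, None)
    sig = np.sqrt(s2)
    u = (f - m[:, None]) / sig[:, None]
    A = (u.T @ u) / n
    # binomial noise of observed frequencies, in standardized units
    d = (1.0 / pool_size[None, :] + 1.0 / np.maximum(coverage, 1)).mean(axis=0)
    P = np.eye(j) - np.full((j, j), 1.0 / j)
    A = A - P @ np.diag(d) @ P
    var_pi = beta_a * beta_b / ((beta_a + beta_b) ** 2 * (beta_a + beta_b + 1.0))
    es2 = float(s2.mean())
    var_m = float(m.var())
    noise_m = es2 * float(d.sum()) / j**2
    c1 = max((var_m - var_pi - noise_m) * j**2 / es2, 0.05 * j)
    w = ((m - m.mean())[:, None] * u).mean(axis=0)
    q = P @ (w / sig.mean())
    ones = np.ones(j)
    omega = A + np.outer(q, ones) + np.outer(ones, q) + (c1 / j**2) * np.ones((j, j))
    omega = 0.5 * (omega + omega.T)
    vals, vecs = np.linalg.eigh(omega)
    vals = np.clip(vals, eig_floor, None)
    return (vecs * vals) @ vecs.T


@dataclass
class MCMCSettings:
    """Chain-length and tuning parameters.

    Defaults mirror the conventions of Pool-Seq GEA software: 15 pilot
    runs of 500 sweeps for proposal tuning, 2,500 burn-in sweeps, then
    1,000 retained samples thinned by 20.
    """

    n_pilot: int = 15
    pilot_length: int = 500
    burn_in: int = 2500
    n_samples: int = 1000
    thin: int = 20
    ess_floor: float = 50.0

    @classmethod
    def quick(cls) -> "MCMCSettings":
        """Desk-scale settings for simulation studies and tests."""
        return cls(n_pilot=4, pilot_length=100, burn_in=400, n_samples=400, thin=2)

    @classmethod
    def rapid(cls) -> "MCMCSettings":
        """Minimal settings for replicated power studies."""
        return cls(n_pilot=2, pilot_length=60, burn_in=250, n_samples=250, thin=1)

    @property
    def total_sweeps(self) -> int:
        return (
            self.n_pilot * self.pilot_length
            + self.burn_in
            + self.n_samples * self.thin
        )


@dataclass
class SamplerResult:
    pi_mean: np.ndarray
    alpha_mean: np.ndarray          # (N, J)
    m2: np.ndarray | None           # (N, J, J) posterior mean of abar abar^T
    xtx: np.ndarray | None          # direct posterior-mean XtX (aux mode)
    xtx_single_draw: np.ndarray | None          # calibration diagnostic
    omega_mean: np.ndarray
    pip: np.ndarray | None
    beta_hat: np.ndarray | None
    p_mean: float | None
    n_retained: int
    acceptance: dict[str, float]
    ess: float
    settings: MCMCSettings = field(repr=False, default_factory=MCMCSettings)
    seed: int | None = None


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangular wrap)."""
    span = hi - lo
    t = np.mod(v - lo, 2.0 * span)
    return lo + np.where(t > span, 2.0 * span - t, t)


def _ess_from_trace(trace: np.ndarray) -> float:
    """Effective sample size of a scalar chain (initial positive sequence)."""
    n = len(trace)
    if n < 10 or np.var(trace) == 0:
        return float(n)
    x = trace - trace.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


class PoolSeqGibbsSampler:
    """One sampler serves both the core model and the AUX association model.

    Parameters
    ----------
    ref, cov : (N, J) int arrays
        Reference read counts and total coverage.
    pool_size : (J,) int array
        Haploid pool sizes.
    omega : (J, J) array or None
        Fixed scaled covariance (aux mode); when None the sampler
        estimates Omega by conjugate updates (core mode).
    covariate : (J,) array or None
        Standardized covariate; switches on the spike-and-slab component.
    """

    def __init__(
        self,
        ref: np.ndarray,
        cov: np.ndarray,
        pool_size: np.ndarray,
        *,
        omega: np.ndarray | None = None,
        covariate: np.ndarray | None = None,
        beta_a: float = 2.78,
        beta_b: float = 0.710,
        maf_floor: float = 0.01,
        beta_bound: float = 0.3,
        force_inclusion: bool = False,
        settings: MCMCSettings | None = None,
        seed: int | None = None,
    ) -> None:
        # population-major storage
        self.y = np.ascontiguousarray(np.asarray(ref, dtype=np.int64).T)
        self.c = np.ascontiguousarray(np.asarray(cov, dtype=np.int64).T)
        self.n = np.asarray(pool_size, dtype=np.int64)
        self.J, self.N = self.y.shape
        if len(self.n) != self.J:
            raise ValueError("pool_size length does not match count matrix")
        self.a, self.b = float(beta_a), float(beta_b)
        self.maf = float(maf_floor)
        self.B = float(beta_bound)
        self.settings = settings or MCMCSettings()
        self.seed = seed
        self.rng = np.random.default_rng(seed)

        self.estimate_omega = omega is None
        self.omega = np.eye(self.J) if omega is None else np.array(omega, dtype=float)
        self.z = None if covariate is None else np.asarray(covariate, dtype=float)
        self.aux = self.z is not None
        # force_inclusion switches off the spike: delta = 1 for every SNP
        # and P stays fixed, reducing the sampler to the standard
        # (non-spike-and-slab) covariate model
        self.force_inclusion = bool(force_inclusion)

        self._init_state()
        if self.estimate_omega and self.N >= 10 * self.J:
            with np.errstate(invalid="ignore"):
                f = np.where(self.c > 0, (self.y + 0.5) / (self.c + 1.0), 0.5)
            self.omega = moment_initial_omega(
                f.T, self.n.astype(float), self.c.T, self.a, self.b
            )
        self._set_lambda(self.omega)

    # ------------------------------------------------------------------

    def _init_state(self) -> None:
        y, c, n = self.y, self.c, self.n
        with np.errstate(invalid="ignore"):
            f = np.where(c > 0, (y + 0.5) / (c + 1.0), 0.5)
        self.alpha = np.ascontiguousarray(f.astype(float))
        lo = (y > 0).astype(np.int64)
        hi = n[:, None] - (y < c).astype(np.int64)
        self.x = np.clip(np.rint(self.alpha * n[:, None]).astype(np.int64), lo, hi)
        self.pi = np.clip(self.alpha.mean(axis=0), self.maf, 1 - self.maf)
        self.sig2 = self.pi * (1 - self.pi)
        self.delta = np.zeros(self.N, dtype=bool)
        self.beta = np.zeros(self.N)
        self.P = 0.01
        self.pi_width = np.full(self.N, 0.1)
        self.R = self.alpha - self.pi[None, :]  # deviations from prior mean
        self._acc = {"x": [0, 0], "alpha": [0, 0], "pi": [0, 0]}
        self._sweep_count = 0
        kmax = int(max(self.n.max(), self.c.max())) + 1
        with np.errstate(divide="ignore"):
            self._logtable = np.log(np.arange(kmax + 1, dtype=float))
        self._gammaln_table = gammaln(np.arange(kmax + 2, dtype=float) + 1.0)

    def _set_lambda(self, omega: np.ndarray) -> None:
        self.omega = omega
        self.lam = linalg.inv(omega)
        self.lam = 0.5 * (self.lam + self.lam.T)
        self.lam1 = self.lam.sum(axis=1)
        self.s11 = float(self.lam1.sum())
        if self.aux:
            self.lamz = self.lam @ self.z
            self.zz = float(self.z @ self.lamz)

    def _clip01(self, a: np.ndarray) -> np.ndarray:
        return np.clip(a, _ALPHA_EPS, 1 - _ALPHA_EPS)

    def _lchoose(self, n, k):
        lg = self._gammaln_table
        return lg[n] - lg[k] - lg[n - k]

    # -- update moves ---------------------------------------------------

    def _update_x(self, refresh: bool = False) -> None:
        y, c = self.y, self.c
        n = self.n[:, None]
        ac = self._clip01(self.alpha)
        if refresh:
            xp = self.rng.binomial(n, ac)
        else:
            xp = self.x + self.rng.integers(0, 2, size=self.x.shape) * 2 - 1
            np.clip(xp, 0, n, out=xp)
        lt = self._logtable
        rem = c - y
        # read-likelihood ratio (present in both move types)
        logr = np.where(y > 0, y * (lt[xp] - lt[self.x]), 0.0) + np.where(
            rem > 0, rem * (lt[n - xp] - lt[n - self.x]), 0.0
        )
        if not refresh:
            # random walk: include the binomial prior ratio for x
            logr += (xp - self.x) * (np.log(ac) - np.log1p(-ac))
            logr += self._lchoose(n, xp) - self._lchoose(n, self.x)
        bad = ((y > 0) & (xp == 0)) | ((rem > 0) & (xp == n))
        logr = np.where(bad, -np.inf, logr)
        acc = np.log(self.rng.random(size=logr.shape)) < logr
        self.x = np.where(acc, xp, self.x)
        self._acc["x"][0] += int(acc.sum())
        self._acc["x"][1] += acc.size

    def _update_alpha(self) -> None:
        sd_base = np.sqrt(self.sig2)
        noise = self.rng.standard_normal((self.J, self.N))
        logu = np.log(self.rng.random((self.J, self.N)))
        alpha, R, x = self.alpha, self.R, self.x
        for j in range(self.J):
            ljj = self.lam[j, j]
            u = self.lam[j] @ R
            prop = alpha[j] - u / ljj + (sd_base / np.sqrt(ljj)) * noise[j]
            pc = self._clip01(prop)
            ac = self._clip01(alpha[j])
            xj = x[j]
            logr = xj * np.log(pc / ac) + (self.n[j] - xj) * np.log(
                (1.0 - pc) / (1.0 - ac)
            )
            acc = logu[j] < logr
            da = np.where(acc, prop - alpha[j], 0.0)
            alpha[j] += da
            R[j] += da
            self._acc["alpha"][0] += int(acc.sum())
            self._acc["alpha"][1] += self.N

    def _update_pi(self) -> np.ndarray:
        lamR1 = self.lam1 @ self.R
        q = np.einsum("ji,ji->i", self.lam @ self.R, self.R)
        prop = _reflect(
            self.pi + self.pi_width * self.rng.standard_normal(self.N),
            self.maf,
            1 - self.maf,
        )
        d = self.pi - prop
        qp = q + 2.0 * d * lamR1 + d * d * self.s11
        s2p = prop * (1 - prop)
        logr = (
            (self.a - 1) * (np.log(prop) - np.log(self.pi))
            + (self.b - 1) * (np.log1p(-prop) - np.log1p(-self.pi))
            - 0.5 * self.J * (np.log(s2p) - np.log(self.sig2))
            - 0.5 * qp / s2p
            + 0.5 * q / self.sig2
        )
        acc = np.log(self.rng.random(self.N)) < logr
        self.pi = np.where(acc, prop, self.pi)
        self.sig2 = self.pi * (1 - self.pi)
        self.R += np.where(acc, d, 0.0)[None, :]
        self._acc["pi"][0] += int(acc.sum())
        self._acc["pi"][1] += self.N
        return acc

    def _update_delta_beta(self) -> None:
        B = self.B
        db = self.delta * self.beta
        e = self.R + self.z[:, None] * db[None, :]   # alpha - pi, (J, N)
        bvec = self.lamz @ e
        v = self.sig2 / self.zz
        s = np.sqrt(v)
        m = bvec / self.zz
        hi, lo = (B - m) / s, (-B - m) / s
        l_hi, l_lo = log_ndtr(hi), log_ndtr(lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_diff = l_hi + np.log1p(-np.exp(np.minimum(l_lo - l_hi, -1e-12)))
        lbf = (
            0.5 * np.log(2.0 * np.pi * v)
            - np.log(2.0 * B)
            + 0.5 * m * m / v
            + log_diff
        )
        if self.force_inclusion:
            self.delta = np.ones(self.N, dtype=bool)
        else:
            logit_p = np.log(self.P) - np.log1p(-self.P)
            p1 = 1.0 / (1.0 + np.exp(-(logit_p + lbf)))
            self.delta = self.rng.random(self.N) < p1
        self.beta.fill(0.0)
        idx = np.nonzero(self.delta)[0]
        if idx.size:
            fa, fb = ndtr(lo[idx]), ndtr(hi[idx])
            width = np.maximum(fb - fa, 1e-300)
            u = fa + self.rng.random(idx.size) * width
            bdraw = m[idx] + s[idx] * ndtri(np.clip(u, 1e-300, 1 - 1e-16))
            self.beta[idx] = np.clip(bdraw, -B, B)
        db = self.delta * self.beta
        self.R = e - self.z[:, None] * db[None, :]
        if not self.force_inclusion:
            k = int(self.delta.sum())
            self.P = self.rng.beta(1 + k, 1 + self.N - k)

    def _update_omega(self) -> None:
        estd = self.R / np.sqrt(self.sig2)[None, :]
        scale = np.eye(self.J) + estd @ estd.T
        draw = invwishart.rvs(
            df=self.J + 2 + self.N, scale=scale, random_state=self.rng
        )
        draw = 0.5 * (draw + draw.T)
        self._set_lambda(draw)

    def _sweep(self) -> None:
        self._sweep_count += 1
        self._update_x(refresh=self._sweep_count % 10 == 0)
        self._update_alpha()
        self._update_pi()
        if self.aux:
            self._update_delta_beta()
        if self.estimate_omega:
            self._update_omega()

    # ------------------------------------------------------------------

    def run(self) -> SamplerResult:
        st = self.settings
        # pilot runs: tune the pi random-walk widths
        for _ in range(st.n_pilot):
            acc_count = np.zeros(self.N)
            for _ in range(st.pilot_length):
                self._sweep_count += 1
                self._update_x(refresh=self._sweep_count % 10 == 0)
                self._update_alpha()
                acc_count += self._update_pi()
                if self.aux:
                    self._update_delta_beta()
                if self.estimate_omega:
                    self._update_omega()
            rate = acc_count / max(st.pilot_length, 1)
            self.pi_width *= np.where(
                rate > 0.45, 1.4, np.where(rate < 0.25, 0.7, 1.0)
            )
            np.clip(self.pi_width, 1e-3, 0.5, out=self.pi_width)
        for k in self._acc:
            self._acc[k] = [0, 0]

        for _ in range(st.burn_in):
            self._sweep()

        sum_pi = np.zeros(self.N)
        sum_alpha = np.zeros((self.J, self.N))
        # in aux mode Omega is fixed, so XtX can be accumulated directly;
        # core mode keeps the full second-moment tensor for compute_xtx
        m2 = None if self.aux else np.zeros((self.N, self.J, self.J))
        xtx_sum = np.zeros(self.N) if self.aux else None
        sum_delta = np.zeros(self.N)
        sum_db = np.zeros(self.N)
        sum_p = 0.0
        omega_sum = np.zeros((self.J, self.J))
        trace = np.empty(st.n_samples)

        for it in range(st.n_samples):
            for _ in range(st.thin):
                self._sweep()
            sum_pi += self.pi
            sum_alpha += self.alpha
            dev = self.R
            if self.aux:
                db = self.delta * self.beta
                dev = self.R + self.z[:, None] * db[None, :]
            abar = dev / np.sqrt(self.sig2)[None, :]
            if it == st.n_samples - 1:
                # one posterior draw of the quadratic form: unlike the
                # posterior mean, its marginal distribution matches the
                # chi-square(J) reference when the model is calibrated
                xtx_draw = np.einsum("ji,ji->i", self.lam @ abar, abar)
            if self.aux:
                xtx_sum += np.einsum("ji,ji->i", self.lam @ abar, abar)
                sum_delta += self.delta
                sum_db += self.delta * self.beta
                sum_p += self.P
            else:
                m2 += np.einsum("ji,ki->ijk", abar, abar)
            omega_sum += self.omega
            trace[it] = float(self.pi.mean())

        S = st.n_samples
        ess = _ess_from_trace(trace)
        if ess < st.ess_floor:
            warnings.warn(
                f"effective sample size {ess:.1f} below floor "
                f"{st.ess_floor:.0f}; consider longer chains",
                stacklevel=2,
            )
        acc = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in self._acc.items()}
        return SamplerResult(
            pi_mean=sum_pi / S,
            alpha_mean=(sum_alpha / S).T,
            m2=None if m2 is None else m2 / S,
            xtx=None if xtx_sum is None else xtx_sum / S,
            xtx_single_draw=xtx_draw,
            omega_mean=omega_sum / S,
            pip=sum_delta / S if self.aux else None,
            beta_hat=sum_db / S if self.aux else None,
            p_mean=sum_p / S if self.aux else None,
            n_retained=S,
            acceptance=acc,
            ess=ess,
            settings=st,
            seed=self.seed,
        )
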