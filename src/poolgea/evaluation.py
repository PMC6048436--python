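"""Power-study harness: TPR/FPR/FDR, ROC and precision-recall curves.

Definitions used throughout (scores are association evidence, truth the
planted-SNP labels):

* TPR (power): true positives / truly associated SNPs;
* FPR: false positives / non-associated SNPs;
* FDR: false positives / SNPs called associated (0, flagged, when
  nothing is called);
* ROC curve: TPR against FPR over a sweep of score thresholds;
* PR curve: precision (1 - FDR) against TPR over the same sweep.

Areas under both curves use the trapezoid rule on the achieved-threshold
grid.  The full power study simulates covariates at a grid of Spearman
correlations with the leading axis of population structure, plants
associated SNPs, scans with the generating Omega, and pools replicate
scores before the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ValidationError
from .model.aux import run_aux_scan
from .model.sampler import MCMCSettings
from .simulate import SimConfig, simulate_dataset, simulate_pc_correlated_covariate


@dataclass
class RocPrCurves:
    """Rates over a descending-threshold sweep, with areas under curves."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    fdr: np.ndarray
    roc_auc: float
    pr_auc: float
    n_replicates: int = 1
    rho_level: float | None = None

    def __post_init__(self) -> None:
        for name in ("tpr", "fpr"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValidationError(f"{name} outside [0, 1]")
            if np.any(np.diff(v) < -1e-12):
                raise ValidationError(f"{name} must be monotone along the sweep")
        if not (0 <= self.roc_auc <= 1 and 0 <= self.pr_auc <= 1):
            raise ValidationError("AUCs must lie in [0, 1]")


def confusion_at_threshold(
    scores: np.ndarray, truth: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(TPR, FPR, FDR) when calling every SNP with score >= threshold.

    FDR is reported as 0.0 when nothing is called (undefined by its
    ratio); callers needing the flag can test ``called == 0`` themselves.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth must align")
    pos = int(truth.sum())
    neg = len(truth) - pos
    if pos == 0:
        raise ValidationError("TPR undefined: no positives in truth")
    called = scores >= threshold
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    tpr = tp / pos
    fpr = fp / neg if neg else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return tpr, fpr, fdr


def roc_pr_curves(
    scores: np.ndarray,
    truth: np.ndarray,
    n_replicates: int = 1,
    rho_level: float | None = None,
) -> RocPrCurves:
    """Full threshold sweep with trapezoid AUCs.

    Tied scores enter the sweep as one step, which makes the trapezoid
    ROC area identical to the Mann-Whitney U statistic normalization
    (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = int(truth.sum())
    neg = len(truth) - pos
    if pos == 0 or neg == 0:
        raise ValidationError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    # one sweep step per distinct score
    distinct = np.nonzero(np.diff(s_sorted))[0]
    step_ends = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp = np.cumsum(t_sorted)[step_ends]
    calls = step_ends + 1
    fp = calls - tp
    tpr = tp / pos
    fpr = fp / neg
    fdr = fp / calls
    thresholds = s_sorted[step_ends]
    roc_auc = float(
        np.trapezoid(np.concatenate([[0.0], tpr, [1.0]]),
                     np.concatenate([[0.0], fpr, [1.0]]))
    )
    precision = 1.0 - fdr
    pr_auc = float(
        np.trapezoid(np.concatenate([[precision[0]], precision]),
                     np.concatenate([[0.0], tpr]))
    )
    return RocPrCurves(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        fdr=fdr,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        n_replicates=n_replicates,
        rho_level=rho_level,
    )


@dataclass
class PowerStudyResult:
    curves: dict[float, RocPrCurves] = field(default_factory=dict)
    achieved_rho: dict[float, list[float]] = field(default_factory=dict)
    config: SimConfig | None = None

    def auc_table(self) -> list[tuple[float, float, float]]:
        return [
            (rho, c.roc_auc, c.pr_auc) for rho, c in sorted(self.curves.items())
        ]


def power_study(
    rho_levels=(0.0, 0.5, 0.9),
    n_replicates: int = 5,
    config: SimConfig | None = None,
    mcmc_settings: MCMCSettings | None = None,
    seed: int = 0,
) -> PowerStudyResult:
    """Replicated AUX-scan power study across structure-correlation levels.

    For each Spearman level rho and replicate r: simulate a covariate with
    correlation rho to the leading axis of Omega, simulate a dataset with
    planted effects, scan under the AUX model with the *generating* Omega,
    and pool replicate scores per rho before computing the curves.

    Replicate datasets share their Gaussian field across rho levels (the
    dataset seed depends on the replicate only), so comparisons across rho
    are paired.  Desk-scale default: 32 populations, 2,000 SNPs, 20
    associated (the same 1% rate as the full-scale design) at effect 0.1,
    a single dominant structure axis carrying 90% of the drift variance.
    """
    config = config or SimConfig(
        n_pops=32,
        n_snps=2000,
        n_assoc=20,
        beta_effect=0.1,
        omega_spec=("spiked", 0.9),
        pool_sizes=32,
    )
    settings = mcmc_settings or MCMCSettings(
        n_pilot=3, pilot_length=80, burn_in=300, n_samples=400, thin=1
    )
    omega = config.omega()
    result = PowerStudyResult(config=config)
    for li, rho in enumerate(rho_levels):
        scores, labels = [], []
        achieved = []
        for r in range(n_replicates):
            cov_seed = int(
                np.random.SeedSequence([seed, 1000 + li, r]).generate_state(1)[0]
                % 2**31
            )
            data_seed = int(
                np.random.SeedSequence([seed, 1, r]).generate_state(1)[0] % 2**31
            )
            scan_seed = int(
                np.random.SeedSequence([seed, 2000 + li, r]).generate_state(1)[0]
                % 2**31
            )
            covariate, rho_hat = simulate_pc_correlated_covariate(
                omega, rho, seed=cov_seed
            )
            matrix, pops, truth = simulate_dataset(
                config, covariate=covariate, seed=data_seed
            )
            scan = run_aux_scan(
                matrix, pops, omega, covariate, settings, seed=scan_seed
            )
            scores.append(scan.bf_db)
            labels.append(truth.truth_mask(scan.snp_ids))
            achieved.append(rho_hat)
        pooled = np.concatenate(scores)
        pooled_truth = np.concatenate(labels)
        result.curves[float(rho)] = roc_pr_curves(
            pooled, pooled_truth, n_replicates=n_replicates, rho_level=float(rho)
        )
        result.achieved_rho[float(rho)] = achieved
    return result
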