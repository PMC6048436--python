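"""Fold-enrichment tests with circular-permutation nulls.

Two flavours of the same statistic:

* annotation enrichment, FE = (s_a / s) / (S_a / S): is a functional
  category (say, amino-acid-changing SNPs) over-represented among the
  top-associated SNPs relative to its genome-wide share?
* differentiation overlap, FE = (n_a / n) / (N_a / N): do the
  top-associated SNPs fall in the extreme tail of the XtX differentiation
  scan more often than chance?

Significance comes from rotating the tail-membership indicator along the
concatenated genome by a random offset and recomputing FE.  Rotation
preserves runs of neighbouring SNPs -- the local linkage-disequilibrium
structure that makes independent shuffling anti-conservative -- which is
the point of using it instead of a plain permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError


@dataclass
class EnrichmentResult:
    """Counts, fold enrichment and permutation significance for one test.

    ``tail_size``/``tail_hits`` are the generic (s, s_a) or (n, n_a)
    counts; ``total``/``total_hits`` the genome-wide (S, S_a) or (N, N_a).
    """

    covariate: str
    category: str
    tail_size: int
    tail_hits: int
    total: int
    total_hits: int
    fold_enrichment: float
    direction: str = "over"
    n_permutations: int = 0
    p_perm: float | None = None
    fdr_adjusted_p: float | None = None
    undefined: bool = False

    def __post_init__(self) -> None:
        if not (
            0 <= self.tail_hits <= self.tail_size <= self.total
            and self.total_hits <= self.total
        ):
            raise ValidationError("inconsistent enrichment counts")
        if self.p_perm is not None and not 0 < self.p_perm <= 1:
            raise ValidationError("p_perm must lie in (0, 1]")


def upper_tail(values: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the floor(fraction * N) largest values.

    Ties are broken by genome order (the earlier SNP wins), so the tail is
    deterministic.  Input order is taken to be genome order.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty input")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    k = int(np.floor(fraction * len(values)))
    order = np.lexsort((np.arange(len(values)), -values))
    return np.sort(order[:k])


def fold_enrichment_annotation(
    top_idx: np.ndarray,
    categories: np.ndarray,
    category: str,
    covariate: str = "covariate",
) -> EnrichmentResult:
    """FE of an annotation category within a top-SNP set.

    ``categories`` gives the annotation class of every SNP in genome
    order; ``top_idx`` indexes the tail SNPs into that same order.
    """
    categories = np.asarray(categories, dtype=object)
    top_idx = np.asarray(top_idx)
    in_cat = categories == category
    s = len(top_idx)
    s_a = int(in_cat[top_idx].sum())
    S = len(categories)
    S_a = int(in_cat.sum())
    undefined = S_a == 0 or s == 0
    fe = np.nan if undefined else (s_a / s) / (S_a / S)
    return EnrichmentResult(
        covariate=covariate,
        category=category,
        tail_size=s,
        tail_hits=s_a,
        total=S,
        total_hits=S_a,
        fold_enrichment=float(fe),
        direction="over" if undefined or fe >= 1.0 else "under",
        undefined=undefined,
    )


def fold_enrichment_xtx(
    top_bf_idx: np.ndarray,
    top_xtx_idx: np.ndarray,
    n_total: int,
    covariate: str = "covariate",
) -> EnrichmentResult:
    """FE of the XtX upper tail within the BF upper tail.

    With n = |XtX tail|, N_a = |BF tail| and n_a their overlap,
    FE = (n_a / n) / (N_a / N).
    """
    top_bf = np.asarray(top_bf_idx)
    top_xtx = np.asarray(top_xtx_idx)
    n = len(top_xtx)
    n_a = len(np.intersect1d(top_bf, top_xtx, assume_unique=True))
    N_a = len(top_bf)
    undefined = n == 0 or N_a == 0
    fe = np.nan if undefined else (n_a / n) / (N_a / n_total)
    return EnrichmentResult(
        covariate=covariate,
        category="XtX tail",
        tail_size=n,
        tail_hits=n_a,
        total=n_total,
        total_hits=N_a,
        fold_enrichment=float(fe),
        direction="over" if undefined or fe >= 1.0 else "under",
        undefined=undefined,
    )


def _fe_from_indicator(tail: np.ndarray, attr: np.ndarray) -> float:
    """FE of attribute within tail, both as 0/1 vectors in genome order."""
    s = tail.sum()
    sa = int((tail & attr).sum())
    S = len(tail)
    Sa = int(attr.sum())
    if s == 0 or Sa == 0:
        return np.nan
    return (sa / s) / (Sa / S)


def circular_permutation_test(
    tail_indicator: np.ndarray,
    attribute: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    observed_fe: float | None = None,
    direction: str = "over",
    exhaustive: bool = False,
) -> tuple[float, np.ndarray]:
    """Circular-permutation p-value for a fold enrichment.

    The tail-membership indicator is rotated along the genome by a random
    offset while the attribute labels stay fixed; FE is recomputed at each
    rotation.  The add-one estimator
    ``p = (1 + #{FE_null >= FE_obs}) / (1 + n_perm)`` is returned for
    over-representation (mirrored for under-representation), so p is never
    exactly zero.  Offsets are drawn uniformly with replacement; with
    ``exhaustive=True`` every offset 1 .. N-1 is evaluated exactly once
    (the n_perm argument is then ignored).

    Returns ``(p_perm, null_fe)``.
    """
    tail = np.asarray(tail_indicator).astype(bool)
    attr = np.asarray(attribute).astype(bool)
    if tail.shape != attr.shape:
        raise ValidationError("tail and attribute must share genome order")
    n = len(tail)
    if n < 2:
        raise ValidationError("need at least two SNPs")
    if observed_fe is None:
        observed_fe = _fe_from_indicator(tail, attr)
    if exhaustive:
        offsets = np.arange(1, n)
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        offsets = rng.integers(1, n, size=n_perm)
    null = np.empty(len(offsets))
    # FE at each rotation via the cross-correlation of the two indicators
    s = int(tail.sum())
    Sa = int(attr.sum())
    if s == 0 or Sa == 0:
        raise ValidationError("degenerate tail or attribute (all zero)")
    overlap = _circular_overlap(tail, attr, offsets)
    null = (overlap / s) / (Sa / n)
    if direction == "over":
        extreme = int((null >= observed_fe - 1e-12).sum())
    elif direction == "under":
        extreme = int((null <= observed_fe + 1e-12).sum())
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    p = (1.0 + extreme) / (1.0 + len(offsets))
    return float(p), null


def _circular_overlap(
    tail: np.ndarray, attr: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """#(rotated tail AND attr) for each offset, via FFT cross-correlation."""
    n = len(tail)
    if len(offsets) * n <= 4_000_000:
        # direct evaluation is cheaper for small problems and exact
        return np.array(
            [int((np.roll(tail, o) & attr).sum()) for o in offsets]
        )
    ft = np.fft.rfft(tail.astype(float))
    fa = np.fft.rfft(attr.astype(float))
    # corr[o] = sum_i tail[(i - o) mod n] * attr[i]
    corr = np.fft.irfft(fa * np.conj(ft), n)
    return np.rint(corr[offsets % n]).astype(np.int64)


def attach_permutation_p(
    result: EnrichmentResult,
    tail_indicator: np.ndarray,
    attribute: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Fill ``p_perm`` of an EnrichmentResult via circular permutation."""
    p, _ = circular_permutation_test(
        tail_indicator,
        attribute,
        n_perm=n_perm,
        seed=seed,
        observed_fe=result.fold_enrichment,
        direction=result.direction,
    )
    result.p_perm = p
    result.n_permutations = n_perm
    return result


def adjust_enrichment_fdr(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Benjamini-Hochberg correction across a family of enrichment tests.

    The family is whatever list is passed in -- typically all categories
    x covariates of one analysis.  Results without a permutation p-value
    are left untouched.
    """
    tested = [r for r in results if r.p_perm is not None]
    if not tested:
        return results
    pvals = np.array([r.p_perm for r in tested])
    _, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, p in zip(tested, adj):
        r.fdr_adjusted_p = float(p)
    return results
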