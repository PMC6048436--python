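"""Climate-covariate pruning, climate PCA and spatial-grain analysis.

The spatial machinery decomposes the geometry of the sampled populations
into orthogonal eigenvector maps (Principal Coordinates of Neighbour
Matrices, PCNM): the leading components vary smoothly over the whole
sampling area (coarse spatial grain), the trailing ones oscillate between
near neighbours (fine grain).  Regressing a climate variable on all
components and keeping the significant ones (Benjamini-Hochberg) reads
off the spatial scales at which that variable varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .datamodel import ValidationError


@dataclass
class SpatialBasis:
    """Orthogonal spatial eigenvectors from a truncated distance matrix."""

    vectors: np.ndarray          # (n_pops, n_components), unit norm
    eigenvalues: np.ndarray      # positive, decreasing
    truncation_threshold: float

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ClimateSpace:
    """PCA of locations in climate space."""

    scores: np.ndarray           # (n_locations, n_components)
    loadings: np.ndarray         # (n_variables, n_components)
    explained_fraction: np.ndarray
    var_names: list[str]
    groups: np.ndarray | None = None

    def group_scores(self, group, component: int = 0) -> np.ndarray:
        if self.groups is None:
            raise ValidationError("no group labels attached")
        return self.scores[self.groups == group, component]


# ---------------------------------------------------------------------------
# covariate pruning and climate PCA
# ---------------------------------------------------------------------------

def prune_covariates(
    climate: pd.DataFrame,
    rho_threshold: float = 0.8,
    preference_order: list[str] | None = None,
) -> list[str]:
    """Greedy Spearman-correlation pruning of covariates.

    Variables are visited in preference order (input column order by
    default, standing in for the expert's ranking of ecological
    relevance); a variable is kept iff its absolute Spearman correlation
    with every already-kept variable stays at or below the threshold.
    Constant variables are excluded with a warning.
    """
    import warnings

    names = preference_order or list(climate.columns)
    missing = set(names) - set(climate.columns)
    if missing:
        raise ValidationError(f"preference order names unknown: {sorted(missing)}")
    kept: list[str] = []
    for name in names:
        v = climate[name].to_numpy(float)
        if np.ptp(v) == 0:
            warnings.warn(f"constant covariate {name!r} excluded", stacklevel=2)
            continue
        ok = True
        for prev in kept:
            rho = stats.spearmanr(v, climate[prev].to_numpy(float)).statistic
            if abs(rho) > rho_threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


def climate_pca(
    climate: pd.DataFrame, groups: np.ndarray | None = None
) -> ClimateSpace:
    """PCA of locations on standardized climate variables."""
    import warnings

    X = climate.to_numpy(float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least two locations")
    if n < p:
        warnings.warn("fewer locations than variables", stacklevel=2)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    var = s**2
    return ClimateSpace(
        scores=u * s,
        loadings=vt.T,
        explained_fraction=var / var.sum(),
        var_names=list(climate.columns),
        groups=None if groups is None else np.asarray(groups),
    )


def range_fraction(
    space: ClimateSpace, subgroup, reference_group=None, component: int = 0
) -> float:
    """Percent of a reference group's score range spanned by a subgroup.

    With no reference group, the whole data set is the reference.
    """
    sub = space.group_scores(subgroup, component)
    ref = (
        space.scores[:, component]
        if reference_group is None
        else space.group_scores(reference_group, component)
    )
    ref_range = np.ptp(ref)
    if ref_range == 0:
        raise ValidationError("degenerate reference range")
    return 100.0 * float(np.ptp(sub)) / float(ref_range)


# ---------------------------------------------------------------------------
# PCNM spatial basis and regressions
# ---------------------------------------------------------------------------

def compute_pcnm(
    coordinates: np.ndarray, truncation: float | None = None
) -> SpatialBasis:
    """Principal Coordinates of Neighbour Matrices from point coordinates.

    Classical construction: Euclidean distances; distances above the
    truncation threshold (by default the longest edge of the minimum
    spanning tree, which keeps the neighbour graph connected) are replaced
    by four times the threshold; principal-coordinates analysis of the
    modified matrix; components with positive eigenvalues are returned in
    decreasing order.  Coordinates are planar (project first if the extent
    is large enough for the Earth's curvature to matter).
    """
    xy = np.asarray(coordinates, dtype=float)
    if xy.ndim != 2 or len(xy) < 3:
        raise ValidationError("need at least three points (n x 2 array)")
    d = squareform(pdist(xy))
    if d[np.triu_indices_from(d, 1)].max() == 0:
        raise ValidationError("all points are collocated")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    dmod = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dmod, 0.0)
    # Gower-centered principal coordinates
    n = len(xy)
    a = -0.5 * dmod**2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    b = centering @ a @ centering
    vals, vecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-9, 1e-9 * abs(vals[0]))
    return SpatialBasis(
        vectors=vecs[:, keep],
        eigenvalues=vals[keep],
        truncation_threshold=truncation,
    )


def pcnm_regression(
    variable: np.ndarray,
    basis: SpatialBasis,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """OLS of one variable on all PCNM components jointly, with BH-FDR.

    Returns one row per component: coefficient, t, p, BH-adjusted p and a
    significance flag at ``fdr_level``.
    """
    from statsmodels.stats.multitest import multipletests

    y = np.asarray(variable, dtype=float)
    X = basis.vectors
    if len(y) != X.shape[0]:
        raise ValidationError("variable and basis differ in populations")
    if X.shape[1] > len(y) - 2:
        raise ValidationError("more components than populations allow")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = fit.params[1:]
    tvals = fit.tvalues[1:]
    pvals = fit.pvalues[1:]
    if np.ptp(y) == 0:
        pvals = np.ones_like(pvals)
    reject, adj, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    return pd.DataFrame(
        {
            "component": np.arange(1, X.shape[1] + 1),
            "coef": coefs,
            "t": tvals,
            "p": pvals,
            "p_bh": adj,
            "significant": reject,
        }
    )


def genomic_geography_regression(
    pc_scores: np.ndarray,
    latitude: np.ndarray,
    longitude: np.ndarray,
) -> dict:
    """Regress a genomic principal component on geography.

    Model: score ~ latitude + longitude + latitude x longitude.  Returns
    coefficients, t-values, p-values and the adjusted R^2.
    """
    y = np.asarray(pc_scores, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    X = np.column_stack([lat, lon, lat * lon])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(lat), X])) < 4:
        raise ValidationError("degenerate (collinear) geographic design")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept", "latitude", "longitude", "latitude:longitude"]
    return {
        "coef": dict(zip(names, fit.params)),
        "t": dict(zip(names, fit.tvalues)),
        "p": dict(zip(names, fit.pvalues)),
        "adj_r2": float(fit.rsquared_adj),
    }
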