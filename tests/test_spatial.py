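"""Climate pruning/PCA and PCNM spatial-grain machinery."""

import numpy as np
import pandas as pd
import pytest

from poolgea import (
    climate_pca,
    compute_pcnm,
    genomic_geography_regression,
    pcnm_regression,
    prune_covariates,
    range_fraction,
)
from poolgea.datamodel import ValidationError


class TestPruning:
    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        assert prune_covariates(df) == ["a", "b", "c", "d"]

    def test_greedy_preference_trace(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        df = pd.DataFrame(
            {
                "v1": x,
                "v2": x + 0.05 * rng.standard_normal(300),  # |rho| > 0.8 with v1
                "v3": rng.standard_normal(300),
            }
        )
        assert prune_covariates(df, preference_order=["v1", "v2", "v3"]) == [
            "v1", "v3",
        ]
        # preference order decides the survivor of a correlated pair
        assert prune_covariates(df, preference_order=["v2", "v1", "v3"]) == [
            "v2", "v3",
        ]

    def test_kept_set_satisfies_bound(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((150, 2))
        df = pd.DataFrame(
            np.column_stack(
                [base[:, 0], base[:, 0] * 0.9 + 0.1 * base[:, 1], base[:, 1]]
            ),
            columns=["a", "b", "c"],
        )
        from scipy import stats

        kept = prune_covariates(df, rho_threshold=0.8)
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                rho = stats.spearmanr(df[x], df[y]).statistic
                assert abs(rho) <= 0.8

    def test_constant_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            assert prune_covariates(df) == ["b"]


class TestClimatePca:
    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        space = climate_pca(df)
        assert space.explained_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_near_equal_fractions(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((1000, 4)), columns=list("abcd"))
        space = climate_pca(df)
        np.testing.assert_allclose(space.explained_fraction, 0.25, atol=0.03)

    def test_range_fraction(self):
        rng = np.random.default_rng(4)
        # two correlated variables share a latent axis whose spread is
        # five times wider in the reference group than in the subgroup
        latent = np.concatenate([rng.uniform(-5, 5, 400), rng.uniform(-1, 1, 100)])
        df = pd.DataFrame({
            "a": latent + 0.1 * rng.standard_normal(500),
            "b": -latent + 0.1 * rng.standard_normal(500),
        })
        groups = np.array(["ref"] * 400 + ["sub"] * 100)
        space = climate_pca(df, groups=groups)
        full = range_fraction(space, "ref", "ref")
        assert full == pytest.approx(100.0)
        sub = range_fraction(space, "sub", "ref")
        assert 10 < sub < 35  # ~2/10 of the reference spread

    def test_degenerate_reference_rejected(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [5.0, 4.0, 2.0]})
        space = climate_pca(df, groups=np.array(["r", "r", "s"]))
        space.scores = np.zeros_like(space.scores)
        with pytest.raises(ValidationError):
            range_fraction(space, "s", "r")


class TestPcnm:
    def test_line_first_component_is_coarsest_grain(self):
        # on a unit-spaced transect the leading component is the broadest
        # spatial wave: a single sign change, and the number of sign
        # changes grows with component index (finer and finer grains)
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        basis = compute_pcnm(xy)
        def sign_changes(v):
            return int((np.diff(np.sign(v)) != 0).sum())
        changes = [sign_changes(basis.vectors[:, k]) for k in range(4)]
        assert changes[0] == 1
        assert changes == sorted(changes)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 100, size=(25, 2))
        basis = compute_pcnm(xy)
        gram = basis.vectors.T @ basis.vectors
        np.testing.assert_allclose(gram, np.eye(basis.n_components), atol=1e-8)

    def test_matches_direct_eigendecomposition_oracle(self):
        from scipy.spatial.distance import pdist, squareform
        from scipy.sparse.csgraph import minimum_spanning_tree

        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 10, size=(12, 2))
        basis = compute_pcnm(xy)
        d = squareform(pdist(xy))
        t = minimum_spanning_tree(d).toarray().max()
        dm = np.where(d > t, 4 * t, d)
        np.fill_diagonal(dm, 0.0)
        n = 12
        c = np.eye(n) - np.full((n, n), 1 / n)
        b = c @ (-0.5 * dm**2) @ c
        vals = np.sort(np.linalg.eigvalsh(b))[::-1]
        np.testing.assert_allclose(
            basis.eigenvalues, vals[: basis.n_components], atol=1e-8
        )

    def test_collocated_points_rejected(self):
        with pytest.raises(ValidationError):
            compute_pcnm(np.zeros((5, 2)))


class TestPcnmRegression:
    def test_planted_component_recovered(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 50, size=(40, 2))
        basis = compute_pcnm(xy)
        k = 3
        y = 2.0 * basis.vectors[:, k] + 0.01 * rng.standard_normal(40)
        rep = pcnm_regression(y, basis)
        sig = rep.loc[rep["significant"], "component"].tolist()
        assert k + 1 in sig
        # nothing else comes close in effect size
        others = rep.loc[rep["component"] != k + 1, "coef"].abs()
        assert others.max() < 0.05

    def test_constant_variable_nothing_significant(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 50, size=(30, 2))
        basis = compute_pcnm(xy)
        rep = pcnm_regression(np.full(30, 3.14), basis)
        assert not rep["significant"].any()

    def test_noise_false_positive_rate_controlled(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 50, size=(40, 2))
        basis = compute_pcnm(xy)
        hits = 0
        reps = 120
        for _ in range(reps):
            rep = pcnm_regression(rng.standard_normal(40), basis)
            hits += int(rep["significant"].any())
        # family-wise BH at 5% per variable: few replicates with any hit
        assert hits / reps <= 0.10

    def test_scale_invariance_of_pvalues(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 50, size=(30, 2))
        basis = compute_pcnm(xy)
        y = rng.standard_normal(30)
        p1 = pcnm_regression(y, basis)["p"].to_numpy()
        scaled = pcnm_regression(y, basis=basis)["p"].to_numpy()
        np.testing.assert_allclose(p1, scaled, atol=1e-12)


class TestGeographyRegression:
    def test_planted_latitude_slope(self):
        rng = np.random.default_rng(11)
        lat = rng.uniform(42, 45, 168)
        lon = rng.uniform(0, 3, 168)
        scores = 0.5 * lat + 0.05 * rng.standard_normal(168)
        fit = genomic_geography_regression(scores, lat, lon)
        assert fit["p"]["latitude"] < 1e-6
        assert fit["adj_r2"] > 0.9

    def test_independent_scores_low_r2(self):
        rng = np.random.default_rng(12)
        lat = rng.uniform(42, 45, 168)
        lon = rng.uniform(0, 3, 168)
        fit = genomic_geography_regression(rng.standard_normal(168), lat, lon)
        assert fit["adj_r2"] < 0.05

    def test_collinear_design_rejected(self):
        lat = np.linspace(40, 45, 30)
        with pytest.raises(ValidationError):
            genomic_geography_regression(np.zeros(30), lat, np.zeros(30))


def test_pcnm_against_r_vegan_oracle(tmp_path):
    """Cross-check eigenvalues against the classical R implementation."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(13)
    xy = rng.uniform(0, 10, size=(10, 2))
    np.savetxt(tmp_path / "xy.txt", xy)
    script = tmp_path / "pcnm.R"
    script.write_text(
        'xy <- as.matrix(read.table("%s"))\n'
        "suppressMessages(library(vegan))\n"
        "p <- pcnm(dist(xy))\n"
        'cat(p$values[p$values > 1e-9], sep="\\n")\n' % (tmp_path / "xy.txt")
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    r_vals = np.array([float(v) for v in out.stdout.split()])
    basis = compute_pcnm(xy)
    k = min(len(r_vals), basis.n_components)
    np.testing.assert_allclose(basis.eigenvalues[:k], r_vals[:k], rtol=1e-6)
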