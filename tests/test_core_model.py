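"""Omega estimation, FMD distances, SVD and XtX."""

import numpy as np
import pytest

from poolgea import (
    MCMCSettings,
    OmegaMatrix,
    SimConfig,
    compute_xtx,
    estimate_core_model,
    fmd_distance,
    omega_from_spec,
    omega_svd,
    simulate_dataset,
    subsample_snps,
)
from poolgea.datamodel import ValidationError
from poolgea.model.core import CoreModelPosterior

TINY = MCMCSettings(n_pilot=1, pilot_length=30, burn_in=80, n_samples=80, thin=1)
SHORT = MCMCSettings(n_pilot=2, pilot_length=50, burn_in=250, n_samples=200, thin=1)


class TestSubsampling:
    def test_two_subsets_interleave(self, tiny_matrix):
        cfg = SimConfig(n_pops=4, n_snps=10, n_assoc=0, seed=0)
        m, _, _ = simulate_dataset(cfg)
        subs = subsample_snps(m, 2)
        assert [s.n_snps for s in subs] == [5, 5]
        assert subs[0].snp_ids.tolist() == m.snp_ids[0::2].tolist()
        assert subs[1].snp_ids.tolist() == m.snp_ids[1::2].tolist()

    def test_uneven_sizes(self):
        cfg = SimConfig(n_pops=4, n_snps=7, n_assoc=0, seed=0)
        m, _, _ = simulate_dataset(cfg)
        assert [s.n_snps for s in subsample_snps(m, 3)] == [3, 2, 2]

    def test_subsets_partition_input(self):
        cfg = SimConfig(n_pops=4, n_snps=33, n_assoc=0, seed=1)
        m, _, _ = simulate_dataset(cfg)
        subs = subsample_snps(m, 5)
        all_ids = sorted(i for s in subs for i in s.snp_ids)
        assert all_ids == sorted(m.snp_ids)

    def test_errors(self, tiny_matrix):
        with pytest.raises(ValueError):
            subsample_snps(tiny_matrix, 0)
        with pytest.raises(ValueError):
            subsample_snps(tiny_matrix, 3)


class TestFmdDistance:
    def test_identity_case(self):
        a = OmegaMatrix.identity(4)
        assert fmd_distance(a, a) == 0.0

    def test_closed_form_2x2(self):
        a = OmegaMatrix.identity(2)
        b = OmegaMatrix(np.diag([2.0, 2.0]))
        assert fmd_distance(a, b) == pytest.approx(np.sqrt(2) * np.log(2), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 5))
        a = OmegaMatrix(x @ x.T + 5 * np.eye(5))
        b = OmegaMatrix.compound_symmetry(5, 0.3)
        assert fmd_distance(a, b) == pytest.approx(fmd_distance(b, a), abs=1e-10)
        assert fmd_distance(a, b) > 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            fmd_distance(OmegaMatrix.identity(3), OmegaMatrix.identity(4))


class TestOmegaSvd:
    def test_identity_equal_fractions(self):
        _, _, frac = omega_svd(OmegaMatrix.identity(8))
        np.testing.assert_allclose(frac, 1 / 8)

    def test_equicorrelation_closed_form(self):
        _, _, frac = omega_svd(OmegaMatrix.compound_symmetry(10, 0.9))
        assert frac[0] == pytest.approx((1 + 9 * 0.9) / 10, abs=1e-12)

    def test_fractions_sum_to_one_and_sorted(self):
        om = OmegaMatrix.spiked(12, 0.7)
        vals, vecs, frac = omega_svd(om)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(vals) <= 1e-12).all()
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(12), atol=1e-10)


class TestOmegaSpec:
    def test_named_forms(self):
        assert omega_from_spec("identity", 3).n_pops == 3
        cs = omega_from_spec(("cs", 0.4), 5)
        assert cs.omega[0, 1] == pytest.approx(0.4)
        blk = omega_from_spec(("block", [2, 3], 0.5), 5)
        assert blk.omega[0, 4] == 0.0
        sp = omega_from_spec(("spiked", 0.75), 8)
        assert np.trace(sp.omega) == pytest.approx(8.0)
        _, _, frac = omega_svd(sp)
        assert frac[0] == pytest.approx(0.75, abs=1e-12)

    def test_invalid_forms(self):
        with pytest.raises(ValidationError):
            omega_from_spec("mystery", 4)
        with pytest.raises(ValidationError):
            omega_from_spec(("block", [2, 3], 0.5), 6)
        with pytest.raises(ValidationError):
            OmegaMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD


class TestXtX:
    def test_single_draw_quadratic_form(self):
        abar = np.array([1.0, -1.0, 2.0, 0.0])
        post = CoreModelPosterior(
            pi_mean=np.array([0.5]),
            alpha_mean=abar[None, :],
            m2=np.outer(abar, abar)[None, :, :],
            xtx=np.empty(0),
            snp_ids=np.array(["s"], dtype=object),
            acceptance={},
            ess=1.0,
            settings=TINY,
            seed=0,
        )
        xtx = compute_xtx(post, OmegaMatrix.identity(4))
        assert xtx[0] == pytest.approx(6.0, abs=1e-12)

    def test_neutral_mean_near_pop_count(self):
        cfg = SimConfig(n_pops=8, n_snps=1500, n_assoc=0, seed=4)
        m, pops, _ = simulate_dataset(cfg)
        post, om = estimate_core_model(m, pops, TINY, seed=5)
        assert post.xtx.mean() == pytest.approx(8.0, rel=0.06)
        assert (post.xtx >= 0).all()


class TestCoreEstimation:
    def test_identity_recovery_off_diagonals(self):
        cfg = SimConfig(n_pops=8, n_snps=1200, n_assoc=0, seed=21)
        m, pops, _ = simulate_dataset(cfg)
        _, om = estimate_core_model(m, pops, SHORT, seed=22)
        off = om.omega[np.triu_indices(8, 1)]
        assert np.abs(off).max() < 0.1

    def test_structured_beats_identity_and_self_consistency(self):
        true_om = OmegaMatrix.compound_symmetry(8, 0.5)
        cfg = SimConfig(n_pops=8, n_snps=2000, n_assoc=0,
                        omega_spec=("cs", 0.5), seed=31)
        m, pops, _ = simulate_dataset(cfg)
        subs = subsample_snps(m, 2)
        _, om_a = estimate_core_model(subs[0], pops, SHORT, seed=32)
        _, om_b = estimate_core_model(subs[1], pops, SHORT, seed=33)
        assert fmd_distance(om_a, true_om) < fmd_distance(
            OmegaMatrix.identity(8), true_om
        )
        # disjoint-subset concordance, mirroring a multi-subset design
        tri = np.triu_indices(8)
        r = np.corrcoef(om_a.omega[tri], om_b.omega[tri])[0, 1]
        assert r > 0.9

    def test_reproducible_under_seed(self):
        cfg = SimConfig(n_pops=5, n_snps=300, n_assoc=0, seed=2)
        m, pops, _ = simulate_dataset(cfg)
        _, om1 = estimate_core_model(m, pops, TINY, seed=7)
        _, om2 = estimate_core_model(m, pops, TINY, seed=7)
        np.testing.assert_array_equal(om1.omega, om2.omega)

    def test_too_few_populations_rejected(self):
        cfg = SimConfig(n_pops=2, n_snps=50, n_assoc=0, seed=0)
        m, pops, _ = simulate_dataset(cfg)
        with pytest.raises(ValidationError):
            estimate_core_model(m, pops, TINY, seed=0)
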