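import math

import numpy as np
import pytest
from scipy import stats

from chromofiber import (ModelParams, build_chain_2d, build_chain_3d,
                         build_ensemble, contact_profile,
                         sample_linker_lengths, linker_sampler)
from chromofiber.frc import (JOINT_DNA, JOINT_NUCLEOSOME, JOINT_PROTEIN,
                             LinkerError, dna_tangent_ensemble,
                             fit_persistence_length, theta_d)


class TestChainConstruction:
    def test_tangents_are_unit_vectors(self, params):
        ch = build_chain_3d(50, 42.0, 0.3, 90.0, params, seed=1)
        norms = np.linalg.norm(ch.tangents, axis=1)
        assert np.allclose(norms, 1.0, rtol=1e-12)

    def test_measured_angles_match_imposed(self, params):
        ch = build_chain_3d(50, 42.0, 0.5, (90.0, 135.0), params, seed=2)
        assert np.allclose(ch.measured_joint_angles(), ch.joint_theta,
                           atol=1e-9)

    def test_joint_census(self, params):
        M = 40
        ch = build_chain_3d(M, 42.0, 0.0, 90.0, params, seed=3)
        assert np.sum(ch.joint_kind == JOINT_NUCLEOSOME) == M
        assert ch.n_proteins == 0
        # 42 bp = 4 bonds per linker, plus entry/exit histone-bound bonds
        assert ch.n_bonds == 1 + M + (M - 1) * 5
        assert len(ch.vertices) == ch.n_bonds + 1
        # nucleosome joints measure theta_n = 120 deg
        nuc_angles = ch.joint_theta[ch.joint_kind == JOINT_NUCLEOSOME]
        assert np.allclose(nuc_angles, math.radians(120))

    def test_saturated_protein_occupancy(self, params):
        # rho = 1: exactly one protein joint per linker, at the imposed angle
        ch = build_chain_3d(3, 42.0, 1.0, 90.0, params, seed=4)
        assert ch.n_proteins == 2
        prot_angles = ch.joint_theta[ch.joint_kind == JOINT_PROTEIN]
        assert np.allclose(prot_angles, math.radians(90))

    def test_rigid_linker_limit_is_collinear(self):
        # Lp -> infinity makes theta_d -> 0: every non-nucleosome joint
        # is a straight continuation
        p = ModelParams(Lp_bp=1e12)
        ch = build_chain_3d(5, 42.0, 0.0, 90.0, p, seed=5)
        dna = ch.joint_kind == JOINT_DNA
        assert np.allclose(ch.measured_joint_angles()[dna], 0.0, atol=1e-5)

    def test_minimum_size(self, params):
        build_chain_3d(2, 42.0, 0.0, 90.0, params, seed=6)
        with pytest.raises(ValueError):
            build_chain_3d(1, 42.0, 0.0, 90.0, params, seed=6)

    def test_linker_must_be_multiple_of_repeat(self, params):
        with pytest.raises(ValueError):
            build_chain_3d(5, 40.0, 0.0, 90.0, params, seed=7)

    def test_short_linker_cannot_host_protein(self, params):
        with pytest.raises(LinkerError, match="linker"):
            build_chain_3d(5, 21.0, 0.5, 90.0, params, seed=8)
        # without proteins short linkers are fine
        build_chain_3d(5, 21.0, 0.0, 90.0, params, seed=8)

    def test_ensemble_reproducible_and_seed_sensitive(self, params):
        a1, _ = build_ensemble(20, 30, 42.0, 0.3, 90.0, params, seed=9)
        a2, _ = build_ensemble(20, 30, 42.0, 0.3, 90.0, params, seed=9)
        b, _ = build_ensemble(20, 30, 42.0, 0.3, 90.0, params, seed=10)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_single_chain_matches_ensemble_path(self, params):
        # the annotated single-chain vertices reproduce the vectorized
        # nucleosome positions for the same seed
        ch = build_chain_3d(30, 42.0, 0.4, 90.0, params, seed=11)
        pos, _ = build_ensemble(1, 30, 42.0, 0.4, 90.0, params, seed=11)
        assert np.allclose(ch.nucleosome_positions, pos[0], atol=1e-9)


class TestChain2D:
    def test_planar(self, params):
        ch = build_chain_2d(24, 42.0, 0.24, 120.0, params, seed=1)
        assert np.allclose(ch.vertices[:, 2], 0.0)

    def test_zigzag_alternates_turn_sides(self, params):
        # with rho=0 the nucleosome turn directions alternate strictly
        ch = build_chain_2d(24, 42.0, 0.0, 120.0, params, seed=2)
        nuc_joints = np.nonzero(ch.joint_kind == JOINT_NUCLEOSOME)[0]
        t_in = ch.tangents[nuc_joints]
        t_out = ch.tangents[nuc_joints + 1]
        signs = np.sign(np.cross(t_in, t_out)[:, 2])
        assert np.all(signs[1:] * signs[:-1] == -1)

    def test_protein_count_expectation(self, params):
        # Fig-4-like conditions: 24 nucleosomes, rho=0.24 -> about
        # 0.24 * 23 = 5.5 protein joints per chain on average
        _, nprot = build_ensemble(600, 24, 42.0, 0.24, 120.0, params,
                                  seed=3, two_d=True)
        assert nprot.mean() == pytest.approx(0.24 * 23, abs=0.4)

    def test_minimal_two_nucleosomes(self, params):
        ch = build_chain_2d(2, 42.0, 0.0, 120.0, params, seed=4)
        assert np.sum(ch.joint_kind == JOINT_NUCLEOSOME) == 2


class TestThetaD:
    def test_sqrt_mapping_default(self):
        # a = 5.25 bp, Lp = 150 bp -> sqrt(21/150) = 0.374 rad
        assert theta_d(ModelParams()) == pytest.approx(
            math.sqrt(21.0 / 150.0), rel=1e-12)

    def test_literal_mapping_option(self):
        assert theta_d(ModelParams(theta_d_literal=True)) == pytest.approx(
            21.0 / 150.0, rel=1e-12)

    def test_stiff_limit(self):
        assert theta_d(ModelParams(Lp_bp=1e15)) == pytest.approx(0.0, abs=1e-6)

    def test_persistence_length_recovered(self, params):
        # tangent correlation of a pure DNA chain decays with Lp within
        # 10% of 150 bp -- validates the sqrt mapping
        tang = dna_tangent_ensemble(800, 250, params, seed=11)
        Lp = fit_persistence_length(tang)
        assert Lp == pytest.approx(150.0, rel=0.10)


class TestZigZagStatistics:
    def test_next_neighbor_contacts_dominate_without_proteins(self, params):
        pos, _ = build_ensemble(300, 200, 42.0, 0.0, 90.0, params, seed=21)
        prof = contact_profile(pos, params.contact_cutoff, 6)
        assert prof.I[1] > prof.I[0]
        assert prof.I[1] > prof.I[2:].max()

    def test_protein_joint_count_is_binomial(self, params):
        # chi-square goodness of fit of per-chain protein counts against
        # Binomial(M-1, rho) at the 1% level
        M, rho, R = 20, 0.3, 2000
        _, nprot = build_ensemble(R, M, 42.0, rho, 90.0, params, seed=22)
        n = M - 1
        counts = np.bincount(nprot, minlength=n + 1)
        pmf = stats.binom.pmf(np.arange(n + 1), n, rho)
        # pool tails so expected counts are not tiny
        keep = pmf * R >= 5
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(pmf[keep] * R, pmf[~keep].sum() * R)
        chi2 = ((obs - exp)**2 / exp).sum()
        pval = stats.chi2.sf(chi2, len(obs) - 1)
        assert pval > 0.01


class TestLinkerSampling:
    def test_mean_converges(self):
        s = sample_linker_lengths(42.0, (31.5, 73.5), 100_000, seed=1)
        assert s.mean() == pytest.approx(42.0, rel=0.01)
        assert set(np.unique(s)) <= {31.5, 42.0, 52.5, 63.0, 73.5}

    def test_degenerate_range(self):
        s = sample_linker_lengths(42.0, (42.0, 42.0), 100, seed=2)
        assert np.all(s == 42.0)

    def test_mean_at_support_minimum_is_point_mass(self):
        s = sample_linker_lengths(31.5, (31.5, 73.5), 100, seed=3)
        assert np.all(s == 31.5)

    def test_infeasible_mean(self):
        with pytest.raises(ValueError):
            sample_linker_lengths(80.0, (31.5, 73.5), 10, seed=4)

    def test_range_must_align_to_repeat(self):
        with pytest.raises(ValueError):
            sample_linker_lengths(42.0, (30.0, 70.0), 10, seed=5)

    def test_variable_linker_ensemble(self, params):
        pos, _ = build_ensemble(10, 20, linker_sampler(), 0.25,
                                (90.0, 135.0), params, seed=6)
        assert pos.shape == (10, 20, 3)
        assert np.isfinite(pos).all()
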