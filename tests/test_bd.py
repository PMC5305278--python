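import math

import numpy as np
import pytest

from chromofiber import (ModelParams, forces, init_conformation,
                         pair_nucleosomes, place_proteins, total_energy)
from chromofiber import bd
from chromofiber.bd import (BDInstabilityError, dna_chain_system,
                            energy_bend, energy_harmonic, energy_lj,
                            energy_morse, energy_nucl_angle, energy_pairs,
                            integrate_system, step, run)


class TestInitConformation:
    def test_bead_bookkeeping(self, params):
        # 20 nucleosomes x 14 wrapped beads + 19 linkers x 4 beads
        s = init_conformation(20, 42.0, params, seed=1)
        assert s.n_dna == 20 * 14 + 19 * 4 == 356
        assert s.n_beads == 356 + 20
        assert len(s.bonds_dna) == 355
        assert len(s.bonds_wrap) == 20 * 14
        assert len(s.bend_triplets) == 354

    def test_single_nucleosome(self, params):
        s = init_conformation(1, 42.0, params, seed=2)
        assert s.n_dna == 14
        assert len(s.bonds_h1) == 0
        assert len(s.linker_beads) == 0

    def test_wrap_radius_is_rest_length(self, params):
        s = init_conformation(5, 42.0, params, seed=3)
        for m in range(5):
            d = np.linalg.norm(s.pos[s.wrapped[m]]
                               - s.pos[s.nucleosome_beads[m]], axis=1)
            assert np.allclose(d, params.rn, atol=1e-9)

    def test_no_nonbonded_overlaps(self, params):
        s = init_conformation(10, 42.0, params, seed=4)
        dna = s.pos[:s.n_dna]
        iu, ju = np.triu_indices(s.n_dna, 2)
        d = np.linalg.norm(dna[iu] - dna[ju], axis=1)
        assert d.min() > 0.95 * 2 * params.a

    def test_effective_mode_layout(self, params):
        s = init_conformation(10, 42.0, params, mode="effective_angle")
        # 10 nucleosome beads + 9 x 4 linker beads + 2 stubs
        assert s.n_dna == 10 + 36 + 2
        assert len(s.angle_triplets) == 10
        assert len(s.bonds_wrap) == 0
        # entry/exit rays start exactly at alpha_n: zero angle energy
        assert energy_nucl_angle(s) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_inputs(self, params):
        with pytest.raises(ValueError):
            init_conformation(0, 42.0, params)
        with pytest.raises(ValueError):
            init_conformation(5, 40.0, params)
        with pytest.raises(ValueError):
            init_conformation(5, 42.0, params, mode="implicit")


class TestProteinPlacement:
    def test_bonds_strictly_inside_linkers(self, params):
        s = init_conformation(10, 42.0, params, seed=5)
        place_proteins(s, 1.0, seed=6)
        assert len(s.bonds_protein) == 9
        wrapped = set(s.wrapped.ravel())
        for (i, j), (start, nl) in zip(s.bonds_protein, s.linker_beads):
            assert j - i == params.protein_span
            assert start <= i and j <= start + nl - 1
            assert not ({i, j} & wrapped)

    def test_occupancy_probability(self, params):
        s = init_conformation(40, 42.0, params, seed=7)
        place_proteins(s, 0.0, seed=8)
        assert len(s.bonds_protein) == 0
        counts = []
        for sd in range(30):
            place_proteins(s, 0.5, seed=sd)
            counts.append(s.linker_occupancy.sum())
        assert np.mean(counts) == pytest.approx(0.5 * 39, abs=2.5)

    def test_linker_too_short_for_span(self, params):
        s = init_conformation(5, 31.5, params, seed=9)   # 3-bead linkers
        with pytest.raises(ValueError, match="linker"):
            place_proteins(s, 1.0, seed=10, span=3)
        place_proteins(s, 1.0, seed=10, span=2)          # fits


class TestEnergies:
    def test_all_bonds_at_rest_zero_energy(self, params):
        s = dna_chain_system(10, params)
        rep = total_energy(s)
        assert rep.Utot == 0.0

    def test_stretched_bond(self, params):
        s = dna_chain_system(2, params)
        s.pos[1, 0] += 0.1
        rep = energy_harmonic(s)
        assert rep.Us == pytest.approx(0.5 * params.ks * 0.1**2)

    def test_pair_energy_harmonic(self, params):
        # frozen pair of nucleosomes stretched a beyond rh:
        # kh a^2/2 = 12.5 kBT at k~h = 50
        s = init_conformation(2, 42.0, params, seed=1)
        pairs = np.array([[0, 1]])
        b = s.nucleosome_beads
        s.pos[b[1]] = s.pos[b[0]] + [params.rh, 0, 0]
        assert energy_pairs(s, pairs=pairs) == pytest.approx(0.0)
        s.pos[b[1]] = s.pos[b[0]] + [params.rh + params.a, 0, 0]
        assert energy_pairs(s, pairs=pairs) == pytest.approx(12.5)

    def test_lj_reference_points(self, params):
        s = dna_chain_system(3, params)
        two_a = 2 * params.a

        def lj_at(r):
            s.pos[:] = 0.0
            s.pos[1] = [50.0, 0, 0]          # park the middle bead far away
            s.pos[2] = [r, 0, 0]
            return energy_lj(s)

        assert lj_at(two_a) == pytest.approx(0.0, abs=1e-12)
        assert lj_at(3 * params.a) == 0.0    # beyond cutoff, exactly zero
        # the shifted minimum-energy distance gives exactly epsilon
        assert lj_at(two_a * 2**(-1 / 6)) == pytest.approx(params.epsilon)

    def test_bend_kink_energies(self, params):
        s = dna_chain_system(3, params)
        assert energy_bend(s) == pytest.approx(0.0)
        s.pos[2] = s.pos[1] + [0, 1, 0]      # 90 degree kink
        assert energy_bend(s) == pytest.approx(params.kb, rel=1e-9)
        assert energy_bend(s) == pytest.approx(14.0, abs=0.05)
        s.pos[2] = s.pos[0]                  # hairpin: 1 - cos(180) = 2
        assert energy_bend(s) == pytest.approx(2 * params.kb)

    def test_nucleosome_angle_energy(self, params):
        s = init_conformation(3, 42.0, params, mode="effective_angle")
        a, b, c = s.angle_triplets[1]
        # straighten one nucleosome: alpha = 180, alpha_n = 60
        s.pos[c] = 2 * s.pos[b] - s.pos[a]
        expected = params.kn_eff * (1 - math.cos(math.radians(120)))
        assert energy_nucl_angle(s) == pytest.approx(expected)
        # alpha = alpha_n + 90 -> kn_eff
        ray = s.pos[a] - s.pos[b]
        ang = math.radians(150.0)
        rot = np.array([[math.cos(ang), -math.sin(ang), 0],
                        [math.sin(ang), math.cos(ang), 0], [0, 0, 1]])
        s.pos[c] = s.pos[b] + rot @ ray
        assert energy_nucl_angle(s) == pytest.approx(params.kn_eff, rel=1e-9)

    def test_nucl_angle_requires_effective_mode(self, params):
        s = init_conformation(2, 42.0, params, seed=1)
        with pytest.raises(ValueError):
            energy_nucl_angle(s)

    def test_morse_matches_harmonic_curvature(self):
        p = ModelParams(morse=True, kh_tilde=50.0)
        s = init_conformation(2, 42.0, p, seed=1)
        pairs = np.array([[0, 1]])
        b = s.nucleosome_beads

        def at(r):
            s.pos[b[1]] = s.pos[b[0]] + [r, 0, 0]
            return energy_morse(s, pairs=pairs)

        assert at(p.rh) == pytest.approx(0.0)
        delta = 0.1 * p.a
        harm = 0.5 * p.kh * delta**2
        assert at(p.rh + delta) == pytest.approx(harm, rel=0.05)
        assert at(p.rh + 1e3) == pytest.approx(p.morse_D, rel=1e-6)

    def test_morse_requires_mode(self, params):
        s = init_conformation(2, 42.0, params, seed=1)
        with pytest.raises(ValueError):
            energy_morse(s)

    def test_total_energy_sum_order(self, params):
        s = init_conformation(3, 42.0, params, seed=2)
        rep = total_energy(s)
        assert rep.Utot == ((((rep.Us + rep.Un) + rep.Ul) + rep.Up)
                            + rep.Uh + rep.ULJ + rep.Ub)


class TestPairing:
    def _params(self, **kw):
        return ModelParams(**kw)

    def test_two_cores_within_cutoff(self):
        p = self._params()
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0]])    # 8a < 9a
        assert len(pair_nucleosomes(pos, p)) == 1

    def test_collinear_triplet_excludes_far_pair(self):
        # spacing 5a: (0,1) and (1,2) accepted; (0,2) at 10a > 9a excluded
        p = self._params()
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]])
        pairs = pair_nucleosomes(pos, p)
        assert sorted(map(tuple, pairs)) == [(0, 1), (1, 2)]

    def test_partner_cap(self):
        # 5 clustered cores: cap 2 limits the degree, cap 4 admits more
        rng = np.random.default_rng(3)
        pos = rng.normal(0, 0.8, (5, 3))
        pairs2 = pair_nucleosomes(pos, self._params(max_tail_partners=2))
        pairs4 = pair_nucleosomes(pos, self._params(max_tail_partners=4))
        deg2 = np.bincount(np.ravel(pairs2), minlength=5)
        assert deg2.max() <= 2
        assert len(pairs4) > len(pairs2)

    def test_greedy_prefers_closest(self):
        # cap 1: of the three possible pairs only the closest survives
        p = self._params(max_tail_partners=1)
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.5, 0, 0]])
        assert [tuple(x) for x in pair_nucleosomes(pos, p)] == [(0, 1)]


class TestForces:
    @pytest.mark.parametrize("mode,rho,morse", [
        ("explicit_core", 0.0, False),
        ("explicit_core", 1.0, False),
        ("explicit_core", 1.0, True),
        ("effective_angle", 1.0, False),
    ])
    def test_forces_match_numerical_gradient(self, mode, rho, morse):
        p = ModelParams(kh_tilde=50.0, morse=morse)
        s = init_conformation(3, 42.0, p, mode=mode, seed=2)
        if rho > 0:
            place_proteins(s, rho, seed=3)
        rng = np.random.default_rng(4)
        pos = s.pos + rng.normal(0, 0.05, s.pos.shape)
        pairs = pair_nucleosomes(pos[s.nucleosome_beads], p)
        f = forces(s, pos, pairs=pairs)
        h = 1e-6
        scale = max(np.abs(f).max(), 1.0)
        for i in range(0, pos.shape[0], 7):
            for c in range(3):
                pp = pos.copy(); pp[i, c] += h
                pm = pos.copy(); pm[i, c] -= h
                num = -(total_energy(s, pp, pairs).Utot
                        - total_energy(s, pm, pairs).Utot) / (2 * h)
                assert abs(f[i, c] - num) / scale < 1e-5


class TestDynamics:
    def test_zero_noise_rest_is_fixed_point(self, params):
        s = dna_chain_system(8, params)
        before = s.pos.copy()
        step(s, seed=1, noise=False)
        assert np.allclose(s.pos, before, atol=1e-14)

    def test_instability_aborts_with_diagnostic(self, params):
        s = dna_chain_system(2, params)
        s.pos[1, 0] = 3000.0          # absurd stretch -> huge force
        with pytest.raises(BDInstabilityError, match="timestep|dt"):
            step(s, seed=1)

    def test_zero_steps_returns_initial_conformation(self, params):
        res = run(4, 42.0, 0.0, 120.0, params, n_steps=0, sample_every=10,
                  seed=5)
        fresh = init_conformation(4, 42.0, params,
                                  seed=bd.spawn_seeds(5, 3)[0])
        assert np.array_equal(res.frames[0], fresh.pos)

    def test_run_produces_frames_and_energies(self, params):
        res = run(3, 42.0, 0.5, 120.0, params, n_steps=2000,
                  sample_every=500, seed=6, equil_steps=500)
        assert res.frames.shape == (4, res.system.n_beads, 3)
        assert res.nucleosome_trajectory.shape == (4, 3, 3)
        for col in ("Us", "Un", "Ul", "Up", "Uh", "ULJ", "Ub", "Utot", "Rg"):
            assert col in res.energies
        assert np.isfinite(res.energies.to_numpy()).all()

    def test_integration_reproducible(self, params):
        s1 = dna_chain_system(5, params)
        s2 = dna_chain_system(5, params)
        f1 = integrate_system(s1, 500, 100, seed=7)
        f2 = integrate_system(s2, 500, 100, seed=7)
        assert np.array_equal(f1, f2)
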