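"""Energy evaluators: exactness oracles, decompositions, forces."""

import numpy as np
import pytest

from zdsum.electrostatics import (
    ElectrostaticsConfig,
    evaluate,
    forces,
    resa_energy,
    shifted_force_energy,
    wolf_energy,
    zd_energy,
)
from zdsum.ewald import direct_cluster_energy
from zdsum.generators import make_cluster, make_electrolyte, make_water_lattice
from zdsum.neighbors import brute_force_pairs, cell_list_pairs
from zdsum.system import ParticleSystem
from zdsum.units import COULOMB

ZD12 = ElectrostaticsConfig(method="zd", r_c=12.0, alpha=0.0)


def random_neutral_zero_dipole_cluster(rng, n_half=2, spread=3.0):
    """Inversion-symmetric charge placement (same charge at ±p): the dipole
    of each mirror pair cancels, and equal +/− pair counts cancel the
    monopole."""
    plus = rng.uniform(-spread, spread, size=(n_half, 3))
    minus = rng.uniform(-spread, spread, size=(n_half, 3))
    spec = [(1.0, p) for p in plus] + [(1.0, -p) for p in plus]
    spec += [(-1.0, p) for p in minus] + [(-1.0, -p) for p in minus]
    return make_cluster(spec)


class TestZDExactness:
    def test_zero_dipole_cluster_equals_direct_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            cl = random_neutral_zero_dipole_cluster(rng)
            rep = zd_energy(cl, ZD12)
            direct = direct_cluster_energy(cl)
            assert rep.total == pytest.approx(direct, rel=1e-12)

    def test_dipolar_cluster_defect_is_analytic(self):
        """Deviation from the direct sum equals −k_C |D|² / (2 r_c³)."""
        rng = np.random.default_rng(1)
        pos = rng.uniform(-2.5, 2.5, size=(6, 3))
        charges = [1.0, 1.0, 1.0, -1.0, -1.0, -1.0]
        cl = make_cluster(list(zip(charges, pos)))
        rep = zd_energy(cl, ZD12)
        direct = direct_cluster_energy(cl)
        d = cl.dipole_moment()
        predicted = -COULOMB * float(d @ d) / (2 * 12.0**3)
        assert rep.total - direct == pytest.approx(predicted, rel=1e-10)

    def test_single_particle_self_term_only(self):
        s = make_cluster([(1.0, (0, 0, 0))])
        rep = zd_energy(s, ZD12)
        assert rep.components["pair_sum"] == 0.0
        assert rep.total == pytest.approx(rep.components["self_term"])
        assert rep.total == pytest.approx(-COULOMB * 3 / (4 * 12.0))


class TestWolf:
    def test_neutral_cluster_equals_direct_sum_at_alpha_zero(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-3, 3, size=(6, 3))
        cl = make_cluster(list(zip([1, -1, 1, -1, 1, -1], pos)))
        cfg = ElectrostaticsConfig(method="wolf", r_c=12.0, alpha=0.0)
        assert wolf_energy(cl, cfg).total == pytest.approx(
            direct_cluster_energy(cl), rel=1e-12
        )

    def test_wolf_and_shifted_force_differ(self):
        s = make_electrolyte(20, box=(30, 30, 30), rng_seed=3)
        e_w = wolf_energy(s, ElectrostaticsConfig(method="wolf", r_c=10.0)).total
        e_sf = shifted_force_energy(
            s, ElectrostaticsConfig(method="shifted_force", r_c=10.0)
        ).total
        assert e_w != pytest.approx(e_sf, rel=1e-6)


class TestResa:
    def _line(self, spacing):
        return ParticleSystem(
            positions=[[0, 0, 0], [spacing, 0, 0], [2 * spacing, 0, 0]],
            charges=[1.0, -1.0, 1.0],
            residue_id=[0, 1, 2],
            molecule_id=[0, 1, 2],
        )

    def test_everything_visible_equals_direct_sum(self):
        s = self._line(3.0)
        cfg = ElectrostaticsConfig(method="resa", r_c=12.0)
        assert resa_energy(s, cfg).total == pytest.approx(
            direct_cluster_energy(s), rel=1e-12
        )

    def test_disjoint_residues_beyond_cutoff_vanish(self):
        s = self._line(20.0)
        cfg = ElectrostaticsConfig(method="resa", r_c=12.0)
        assert resa_energy(s, cfg).total == 0.0

    def test_one_sided_visibility_half_weight(self):
        """B sees A and C; A and C cannot see each other: hand-built sum."""
        s = self._line(8.0)  # A-B 8, B-C 8, A-C 16 > r_c
        cfg = ElectrostaticsConfig(method="resa", r_c=12.0)
        # both sides see each other for A-B and B-C (full weight); A-C absent
        expected = COULOMB * ((1 * -1) / 8.0 + (-1 * 1) / 8.0)
        assert resa_energy(s, cfg).total == pytest.approx(expected, rel=1e-12)

    def test_asymmetric_pair_enters_at_half_weight(self):
        # two-atom residue B straddles the cutoff of single-atom residue A:
        # A sees residue B (via its near atom), B's far atom does not see A
        s = ParticleSystem(
            positions=[[0, 0, 0], [11, 0, 0], [14, 0, 0]],
            charges=[1.0, 1.0, -1.0],
            residue_id=[0, 1, 1],
            molecule_id=[0, 1, 1],
        )
        cfg = ElectrostaticsConfig(method="resa", r_c=12.0)
        # pairs: A-B1 (seen both ways: 1), A-B2 (A counts residue B fully,
        # B2's own sphere contains A? |14| > 12 -> no; weight ½),
        # B1-B2 intra-residue (1)
        expected = COULOMB * (
            1 / 11.0 + 0.5 * (-1) / 14.0 + (-1) / 3.0
        )
        assert resa_energy(s, cfg).total == pytest.approx(expected, rel=1e-12)

    def test_missing_residues_rejected(self):
        s = self._line(3.0)
        s.residue_id = None
        with pytest.raises(ValueError):
            resa_energy(s, ElectrostaticsConfig(method="resa", r_c=12.0))


class TestDecompositionAndForces:
    @pytest.mark.parametrize("method", ["zd", "wolf", "shifted_force", "resa"])
    def test_per_atom_sums_to_total(self, method):
        s = make_water_lattice(2, rng_seed=4)  # has exclusions
        cfg = ElectrostaticsConfig(method=method, r_c=3.0)
        rep = evaluate(s, cfg)
        assert rep.per_atom.sum() == pytest.approx(rep.total, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("method", ["zd", "wolf", "shifted_force", "resa"])
    def test_forces_match_finite_differences(self, method):
        s = make_electrolyte(25, box=(30, 30, 30), rng_seed=3)
        cfg = ElectrostaticsConfig(method=method, r_c=10.0, alpha=0.1)
        f = forces(s, cfg)
        h = 1e-5
        for i in (0, 13, 40):
            for d in range(3):
                p = s.positions.copy()
                p[i, d] += h
                ep = evaluate(s.with_positions(p), cfg).total
                p[i, d] -= 2 * h
                em = evaluate(s.with_positions(p), cfg).total
                fd = -(ep - em) / (2 * h)
                assert f[i, d] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("method", ["zd", "wolf", "shifted_force", "resa"])
    def test_newtons_third_law(self, method):
        s = make_electrolyte(30, box=(30, 30, 30), rng_seed=6)
        f = forces(s, ElectrostaticsConfig(method=method, r_c=10.0))
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_isolated_pair_at_cutoff_zero_zd_force(self):
        s = make_cluster([(1.0, (0, 0, 0)), (-1.0, (12.0, 0, 0))])
        f = forces(s, ZD12)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_exclusion_policy_removes_bare_coulomb_only(self):
        """Excluded pair inside r_c keeps the completion terms u(r) − 1/r."""
        s = ParticleSystem(
            positions=[[0, 0, 0], [2.0, 0, 0]],
            charges=[1.0, -1.0],
            molecule_id=[0, 0],
            residue_id=[0, 0],
            exclusions=[(0, 1)],
        )
        rep = zd_energy(s, ZD12)
        a, b = 1 / (2 * 12.0**3), -3 / (2 * 12.0)
        completion = COULOMB * (-1.0) * (a * 4.0 + b)
        self_term = -COULOMB * 3 / (4 * 12.0) * 2
        assert rep.total == pytest.approx(completion + self_term, rel=1e-12)


class TestCutoffValidation:
    def test_cutoff_beyond_half_box_rejected(self):
        s = make_electrolyte(5, box=(20, 30, 30), rng_seed=0)
        with pytest.raises(ValueError, match="half the shortest box edge"):
            zd_energy(s, ElectrostaticsConfig(method="zd", r_c=11.0))

    def test_open_cluster_allows_any_cutoff(self):
        cl = make_cluster([(1.0, (0, 0, 0)), (-1.0, (1, 0, 0))])
        zd_energy(cl, ElectrostaticsConfig(method="zd", r_c=100.0))

    def test_resa_forces_residue_mode(self):
        cfg = ElectrostaticsConfig(method="resa", r_c=12.0, cutoff_mode="atom_based")
        assert cfg.cutoff_mode == "residue_based"


class TestNeighborSearch:
    @pytest.mark.parametrize("n_pairs, box, r_c", [(60, 30.0, 6.0), (150, 45.0, 9.0)])
    def test_cell_list_matches_brute_force(self, n_pairs, box, r_c):
        s = make_electrolyte(n_pairs, box=(box, box, box), rng_seed=11)
        bi, bj, br = brute_force_pairs(s, r_c)
        ci, cj, cr = cell_list_pairs(s, r_c)
        brute = set(zip(bi.tolist(), bj.tolist()))
        cells = set(zip(ci.tolist(), cj.tolist()))
        assert brute == cells
        np.testing.assert_allclose(np.sort(br), np.sort(cr), rtol=1e-12)
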