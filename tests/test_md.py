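"""MD engine: conservation, determinism, thermostat behaviour."""

import numpy as np
import pytest

from zdsum.electrostatics import ElectrostaticsConfig
from zdsum.generators import make_coarse_duplex, make_electrolyte, make_water_lattice
from zdsum.md import (
    ForceField,
    MDConfig,
    maxwell_boltzmann_velocities,
    run_md,
    stability_demo,
)
from zdsum.system import ParticleSystem
from zdsum.units import KB, MASS_ACC


def harmonic_dimer(k=3.0, r0=2.0, stretch=0.5):
    return ParticleSystem(
        positions=[[0.0, 0.0, 0.0], [r0 + stretch, 0.0, 0.0]],
        charges=[0.0, 0.0],
        masses=[50.0, 50.0],
        bonded_terms={"bonds": [(0, 1, k, r0)]},
    )


class TestConservation:
    def test_harmonic_oscillator_energy_drift(self):
        """NVE total-energy drift ≤1e−5 over 10⁴ steps at 0.5 fs."""
        s = harmonic_dimer()
        ff = ForceField(bonds=list(s.bonded_terms["bonds"]))
        _, log = run_md(
            s,
            ff,
            MDConfig(dt_fs=0.5, n_steps=10_000, ensemble="NVE", target_T=30.0,
                     velocity_seed=4, log_stride=100),
        )
        e = log["total"].to_numpy()
        assert np.max(np.abs(e - e[0])) / abs(e[0]) <= 1e-5

    def test_frozen_start_stays_frozen(self):
        s = harmonic_dimer(stretch=0.0)
        ff = ForceField(bonds=list(s.bonded_terms["bonds"]))
        traj, log = run_md(
            s, ff, MDConfig(dt_fs=1.0, n_steps=100, ensemble="NVE", target_T=0.0,
                            velocity_seed=0, snapshot_stride=10),
        )
        np.testing.assert_allclose(traj.frames[-1], traj.frames[0], atol=1e-14)
        assert log["total"].std() == pytest.approx(0.0, abs=1e-14)

    def test_same_seed_bit_identical(self):
        s = make_electrolyte(10, box=(20, 20, 20), rng_seed=1)
        cfg = MDConfig(dt_fs=1.0, n_steps=200, target_T=300.0, velocity_seed=7)
        ff = ForceField.from_system(
            s, ElectrostaticsConfig(method="zd", r_c=8.0), lj_cutoff=8.0
        )
        _, log_a = run_md(s, ff, cfg)
        _, log_b = run_md(s, ff, cfg)
        np.testing.assert_array_equal(log_a["total"], log_b["total"])


class TestThermostat:
    def test_reaches_target_temperature(self):
        # uncharged LJ fluid: no condensation heat source, clean steady state
        s = make_electrolyte(30, box=(30, 30, 30), rng_seed=5)
        s.charges[:] = 0.0
        ff = ForceField.from_system(s, None, lj_cutoff=10.0)
        _, log = run_md(
            s, ff, MDConfig(dt_fs=0.5, n_steps=8000, ensemble="NVT", target_T=300.0,
                            tau_fs=100.0, velocity_seed=2, log_stride=50),
        )
        window = log["temperature"].to_numpy()[-40:]
        assert abs(window.mean() - 300.0) / 300.0 <= 0.10

    def test_velocity_init_matches_target_and_zero_momentum(self):
        rng = np.random.default_rng(0)
        masses = np.full(2000, 40.0)
        v = maxwell_boltzmann_velocities(masses, 300.0, rng)
        ke = 0.5 * MASS_ACC * np.sum(masses[:, None] * v**2)
        t = 2 * ke / (3 * len(masses) * KB)
        assert t == pytest.approx(300.0, rel=0.05)
        np.testing.assert_allclose((masses[:, None] * v).sum(axis=0), 0.0, atol=1e-9)


class TestStabilityDemo:
    def test_identical_methods_give_identical_traces(self):
        duplex = make_coarse_duplex(n_per_strand=5, rng_seed=6, box=(30, 30, 30))
        cfg = ElectrostaticsConfig(method="zd", r_c=10.0, alpha=0.0)
        out = stability_demo(
            duplex, cfg, cfg,
            MDConfig(dt_fs=2.0, n_steps=200, target_T=300.0, velocity_seed=9,
                     snapshot_stride=50),
        )
        np.testing.assert_array_equal(out["rmsd_a"], out["rmsd_b"])
        assert out["rmsd_a"][0] == pytest.approx(0.0, abs=1e-12)
        assert len(out["rmsd_a"]) == out["traj_a"].n_frames


class TestForceFieldAssembly:
    def test_water_lattice_force_field_finite_dynamics(self):
        s = make_water_lattice(2, spacing=3.2, rng_seed=8)
        ff = ForceField.from_system(
            s, ElectrostaticsConfig(method="zd", r_c=3.0), lj_cutoff=3.0
        )
        traj, log = run_md(
            s, ff, MDConfig(dt_fs=0.5, n_steps=300, target_T=300.0, velocity_seed=3),
        )
        assert np.isfinite(log["total"]).all()
        assert traj.frames.shape[1] == 24

    def test_bonded_finite_difference(self):
        s = make_water_lattice(1, rng_seed=2)
        ff = ForceField.from_system(s)  # LJ + bonds + angles, no electrostatics
        _, f = ff.energy_forces(s)
        h = 1e-6
        for i in range(3):
            for d in range(3):
                p = s.positions.copy()
                p[i, d] += h
                ep = ff.energy_forces(s.with_positions(p))[0]["potential"]
                p[i, d] -= 2 * h
                em = ff.energy_forces(s.with_positions(p))[0]["potential"]
                assert f[i, d] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5, abs=1e-5)

    def test_nonfinite_forces_reported_with_step(self):
        # coincident bonded particles: the bond direction d/r is 0/0
        s = ParticleSystem(
            positions=[[0, 0, 0], [0, 0, 0]],
            charges=[0.0, 0.0],
            masses=[1.0, 1.0],
        )
        ff = ForceField(bonds=[(0, 1, 100.0, 1.0)])
        with pytest.raises(RuntimeError, match="step"):
            run_md(s, ff, MDConfig(dt_fs=1.0, n_steps=10, ensemble="NVE",
                                   target_T=0.0, velocity_seed=1))
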