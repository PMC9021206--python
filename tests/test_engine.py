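import numpy as np
import pytest

from supramol import models
from supramol.constants import KB, SIGMA
from supramol.engine import (
    SimulationParams,
    _Integrator,
    forces,
    instantaneous_temperature,
    potential_energy,
    run_simulation,
    step_langevin,
)
from supramol.models import (
    BeadRole,
    BeadSpec,
    ForceField,
    LJPair,
    MonomerTopology,
    SystemConfiguration,
)


def lj_shifted(r, eps, sigma=SIGMA, rc=1.1):
    """Independent closed-form evaluation of the truncated-shifted LJ."""
    v = lambda x: 4 * eps * ((sigma / x) ** 12 - (sigma / x) ** 6)
    return v(r) - v(rc) if r < rc else 0.0


def single_bead_system(mass=72.0, box=10.0):
    topo = MonomerTopology(
        "M", [BeadSpec(0, BeadRole.CORE, mass)], [], [], np.zeros((1, 3))
    )
    cfg = SystemConfiguration(topo, 1, box, np.full((1, 3), box / 2), np.zeros(1, int))
    return topo, cfg


def core_pair_system(r, eps, box=20.0):
    """Two bare core beads at separation r (no bonded terms)."""
    topo = MonomerTopology(
        "M", [BeadSpec(0, BeadRole.CORE, 72.0)], [], [], np.zeros((1, 3))
    )
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]])
    # two single-bead "monomers" so the pair is non-bonded
    cfg = SystemConfiguration(topo, 2, box, pos, np.array([0, 1]))
    ff = ForceField([LJPair(BeadRole.CORE, BeadRole.CORE, eps)])
    return cfg, ff


class TestPotentialEnergy:
    def test_lj_vanishes_at_cutoff(self):
        cfg, ff = core_pair_system(1.1, eps=40.0)
        assert potential_energy(cfg, ff)["lj"] == pytest.approx(0.0, abs=1e-12)

    def test_lj_at_sigma_equals_minus_cutoff_shift(self):
        # at r = sigma the plain LJ is zero, so only the shift remains
        cfg, ff = core_pair_system(0.47, eps=40.0)
        expected = lj_shifted(0.47, 40.0)  # = 0.96761 kJ/mol
        assert expected == pytest.approx(0.9676, abs=5e-4)
        assert potential_energy(cfg, ff)["lj"] == pytest.approx(expected, rel=1e-12)

    def test_isolated_monomer_reference_energy(self, m_topology):
        ff = models.build_forcefield("M")
        cfg = SystemConfiguration(
            m_topology, 1, 30.0, m_topology.reference_geometry + 15.0,
            np.zeros(7, int),
        )
        assert potential_energy(cfg, ff)["bond"] == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_beads_rejected(self):
        cfg, ff = core_pair_system(1e-8, eps=40.0)
        with pytest.raises(ValueError, match="overlap"):
            potential_energy(cfg, ff)

    def test_translational_invariance(self, m_topology):
        ff = models.build_forcefield("M", 45.0)
        cfg = models.build_random_config(m_topology, 10, 8.0, 1.2, seed=4)
        e0 = potential_energy(cfg, ff)["total"]
        shifted = cfg.copy()
        shifted.positions = np.mod(shifted.positions + [1.3, -2.1, 0.7], 8.0)
        e1 = potential_energy(shifted, ff)["total"]
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestForces:
    @pytest.mark.parametrize("species,n,seed", [("M", 8, 0), ("BTA", 4, 1)])
    def test_matches_finite_differences(self, species, n, seed):
        topo = models.build_monomer(species)
        ff = models.build_forcefield(species)
        cfg = models.build_random_config(topo, n, 7.0, 1.2, seed=seed)
        f = forces(cfg, ff)
        h = 1e-6
        rng = np.random.default_rng(seed)
        beads = rng.choice(cfg.n_beads, size=6, replace=False)
        for b in beads:
            for d in range(3):
                up, dn = cfg.copy(), cfg.copy()
                up.positions[b, d] += h
                dn.positions[b, d] -= h
                fd = -(potential_energy(up, ff)["total"]
                       - potential_energy(dn, ff)["total"]) / (2 * h)
                assert fd == pytest.approx(f[b, d], rel=1e-4, abs=1e-4)

    def test_zero_force_at_lj_minimum(self):
        cfg, ff = core_pair_system(2 ** (1 / 6) * SIGMA, eps=40.0)
        f = forces(cfg, ff)
        assert np.abs(f).max() < 1e-8

    def test_newtons_third_law(self):
        cfg, ff = core_pair_system(0.55, eps=40.0)
        f = forces(cfg, ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_pair_list_path_equals_all_pairs(self, m_topology):
        """The Verlet-list kernel must reproduce the all-pairs oracle."""
        ff = models.build_forcefield("M", 45.0)
        cfg = models.build_random_config(m_topology, 25, 9.0, 1.2, seed=6)
        params = SimulationParams(seed=0)
        integ = _Integrator(cfg, ff, params)
        np.testing.assert_allclose(integ.fbuf, forces(cfg, ff),
                                   rtol=1e-10, atol=1e-10)


class TestLangevin:
    def test_velocity_decay_at_zero_temperature(self):
        """Free particle at T = 0 obeys v(t) = v0 exp(-t / tau_t)."""
        topo, cfg = single_bead_system()
        cfg.velocities = np.array([[1.0, 0.0, 0.0]])
        params = SimulationParams(dt=0.002, tau_t=0.1, temperature=0.0, seed=1)
        out = step_langevin(cfg, ForceField([]), params, 100)  # t = 0.2 ps
        assert out.velocities[0, 0] == pytest.approx(np.exp(-2.0), rel=1e-9)

    def test_equipartition_at_300K(self):
        """Mean kinetic energy per dof equals kB T / 2 within 3 SE."""
        topo, cfg = single_bead_system()
        params = SimulationParams(dt=0.02, tau_t=0.1, temperature=300.0, seed=2)
        integ = _Integrator(cfg, ForceField([]), params)
        samples = []
        for _ in range(6000):
            integ.advance(5)  # 0.1 ps = tau_t between samples (decorrelated)
            samples.append(0.5 * 72.0 * np.sum(integ.vel**2) / 3.0)
        samples = np.array(samples[500:])
        target = 0.5 * KB * 300.0
        # KE/dof is chi2_1-distributed: var = 2 target^2; samples ~independent
        se = np.sqrt(2.0) * target / np.sqrt(len(samples))
        assert abs(samples.mean() - target) < 3 * se

    def test_bit_reproducible_under_seed(self, m_topology):
        ff = models.build_forcefield("M", 45.0)
        cfg = models.build_random_config(m_topology, 10, 8.0, 1.2, seed=3)
        params = SimulationParams(dt=0.02, temperature=300.0, seed=7)
        a = step_langevin(cfg, ff, params, 500)
        b = step_langevin(cfg, ff, params, 500)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_zero_step_run_returns_input(self, m_topology):
        ff = models.build_forcefield("M", 45.0)
        cfg = models.build_random_config(m_topology, 5, 8.0, 1.2, seed=3)
        params = SimulationParams(dt=0.02, temperature=300.0, seed=7,
                                  n_steps=0, sample_interval=0.3)
        frames = run_simulation(cfg, ff, params)
        assert len(frames) == 1
        np.testing.assert_array_equal(frames[0].positions,
                                      np.mod(cfg.positions, cfg.box_length))

    def test_energy_conservation_in_nve_limit(self, m_topology):
        """With no noise (T = 0) and negligible friction the splitting
        reduces to velocity Verlet; total energy drifts < 0.1% over 1e5
        steps of a bound two-monomer system."""
        ff = models.build_forcefield("M", 50.0)
        cfg = models.build_stacked_config(m_topology, 1, 2, 0.53, 10.0, seed=1)
        rng = np.random.default_rng(5)
        cfg.velocities = rng.normal(scale=0.05, size=(14, 3))
        params = SimulationParams(dt=0.01, tau_t=1e12, temperature=0.0, seed=1)
        integ = _Integrator(cfg, ff, params)
        masses = integ.masses

        def total_energy():
            ke = 0.5 * np.sum(masses[:, None] * integ.vel**2)
            return ke + potential_energy(integ.snapshot(), ff)["total"]

        e0 = total_energy()
        integ.advance(100_000)
        e1 = total_energy()
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_strongly_bound_dimer_stays_assembled(self, m_topology):
        """A pre-stacked dimer at eps = 50 (~20 kT) survives 2 ns intact."""
        from supramol.clustering import ClusteringParams, detect_assemblies

        ff = models.build_forcefield("M", 50.0)
        cfg = models.build_stacked_config(m_topology, 1, 2, 0.5, 10.0, seed=1)
        params = SimulationParams(dt=0.02, temperature=300.0, seed=4,
                                  n_steps=100_000, sample_interval=10.0)
        frames = run_simulation(cfg, ff, params)
        n_clustered = 0
        for fr in frames:
            sysfr = SystemConfiguration(m_topology, 2, 10.0, fr.positions,
                                        cfg.monomer_index)
            part = detect_assemblies(sysfr, params=ClusteringParams(0.6))
            n_clustered += part.n_assemblies == 1
        assert n_clustered / len(frames) >= 0.99

    def test_instantaneous_temperature_helper(self):
        masses = np.full(100, 72.0)
        rng = np.random.default_rng(0)
        vel = rng.normal(scale=np.sqrt(KB * 300.0 / 72.0), size=(100, 3))
        assert instantaneous_temperature(masses, vel) == pytest.approx(300.0, rel=0.2)
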