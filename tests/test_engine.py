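"""Engine physics oracles: integration, thermostats, constraints,
electrostatics, confinement."""

import math

import numpy as np
import pytest

from cgtribo.builder import (MoleculeTemplate, SystemState,
                             build_polarizable_water)
from cgtribo.engine import (ConfigError, CoulombConfig, Engine,
                            IntegratorConfig, LoadSlideConfig, WallConfig,
                            coulomb_energy, radius_of_gyration, sample_rg)
from cgtribo.forcefield import BeadType, LJPairTable
from cgtribo.units import F_COULOMB, KB


def _free_bead(box=20.0, mass=72.0):
    tpl = MoleculeTemplate("P", [BeadType("A", mass)], np.full((1, 3), box / 2))
    st = SystemState([box] * 3)
    st.add_molecule(tpl)
    return st


def _harmonic_dimer(k=1000.0, r0=0.47, stretch=0.05, mass=72.0):
    tpl = MoleculeTemplate("D", [BeadType("A", mass)] * 2,
                           np.array([[5.0, 5, 5], [5 + r0 + stretch, 5, 5]]),
                           bonds=[(0, 1, r0, k)])
    st = SystemState([10.0] * 3)
    st.add_molecule(tpl)
    return st


def _lj_dimer(eps=2.0, sep=0.6):
    tpl = MoleculeTemplate("LJ2", [BeadType("A", 72, lj_class="P4")] * 2,
                           np.array([[5.0, 5, 5], [5 + sep, 5, 5]]))
    st = SystemState([12.0] * 3)
    st.add_molecule(tpl)
    return st, LJPairTable({("P4", "P4"): (eps, 0.47)})


def _lj_fluid(n=50, box=8.0, seed=0, eps=2.0):
    rng = np.random.default_rng(seed)
    tpl = MoleculeTemplate("F", [BeadType("A", 72, lj_class="P4")], np.zeros((1, 3)))
    st = SystemState([box] * 3)
    placed = 0
    while placed < n:
        cand = rng.uniform(0, box, 3)
        if st.n_beads:
            d = st.pos - cand
            d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=1)) < 0.45:
                continue
        st.add_molecule(tpl, cand.reshape(1, 3))
        placed += 1
    return st, LJPairTable({("P4", "P4"): (eps, 0.47)})


class TestNVE:
    def test_free_bead_uniform_motion(self):
        st = _free_bead()
        st.vel[0] = [0.1, -0.05, 0.02]
        x0, v = st.pos[0].copy(), st.vel[0].copy()
        eng = Engine(st, integrator=IntegratorConfig(dt=0.01))
        for _ in range(1000):
            eng.step()
        assert np.allclose(st.pos[0], x0 + v * 10.0, atol=1e-10)

    def test_harmonic_dimer_period(self):
        """Oscillation period matches 2*pi*sqrt(m_eff/k_eff) within 0.1%
        (E = K d^2 means spring constant 2K; reduced mass m/2)."""
        k, m = 1000.0, 72.0
        st = _harmonic_dimer(k=k, mass=m)
        period = 2 * math.pi * math.sqrt((m / 2) / (2 * k))
        dt = period / 1000
        eng = Engine(st, integrator=IntegratorConfig(dt=dt))
        sep = []
        for _ in range(2500):
            eng.step()
            sep.append(st.pos[1, 0] - st.pos[0, 0])
        d = np.asarray(sep) - 0.47
        crossings = []
        for i in range(1, len(d)):
            if d[i - 1] < 0 <= d[i]:
                crossings.append((i - 1 - d[i - 1] / (d[i] - d[i - 1])) * dt)
        measured = np.diff(crossings).mean()
        assert measured == pytest.approx(period, rel=1e-3)

    def test_lj_dimer_energy_conservation(self):
        """Total-energy drift < 1e-4 relative over 1e5 steps at dt = 5 fs."""
        st, table = _lj_dimer()
        eng = Engine(st, lj_table=table, integrator=IntegratorConfig(dt=0.005))
        log = eng.run(100_000, sample_every=2000, store_frames=False)
        e = np.asarray(log.scalars["e_total"])
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-4

    def test_momentum_conservation(self):
        st, table = _lj_fluid(n=20, box=6.0)
        rng = np.random.default_rng(1)
        st.vel = rng.normal(0, 0.2, st.vel.shape)
        st.vel -= st.vel.mean(axis=0)
        eng = Engine(st, lj_table=table, integrator=IntegratorConfig(dt=0.005))
        p0 = (st.mass[:, None] * st.vel).sum(axis=0)
        for _ in range(200):
            eng.step()
        p1 = (st.mass[:, None] * st.vel).sum(axis=0)
        assert np.allclose(p1, p0, atol=200 * 1e-10)

    def test_time_reversibility(self):
        st, table = _lj_fluid(n=12, box=6.0, seed=2)
        rng = np.random.default_rng(3)
        st.vel = rng.normal(0, 0.15, st.vel.shape)
        pos0 = st.pos.copy()
        eng = Engine(st, lj_table=table, integrator=IntegratorConfig(dt=0.004))
        for _ in range(500):
            eng.step()
        st.vel *= -1
        eng.forces, eng.e_pot = eng.compute_forces()
        for _ in range(500):
            eng.step()
        assert np.allclose(st.pos, pos0, atol=1e-7)

    def test_determinism(self):
        def run():
            st, table = _lj_fluid(n=15, box=6.0, seed=4)
            cfg = IntegratorConfig(dt=0.005, thermostat="langevin", seed=9)
            eng = Engine(st, lj_table=table, integrator=cfg)
            log = eng.run(300, sample_every=50)
            return log.frames[-1], np.asarray(log.scalars["e_total"])

        f1, e1 = run()
        f2, e2 = run()
        assert np.array_equal(f1, f2)
        assert np.array_equal(e1, e2)


class TestThermostats:
    def test_langevin_temperature(self):
        """Time-averaged kinetic temperature within 1% of the 300 K target
        over a >= 1 ns-equivalent dilute-LJ-fluid run."""
        st, table = _lj_fluid(n=40, box=10.0, seed=5, eps=1.0)
        cfg = IntegratorConfig(dt=0.01, thermostat="langevin", t_target=300.0,
                               damping=1.0, seed=6)
        eng = Engine(st, lj_table=table, integrator=cfg)
        eng.run(20_000, sample_every=20_000, store_frames=False)  # equilibrate
        log = eng.run(100_000, sample_every=25, store_frames=False)
        t_mean = np.mean(log.scalars["temperature"])
        assert t_mean == pytest.approx(300.0, rel=0.01)

    def test_axis_restricted_langevin_leaves_other_axes_unperturbed(self):
        st = _free_bead()
        cfg = IntegratorConfig(dt=0.005, thermostat="langevin", t_target=300.0,
                               damping=1.0, thermostat_axes=("y",), seed=7)
        eng = Engine(st, integrator=cfg)
        for _ in range(2000):
            eng.step()
        assert st.vel[0, 0] == 0.0
        assert st.vel[0, 2] == 0.0
        assert st.vel[0, 1] != 0.0

    def test_zero_target_overdamps_single_bead(self):
        st = _free_bead()
        st.vel[0] = [0.3, -0.2, 0.1]
        cfg = IntegratorConfig(dt=0.005, thermostat="langevin", t_target=0.0,
                               damping=1.0, seed=8)
        eng = Engine(st, integrator=cfg)
        norms = []
        for _ in range(800):
            eng.step()
            norms.append(np.linalg.norm(st.vel[0]))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.01

    def test_nose_hoover_reaches_target(self):
        st, table = _lj_fluid(n=32, box=7.0, seed=9)
        rng = np.random.default_rng(10)
        st.vel = rng.normal(0, math.sqrt(KB * 250 / 72), st.vel.shape)
        cfg = IntegratorConfig(dt=0.01, thermostat="nose-hoover", t_target=300.0,
                               damping=1.0, seed=11)
        eng = Engine(st, lj_table=table, integrator=cfg)
        eng.run(10_000, sample_every=10_000, store_frames=False)
        log = eng.run(40_000, sample_every=50, store_frames=False)
        assert np.mean(log.scalars["temperature"]) == pytest.approx(300.0, rel=0.08)

    def test_maxwellian_velocities(self):
        """Equilibrium NVT velocity components are Gaussian: a normality
        test on pooled components must not reject at alpha = 0.01."""
        from scipy import stats

        st, table = _lj_fluid(n=40, box=10.0, seed=12, eps=1.0)
        cfg = IntegratorConfig(dt=0.01, thermostat="langevin", t_target=300.0,
                               damping=0.5, seed=13)
        eng = Engine(st, lj_table=table, integrator=cfg)
        eng.run(5_000, sample_every=5_000, store_frames=False)
        samples = []
        for _ in range(90):
            eng.run(100, sample_every=100, store_frames=False)
            samples.append(st.vel.ravel().copy())
        pooled = np.concatenate(samples)[:10_000]
        stat, p = stats.normaltest(pooled)
        assert p > 0.01

    def test_empty_group_rejected(self):
        st = _free_bead()
        st.add_group("empty", np.zeros(1, dtype=bool))
        cfg = IntegratorConfig(thermostat="langevin", thermostat_group="empty")
        with pytest.raises(ConfigError, match="empty"):
            Engine(st, integrator=cfg)


class TestShake:
    def test_water_constraints_hold_to_tolerance(self):
        st = SystemState([5.0] * 3)
        st.add_molecule(build_polarizable_water())
        rng = np.random.default_rng(14)
        st.vel = rng.normal(0, 0.3, st.vel.shape)
        eng = Engine(st, integrator=IntegratorConfig(dt=0.005, shake_tol=1e-8))
        for _ in range(500):
            eng.step()
            d1 = np.linalg.norm(st.pos[0] - st.pos[1])
            d2 = np.linalg.norm(st.pos[0] - st.pos[2])
            assert abs(d1 - 0.14) < 1e-6
            assert abs(d2 - 0.14) < 1e-6

    def test_satisfied_constraints_are_fixed_point(self):
        from cgtribo.engine import shake_constraints

        pos = np.array([[0.0, 0, 0], [0.14, 0, 0]])
        out = shake_constraints(pos.copy(), pos.copy(),
                                np.array([[0, 1]]), np.array([0.14]),
                                np.array([1 / 24.0, 1 / 24.0]))
        assert np.array_equal(out, pos)

    def test_stretched_dimer_relaxes_com_fixed(self):
        from cgtribo.engine import shake_constraints

        pos = np.array([[0.0, 0, 0], [0.20, 0, 0]])
        ref = pos.copy()
        m = np.array([24.0, 48.0])
        out = shake_constraints(pos.copy(), ref, np.array([[0, 1]]),
                                np.array([0.14]), 1 / m, tol=1e-12)
        assert np.linalg.norm(out[0] - out[1]) == pytest.approx(0.14, abs=1e-10)
        com_before = m @ ref / m.sum()
        com_after = m @ out / m.sum()
        assert np.allclose(com_before, com_after, atol=1e-12)

    def test_momentum_conserved_with_constraints(self):
        st = SystemState([5.0] * 3)
        st.add_molecule(build_polarizable_water())
        rng = np.random.default_rng(15)
        st.vel = rng.normal(0, 0.3, st.vel.shape)
        p0 = (st.mass[:, None] * st.vel).sum(axis=0)
        eng = Engine(st, integrator=IntegratorConfig(dt=0.005))
        for _ in range(300):
            eng.step()
        p1 = (st.mass[:, None] * st.vel).sum(axis=0)
        assert np.allclose(p1, p0, atol=1e-9)


class TestCoulomb:
    def _pair(self, q1, q2, sep=0.5, box=100.0):
        tpl = MoleculeTemplate(
            "ION2",
            [BeadType("I1", 72, charge=q1, lj_class="Q"),
             BeadType("I2", 72, charge=q2, lj_class="Q")],
            np.array([[50.0, 50, 50], [50 + sep, 50, 50]]))
        st = SystemState([box] * 3)
        st.add_molecule(tpl)
        return st

    def test_like_charges_repel(self):
        st = self._pair(+1, +1)
        e, f = coulomb_energy(st, CoulombConfig(r_cut=3.0))
        assert e > 0
        assert f[0, 0] < 0 < f[1, 0]  # pushed apart along x

    def test_neutral_pair_zero(self):
        st = self._pair(0, 0)
        e, f = coulomb_energy(st, CoulombConfig(r_cut=3.0))
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_vacuum_analytic_limit(self):
        """Undamped, large cutoff: energy approaches k_e q1 q2 / r."""
        st = self._pair(+1, -1, sep=0.5, box=10_000.0)
        e, _ = coulomb_energy(st, CoulombConfig(r_cut=4000.0, dielectric=1.0))
        assert e == pytest.approx(-F_COULOMB / 0.5, rel=1e-3)

    def test_continuity_at_cutoff(self):
        cfg = CoulombConfig(r_cut=1.2, alpha=1.0)
        e1, _ = coulomb_energy(self._pair(1, -1, sep=1.19999), cfg)
        e2, _ = coulomb_energy(self._pair(1, -1, sep=1.20001), cfg)
        assert abs(e1) < 1e-6
        assert e2 == 0.0

    def test_cutoff_exceeding_box_rejected(self):
        st = self._pair(1, -1, box=2.0, sep=0.5)
        with pytest.raises(ConfigError, match="cutoff"):
            coulomb_energy(st, CoulombConfig(r_cut=1.5))


class TestConfined:
    def _film(self, n_fluid=40, gap=2.5, seed=0):
        from cgtribo.protocols import _wall_layer

        lx = ly = 2.5
        lower = _wall_layer(lx, ly, 0.45, 0.0, "lower_anchor")
        upper = _wall_layer(lx, ly, 0.45, gap, "upper_anchor")
        rng = np.random.default_rng(seed)
        tpl = MoleculeTemplate("F", [BeadType("F", 72, lj_class="P4")],
                               np.zeros((1, 3)))
        fluid = SystemState([lx, ly, 40.0], periodic=(True, True, False))
        placed = 0
        while placed < n_fluid:
            cand = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                             rng.uniform(0.4, gap - 0.4)])
            if fluid.n_beads:
                d = fluid.pos - cand
                d[:, 0] -= lx * np.round(d[:, 0] / lx)
                d[:, 1] -= ly * np.round(d[:, 1] / ly)
                if np.min(np.linalg.norm(d, axis=1)) < 0.44:
                    continue
            fluid.add_molecule(tpl, cand.reshape(1, 3), species="fluid")
            placed += 1
        lower.merge(fluid)
        lower.merge(upper)
        lower.box[2] = gap + 2.0
        table = LJPairTable({("P4", "P4"): (3.0, 0.47), ("C1", "P4"): (3.0, 0.47),
                             ("C1", "C1"): (3.0, 0.47)})
        return lower, table

    def test_missing_anchor_group_rejected(self):
        st, table = _lj_fluid(n=5, box=5.0)
        eng = Engine(st, lj_table=table)
        with pytest.raises(ConfigError, match="anchor"):
            eng.run_confined(LoadSlideConfig(), 10)

    def test_unloaded_empty_gap_constant(self):
        from cgtribo.protocols import _wall_layer

        lower = _wall_layer(2.0, 2.0, 0.5, 0.0, "lower_anchor")
        upper = _wall_layer(2.0, 2.0, 0.5, 3.0, "upper_anchor")
        lower.merge(upper)
        lower.box[2] = 5.0
        table = LJPairTable({("C1", "C1"): (2.0, 0.47)})
        eng = Engine(lower, lj_table=table, integrator=IntegratorConfig(dt=0.005))
        log = eng.run_confined(LoadSlideConfig(sigma=0.0, v_s=0.0), 2000,
                               sample_every=100)
        gaps = np.asarray(log.scalars["gap"])
        assert np.allclose(gaps, 3.0, atol=1e-6)

    def test_normal_force_balance(self):
        """Time-averaged normal force transmitted to the frozen lower anchor
        equals the applied load sigma * A within 5%."""
        from cgtribo.units import MPA

        st, table = self._film(seed=1)
        cfg = IntegratorConfig(dt=0.008, thermostat="langevin", t_target=300.0,
                               damping=1.0, thermostat_axes=("y",), seed=2)
        eng = Engine(st, lj_table=table, integrator=cfg)
        sigma = 20.0  # MPa
        load = LoadSlideConfig(sigma=sigma, v_s=0.0)
        eng.run_confined(load, 15_000, sample_every=15_000)  # settle
        log = eng.run_confined(load, 40_000, sample_every=20)
        fz = np.mean(log.scalars["f_lower_z"])
        area = st.box[0] * st.box[1]
        expected = -sigma * MPA * area  # film pushes the lower wall down
        assert fz == pytest.approx(expected, rel=0.05)


class TestRg:
    def test_single_bead_zero(self):
        st = _free_bead()
        eng = Engine(st, integrator=IntegratorConfig(dt=0.01))
        log = eng.run(10, sample_every=5)
        assert np.all(sample_rg(log, st, 0) == 0.0)

    def test_two_bead_half_distance(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                                  np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_unwrapping_across_boundary(self):
        st = _harmonic_dimer()
        st.pos[0] = [0.1, 5, 5]
        st.pos[1] = [9.8, 5, 5]  # bonded pair wrapped across x
        eng = Engine(st, integrator=IntegratorConfig(dt=0.005))
        log = eng.run(0, sample_every=1)
        rg = sample_rg(log, st, 0)[0]
        assert rg == pytest.approx(0.15, abs=1e-9)  # true separation 0.3 nm

    def test_missing_molecule(self):
        st = _free_bead()
        eng = Engine(st, integrator=IntegratorConfig())
        log = eng.run(1, sample_every=1)
        with pytest.raises(ValueError, match="no molecule"):
            sample_rg(log, st, 99)


class TestWall:
    def test_harmonic_wall_confines(self):
        st = _free_bead(box=6.0)
        st.vel[0] = [0, 0, 0.5]
        eng = Engine(st, wall=WallConfig(z_lo=0.0, z_hi=4.0, k=200.0),
                     integrator=IntegratorConfig(dt=0.005))
        zs = []
        for _ in range(4000):
            eng.step()
            zs.append(st.pos[0, 2])
        assert max(zs) < 4.5  # bounced back by the top wall
        assert min(zs) > -0.5
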