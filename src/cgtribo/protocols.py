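"""Composed workflows: the adsorption -> squeeze-out -> sliding protocol at
desk scale, plus the validation experiments used throughout the test suite
(closed-loop inversion, Couette shear, Rg-Mw scaling).

These functions wire the builder, engine, mapping and analysis modules
together; every experiment is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analysis, fixtures, mapping
from .builder import (ChainSpec, SurfaceSpec, SystemState, assemble_bulk,
                      build_cgg_chain, build_graft_surface, build_polarizable_water,
                      build_sds, make_contact, MoleculeTemplate)
from .forcefield import BeadType, LJPairTable, ShiftSpec
from .engine import (CoulombConfig, Engine, IntegratorConfig, LoadSlideConfig,
                     TrajectoryLog, minimize_energy)
from .mapping import BondedTopology, MappingScheme, BeadDef

__all__ = [
    "default_scheme",
    "default_targets",
    "closed_loop_inversion",
    "couette_experiment",
    "ideal_chain_rg_experiment",
    "excluded_volume_rg_experiment",
    "confined_film_protocol",
]


def default_scheme() -> MappingScheme:
    """A small two-bead-per-residue mapping used by the inversion fixtures."""
    return MappingScheme(residues={
        "GUA": [
            BeadDef("B1", "P4", atoms=("C1", "C2", "O1", "O2"),
                    masses=(12.011, 12.011, 15.999, 15.999)),
            BeadDef("B2", "P1", atoms=("C3", "C4", "O3", "O4"),
                    masses=(12.011, 12.011, 15.999, 15.999)),
        ]})


def default_targets(temperature: float = 300.0) -> fixtures.BondedTargets:
    """Reference bonded parameters for the inversion round trips: stiff,
    short saccharide-like bonds and a mid-range bending angle."""
    return fixtures.BondedTargets(
        bonds={"P4-P1": (0.47, 5000.0), "P1-P4": (0.47, 5000.0)},
        angles={"P4-P1-P4": (120.0, 25.0), "P1-P4-P1": (120.0, 25.0)},
        temperature=temperature,
    )


@dataclass
class ClosedLoopResult:
    fitted: "mapping.BondedParameterTable"
    reference: mapping.DistributionSet
    simulated: mapping.DistributionSet
    report: "object"  # pandas DataFrame: per-type overlap

    @property
    def min_overlap(self) -> float:
        return float(self.report["overlap"].min())


def _chain_state_from_types(bead_types: list[str], table, box_size: float = 100.0,
                            spacing: float = 0.47) -> SystemState:
    """Bonded-only linear chain state with parameters looked up per type."""
    n = len(bead_types)
    types = [BeadType(t, mass=45.0) for t in bead_types]
    pos = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    pos += box_size / 2.0
    bonds = []
    for i in range(n - 1):
        r0, k = table.bond(bead_types[i], bead_types[i + 1])
        bonds.append((i, i + 1, r0, k))
    angles = []
    for i in range(n - 2):
        t0, k = table.angle(bead_types[i], bead_types[i + 1], bead_types[i + 2])
        angles.append((i, i + 1, i + 2, t0, k))
    tpl = MoleculeTemplate(name="CHAIN", bead_types=types, positions=pos,
                           bonds=bonds, angles=angles)
    state = SystemState(box=np.full(3, box_size))
    state.add_molecule(tpl)
    return state


def closed_loop_inversion(n_frames: int = 20000, seed: int = 0,
                          n_residues: int = 6, temperature: float = 300.0,
                          md_steps: int = 150_000, sample_every: int = 25,
                          n_chains: int = 8) -> ClosedLoopResult:
    """Generate -> map -> fit -> simulate -> collect -> compare.

    A pseudo-atomistic trajectory with known bonded Boltzmann statistics
    is mapped and inverted; a bonded-only chain is then simulated with the
    fitted parameters and its bond/angle distributions are compared to the
    generating ones (overlap coefficient per type).  ``n_chains``
    independent replica chains are integrated in one box (no nonbonded
    terms, so they do not interact) to multiply the sampling.
    """
    scheme = default_scheme()
    targets = default_targets(temperature)
    pseudo = fixtures.gen_pseudo_atomistic_traj(scheme, targets, n_frames, seed,
                                                n_residues=n_residues)
    mapped = mapping.map_trajectory(pseudo.trajectory, scheme)
    ref = mapping.collect_distributions(mapped, pseudo.topology, temperature)
    table = mapping.fit_parameter_table(ref, jacobian=True)

    state = _chain_state_from_types(pseudo.bead_types, table)
    chain_topo = pseudo.topology
    multi = SystemState(box=state.box)
    for c in range(n_chains):
        shifted = state.copy()
        shifted.pos[:, 1] += 2.0 * c
        multi.merge(shifted)
    cfg = IntegratorConfig(dt=0.005, thermostat="langevin", t_target=temperature,
                           damping=0.5, seed=seed + 1)
    eng = Engine(multi, lj_table=None, integrator=cfg)
    log = eng.run(md_steps, sample_every=sample_every)
    # burn-in: drop the first fifth
    frames = log.frames[len(log.frames) // 5:]

    n_per = len(pseudo.bead_types)
    topo = BondedTopology()
    for c in range(n_chains):
        off = c * n_per
        topo.bonds += [(i + off, j + off, lbl) for i, j, lbl in chain_topo.bonds]
        topo.angles += [(i + off, j + off, k + off, lbl)
                        for i, j, k, lbl in chain_topo.angles]
    sim_traj = mapping.MappedTrajectory(
        bead_names=[f"b{i}" for i in range(multi.n_beads)],
        bead_types=list(multi.type_names), bead_masses=multi.mass.copy(),
        frames=frames, boxes=[multi.box])
    sim = mapping.collect_distributions(sim_traj, topo, temperature)
    report = mapping.compare_distributions(ref, sim, bins=50)
    return ClosedLoopResult(fitted=table, reference=ref, simulated=sim, report=report)


# ----------------------------------------------------------------------
# Couette shear of a toy LJ film
# ----------------------------------------------------------------------

@dataclass
class CouetteResult:
    log: TrajectoryLog
    profile: analysis.Profile
    r_squared: float
    slope: float
    state: SystemState


def _wall_layer(lx: float, ly: float, spacing: float, z: float, tag: str,
                jitter: float = 0.0, rng: np.random.Generator | None = None
                ) -> SystemState:
    """A square-lattice wall sheet; ``jitter`` adds quenched positional
    disorder (atomic-scale roughness) so a fluid cannot slip freely."""
    nx = max(1, int(round(lx / spacing)))
    ny = max(1, int(round(ly / spacing)))
    xs = (np.arange(nx) + 0.5) * lx / nx
    ys = (np.arange(ny) + 0.5) * ly / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.full(nx * ny, z)])
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pos += rng.uniform(-jitter, jitter, size=pos.shape)
        pos[:, 2] = np.clip(pos[:, 2], min(z, z - jitter), max(z, z + jitter))
    tpl = MoleculeTemplate(name="WALL",
                           bead_types=[BeadType("WAL", 72.0, lj_class="C1")] * nx * ny,
                           positions=pos)
    st = SystemState(box=[lx, ly, 40.0], periodic=(True, True, False))
    idx = st.add_molecule(tpl, species="wall")
    st.add_group(tag, np.zeros(st.n_beads, dtype=bool))
    st.groups[tag][idx] = True
    return st


def couette_film(lx: float = 2.5, ly: float = 2.5, gap: float = 5.0,
                 n_fluid: int = 210, seed: int = 0,
                 wall_eps: float = 8.0, fluid_eps: float = 4.0
                 ) -> tuple[SystemState, LJPairTable]:
    """A dense LJ fluid film between two rough single-layer walls.

    Wall beads carry quenched positional disorder and a stronger
    wall-fluid attraction than the fluid-fluid one, giving a no-slip
    boundary at the desk scale.
    """
    rng = np.random.default_rng(seed)
    lower = _wall_layer(lx, ly, 0.40, 0.0, "lower_anchor", jitter=0.1, rng=rng)
    upper = _wall_layer(lx, ly, 0.40, gap, "upper_anchor", jitter=0.1, rng=rng)
    fluid_tpl = MoleculeTemplate(name="LJF",
                                 bead_types=[BeadType("LJF", 72.0, lj_class="P4")],
                                 positions=np.zeros((1, 3)))
    fluid = SystemState(box=[lx, ly, 40.0], periodic=(True, True, False))
    walls = np.vstack([lower.pos, upper.pos])
    placed = 0
    attempts = 0
    while placed < n_fluid and attempts < 400000:
        attempts += 1
        cand = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                         rng.uniform(0.35, gap - 0.35)])
        others = np.vstack([walls, fluid.pos]) if fluid.n_beads else walls
        d = others - cand
        for ax in range(2):
            d[:, ax] -= [lx, ly][ax] * np.round(d[:, ax] / [lx, ly][ax])
        if np.min(np.linalg.norm(d, axis=1)) < 0.40:
            continue
        fluid.add_molecule(fluid_tpl, cand.reshape(1, 3), species="fluid")
        placed += 1
    state = lower
    state.merge(fluid)
    state.merge(upper)
    state.box[2] = gap + 2.0
    table = LJPairTable({("P4", "P4"): (fluid_eps, 0.47),
                         ("C1", "P4"): (wall_eps, 0.47),
                         ("C1", "C1"): (fluid_eps, 0.47)})
    return state, table


def couette_experiment(v_s: float = 100.0, sigma: float = 10.0,
                       n_steps: int = 150_000, warmup_frac: float = 0.3,
                       seed: int = 0, dt: float = 0.008,
                       bins: float = 0.28, margin: float = 0.9) -> CouetteResult:
    """Shear a toy LJ film and fit the steady-state velocity profile.

    ``v_s`` in m/s, ``sigma`` in MPa.  The thermostat is Langevin in y
    only (the non-flow, non-normal direction), as in sliding
    non-equilibrium runs.

    The first fluid layer at each wall is dynamically locked to its wall
    (it carries the boundary velocities 0 and v_s); the linear Couette
    region is the sheared interior, so the fit excludes a ``margin`` of
    one bead layer next to each wall, as is conventional when extracting
    NEMD velocity profiles.  Returns the linear-regression R^2 over that
    region.
    """
    from scipy import stats

    state, table = couette_film(seed=seed)
    cfg = IntegratorConfig(dt=dt, thermostat="langevin", t_target=300.0,
                           damping=1.0, thermostat_axes=("y",), seed=seed)
    eng = Engine(state, lj_table=table, shift=ShiftSpec(0.9, 1.2), integrator=cfg)
    minimize_energy(eng, max_steps=300)
    load = LoadSlideConfig(sigma=sigma, v_s=v_s)
    n_warm = int(n_steps * warmup_frac)
    eng.run_confined(load, n_warm, sample_every=max(n_warm, 1), store_frames=False)
    log = eng.run_confined(load, n_steps - n_warm, sample_every=50, store_frames=True)

    fluid_mask = state.species_mask("fluid")

    class _Frames:
        frames = log.frames
        velocities = log.velocities
        species = state.species
        masses = state.mass
        charges = state.charge
        box = state.box

    z_lo = float(state.pos[state.group_mask("lower_anchor"), 2].mean())
    z_hi = float(state.pos[state.group_mask("upper_anchor"), 2].mean())
    prof = analysis.profile(_Frames(), fluid_mask, "velocity", bins=bins,
                            extent=(z_lo, z_hi))
    ok = (~np.isnan(prof.values)) & (prof.centers > z_lo + margin) \
        & (prof.centers < z_hi - margin)
    z, v = prof.centers[ok], prof.values[ok]
    res = stats.linregress(z, v)
    return CouetteResult(log=log, profile=prof, r_squared=float(res.rvalue**2),
                         slope=float(res.slope), state=state)


# ----------------------------------------------------------------------
# Rg - Mw scaling experiments
# ----------------------------------------------------------------------

def _replica_chain_state(n_beads: int, n_chains: int, bond: tuple[float, float],
                         box_size: float, rng: np.random.Generator,
                         lj_class: str = "OFF") -> SystemState:
    """Initial replicas of a linear bead chain, placed on a coarse grid so
    chains start well separated.  With excluded volume the chains are grown
    self-avoiding (no hard-core overlaps at t = 0); without it a plain
    fixed-step random walk is already a draw from the target freely jointed
    ensemble."""
    from .builder import self_avoiding_walk

    r0, k = bond
    self_avoid = lj_class != "OFF"
    state = SystemState(box=np.full(3, box_size))
    tpl_types = [BeadType("CB", mass=72.0, lj_class=lj_class)] * n_beads
    per_side = max(1, int(math.ceil(n_chains ** (1.0 / 3.0))))
    spacing = box_size / (per_side + 1)
    for c in range(n_chains):
        i3 = (c % per_side, (c // per_side) % per_side, c // per_side**2)
        start = (np.asarray(i3, dtype=float) + 1.0) * spacing \
            + rng.uniform(-0.1, 0.1, 3)
        if self_avoid:
            pos = self_avoiding_walk(n_beads, r0, 0.42, rng, max_retry=500,
                                     start=start)
        else:
            pos = np.zeros((n_beads, 3))
            pos[0] = start
            for i in range(1, n_beads):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos[i] = pos[i - 1] + r0 * u
        bonds = [(i, i + 1, r0, k) for i in range(n_beads - 1)]
        tpl = MoleculeTemplate(name="CHAIN", bead_types=tpl_types, positions=pos,
                               bonds=bonds)
        state.add_molecule(tpl, species="chain")
    return state


def _rg_run(n_beads: int, n_chains: int, n_steps: int, seed: int,
            excluded_volume: bool, bond=(0.47, 5000.0), sample_every: int = 200,
            burn_frac: float = 0.25, dt: float = 0.0055,
            damping: float = 10.0) -> float:
    box = 60.0 if excluded_volume else 30.0
    rng = np.random.default_rng(seed)
    lj_class = "REP" if excluded_volume else "OFF"
    state = _replica_chain_state(n_beads, n_chains, bond, box, rng, lj_class)
    table = None
    if excluded_volume:
        # repulsive-core pair interaction: the switch window ends just past
        # the LJ minimum so the attractive tail is removed (good solvent)
        table = LJPairTable({("REP", "REP"): (3.5, 0.47)})
    shift = ShiftSpec(0.45, 0.53) if excluded_volume else ShiftSpec(0.9, 1.2)
    cfg = IntegratorConfig(dt=dt, thermostat="langevin", t_target=300.0,
                           damping=damping, seed=seed)
    eng = Engine(state, lj_table=table, shift=shift, integrator=cfg)
    log = eng.run(n_steps, sample_every=sample_every)
    start = int(len(log.frames) * burn_frac)
    # the engine integrates unwrapped coordinates, so Rg is direct;
    # chains are contiguous blocks of equal-mass beads
    stack = np.stack(log.frames[start:]).reshape(-1, n_chains, n_beads, 3)
    dev = stack - stack.mean(axis=2, keepdims=True)
    rg2 = (dev**2).sum(axis=-1).mean(axis=-1)  # (frames, chains)
    return float(np.sqrt(rg2.mean()))


def ideal_chain_rg_experiment(lengths=(8, 12, 16, 24), n_chains: int = 64,
                              steps_per_n2: int = 250, seed: int = 0,
                              mass_per_bead: float = 72.0):
    """Freely jointed chains (no nonbonded terms): returns
    ([(Mw, Rg)], exponent) where ideal statistics give exponent 1/2 and
    <Rg^2> = b^2 (N^2 - 1) / (6 N).

    The number of integration steps grows with N^2 (the slowest chain
    relaxation mode) so all lengths are sampled over comparable numbers of
    independent conformations.
    """
    out = []
    for li, n in enumerate(lengths):
        n_steps = 40_000 + steps_per_n2 * n * n
        rg = _rg_run(n, n_chains, n_steps, seed + 17 * li, excluded_volume=False)
        out.append((n * mass_per_bead, rg))
    return out, analysis.rg_scaling(out)


def excluded_volume_rg_experiment(lengths=(8, 12, 16, 24, 32),
                                  n_chains=(32, 24, 20, 16, 12),
                                  steps_per_n2: int = 250, seed: int = 0,
                                  mass_per_bead: float = 72.0):
    """Self-avoiding chains (repulsive-core LJ): the scaled-down analogue
    of the full-model Rg-Mw scaling measurement."""
    out = []
    for li, (n, c) in enumerate(zip(lengths, n_chains)):
        n_steps = 40_000 + steps_per_n2 * n * n
        rg = _rg_run(n, c, n_steps, seed + 29 * li, excluded_volume=True)
        out.append((n * mass_per_bead, rg))
    return out, analysis.rg_scaling(out)


# ----------------------------------------------------------------------
# toy adsorption -> squeeze-out -> sliding protocol
# ----------------------------------------------------------------------

@dataclass
class ProtocolResult:
    state: SystemState
    squeeze_log: TrajectoryLog
    slide_log: TrajectoryLog
    coverage: analysis.CoverageReport
    shear_stress_mpa: tuple[float, float]


def confined_film_protocol(sigma: float = 10.0, v_s: float = 1.0,
                           squeeze_steps: int = 4000, slide_steps: int = 6000,
                           seed: int = 0) -> ProtocolResult:
    """Desk-scale sequential workflow: grafted surfaces with an adsorbed
    polyelectrolyte/surfactant/water film, squeezed under constant normal
    load and then slid at constant velocity.

    System sizes are kept small (hundreds of beads) so the full protocol
    runs in seconds; the outputs exercise the same code paths as a
    production run (coverage report from the contact, shear stress from
    the driven-anchor force).
    """
    surf = build_graft_surface(SurfaceSpec(lx=6.0, ly=5.0, graft_density=0.4,
                                           anionic_fraction=0.5, graft_length=2),
                               seed=seed)
    chain = build_cgg_chain(ChainSpec(n_repeat=3, ds=1.0, seed=seed, step=0.4))
    sds, na = build_sds()
    water = build_polarizable_water()
    ads = assemble_bulk([(chain, 1), (sds, 6), (water, 40)],
                        box=[6.0, 5.0, 7.0], neutralize=True, seed=seed + 1,
                        tol=0.35)
    ads.pos[:, 2] += 1.2  # lift the film above the graft layer
    contact = make_contact(surf, ads, gap=9.0)
    table = LJPairTable()
    for a in ("C1", "Qa", "Qd", "Q0", "P1", "P4", "POL"):
        for b in ("C1", "Qa", "Qd", "Q0", "P1", "P4", "POL"):
            table.set(a, b, 3.5, 0.47)
    table.set("OFF", "OFF", 0.0, 0.47)
    for a in ("C1", "Qa", "Qd", "Q0", "P1", "P4", "POL"):
        table.set(a, "OFF", 0.0, 0.47)
    cfg = IntegratorConfig(dt=0.004, thermostat="langevin", t_target=300.0,
                           damping=1.0, seed=seed)
    coul = CoulombConfig(r_cut=1.2, dielectric=2.5, alpha=1.0)
    eng = Engine(contact, lj_table=table, coulomb=coul, integrator=cfg)
    minimize_energy(eng, max_steps=400)
    squeeze = eng.run_confined(LoadSlideConfig(sigma=sigma, v_s=0.0),
                               squeeze_steps, sample_every=100)
    slide = eng.run_confined(LoadSlideConfig(sigma=sigma, v_s=v_s),
                             slide_steps, sample_every=50)
    area = float(contact.box[0] * contact.box[1])
    cov = analysis.coverages(contact, area)
    tau = analysis.shear_stress(slide, area, start_frac=0.3)
    return ProtocolResult(state=contact, squeeze_log=squeeze, slide_log=slide,
                          coverage=cov, shear_stress_mpa=tau)
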