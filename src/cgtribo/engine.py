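"""Desk-scale coarse-grained MD engine.

Velocity-Verlet integration with optional Langevin or Nose-Hoover
thermostatting (axis- and group-restrictable), SHAKE/RATTLE rigid
constraints, force-switched Lennard-Jones nonbonded interactions, damped
force-shifted Coulomb electrostatics, harmonic bonds/angles, harmonic
confining walls, and a confinement mode that freezes the lower anchor
sheet, drives the rigid upper anchor at constant sliding velocity and
applies a constant normal load.

Electrostatics note: the damped force-shifted cutoff scheme replaces mesh
(Ewald/PPPM) summation.  At desk scale it preserves ion pairing and
counterion-condensation physics while keeping energy and force continuous
at the cutoff; it is the largest fidelity compromise of the engine and is
documented as such in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .builder import SystemState
from .forcefield import LJPairTable, ShiftSpec, _switch_coeffs
from .mapping import MappedTrajectory
from .units import F_COULOMB, KB, MPA, M_PER_S

__all__ = [
    "IntegratorConfig",
    "CoulombConfig",
    "WallConfig",
    "LoadSlideConfig",
    "TrajectoryLog",
    "Engine",
    "coulomb_energy",
    "step_nve",
    "apply_thermostat",
    "minimize_energy",
    "shake_constraints",
    "kinetic_temperature",
    "sample_rg",
    "radius_of_gyration",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class IntegrationError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IntegratorConfig:
    """Time step, thermostat and constraint settings.

    ``dt`` in ps (default 0.005 ps = 5 fs).  ``thermostat`` is one of
    ``none | langevin | nose-hoover``; ``damping`` is the thermostat time
    constant in ps.  ``thermostat_axes`` restricts the Langevin
    friction/noise to a subset of Cartesian axes and ``thermostat_group``
    to a named bead group (both default to everything mobile), as used for
    sliding runs where only y and the graft base beads are coupled.
    """

    dt: float = 0.005
    thermostat: str = "none"
    t_target: float = 300.0
    damping: float = 1.0
    thermostat_axes: tuple[str, ...] = ("x", "y", "z")
    thermostat_group: str | None = None
    seed: int = 0
    shake_tol: float = 1e-8
    shake_max_iter: int = 500

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.thermostat not in ("none", "langevin", "nose-hoover"):
            raise ConfigError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.damping <= 0:
            raise ConfigError("thermostat damping must be > 0")
        for ax in self.thermostat_axes:
            if ax not in _AXES:
                raise ConfigError(f"unknown axis {ax!r}")


@dataclass(frozen=True)
class CoulombConfig:
    """Damped force-shifted Coulomb scheme.

    ``alpha`` (1/nm) is the damping parameter (0 = undamped shifted-force);
    ``dielectric`` the uniform relative permittivity.  Energy and force go
    continuously to zero at ``r_cut``.
    """

    r_cut: float = 1.2
    dielectric: float = 1.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.r_cut <= 0 or self.dielectric <= 0 or self.alpha < 0:
            raise ConfigError("invalid Coulomb configuration")


@dataclass(frozen=True)
class WallConfig:
    """One-sided harmonic repulsive walls normal to z."""

    z_lo: float | None = None
    z_hi: float | None = None
    k: float = 100.0  # kJ/mol/nm^2, half-included


@dataclass(frozen=True)
class LoadSlideConfig:
    """Normal load and sliding drive applied to the upper anchor.

    ``sigma`` is the normal stress in MPa (applied as a total downward
    force sigma * lateral area, distributed over the rigid upper anchor);
    ``v_s`` the sliding velocity along +x in m/s.  ``damping`` (ps) adds a
    viscous force -M v_z / damping on the anchor's normal motion so the
    squeeze approaches its equilibrium gap without ringing; it vanishes at
    steady state and therefore does not bias the transmitted load.
    """

    sigma: float = 0.0
    v_s: float = 0.0
    damping: float = 5.0

    def __post_init__(self):
        if self.sigma < 0 or self.v_s < 0:
            raise ConfigError("sigma and v_s must be >= 0")


@dataclass
class TrajectoryLog:
    """Periodic snapshots plus per-sample scalars of a run."""

    times: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    velocities: list[np.ndarray] = field(default_factory=list)
    scalars: dict[str, list[float]] = field(default_factory=dict)
    box: np.ndarray | None = None

    def add_scalar(self, **kv) -> None:
        for key, val in kv.items():
            self.scalars.setdefault(key, []).append(float(val))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.scalars})

    def to_mapped(self, state: SystemState) -> MappedTrajectory:
        """View the logged bead frames as a mapped trajectory."""
        return MappedTrajectory(
            bead_names=list(state.type_names), bead_types=list(state.type_names),
            bead_masses=state.mass.copy(), frames=list(self.frames),
            boxes=[self.box] if self.box is not None else None)


def kinetic_temperature(mass, vel, axes=(0, 1, 2), n_constraints: int = 0) -> float:
    """Kinetic temperature of the given velocity components."""
    axes = list(axes)
    ke = 0.5 * float(np.sum(mass[:, None] * vel[:, axes] ** 2))
    ndof = len(axes) * len(mass) - (n_constraints if len(axes) == 3 else 0)
    if ndof <= 0:
        return 0.0
    return 2.0 * ke / (ndof * KB)


# ----------------------------------------------------------------------
# pairwise interactions
# ----------------------------------------------------------------------

def _coulomb_pair(r, qq, cfg: CoulombConfig):
    """Energy and force magnitude of the damped force-shifted Coulomb pair."""
    ke = F_COULOMB / cfg.dielectric
    rc = cfg.r_cut
    a = cfg.alpha
    if a == 0.0:
        e_rc, f_rc = 1.0 / rc, 1.0 / rc**2
        e = ke * qq * (1.0 / r - e_rc + f_rc * (r - rc))
        f = ke * qq * (1.0 / r**2 - f_rc)
    else:
        two_a_pi = 2.0 * a / math.sqrt(math.pi)
        e_rc = erfc(a * rc) / rc
        f_rc = e_rc / rc + two_a_pi * math.exp(-(a * rc) ** 2) / rc
        er = erfc(a * r) / r
        fr = er / r + two_a_pi * np.exp(-(a * r) ** 2) / r
        e = ke * qq * (er - e_rc + f_rc * (r - rc))
        f = ke * qq * (fr - f_rc)
    inside = r < rc
    return np.where(inside, e, 0.0), np.where(inside, f, 0.0)


def coulomb_energy(state: SystemState, coulomb: CoulombConfig | None = None,
                   pairs: np.ndarray | None = None
                   ) -> tuple[float, np.ndarray]:
    """Total damped-cutoff Coulomb energy and per-bead forces of a state.

    All pairs (or the provided ``pairs`` array) are evaluated with
    minimum-image separations.  ``r_cut`` must not exceed half the smallest
    periodic box edge.
    """
    cfg = coulomb or CoulombConfig()
    per = state.periodic
    half_min = min((state.box[ax] / 2 for ax in range(3) if per[ax]), default=np.inf)
    if cfg.r_cut > half_min + 1e-12:
        raise ConfigError(
            f"Coulomb cutoff {cfg.r_cut} nm exceeds half the smallest periodic "
            f"box edge ({half_min} nm)")
    n = state.n_beads
    if pairs is None:
        iu = np.triu_indices(n, k=1)
        pairs = np.column_stack(iu)
    qq = state.charge[pairs[:, 0]] * state.charge[pairs[:, 1]]
    d = state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]]
    for ax in range(3):
        if per[ax]:
            d[:, ax] -= state.box[ax] * np.round(d[:, ax] / state.box[ax])
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise IntegrationError("overlapping charges at zero separation")
    e, fmag = _coulomb_pair(r, qq, cfg)
    forces = np.zeros((n, 3))
    fvec = (fmag / r)[:, None] * d
    np.add.at(forces, pairs[:, 0], fvec)
    np.add.at(forces, pairs[:, 1], -fvec)
    return float(e.sum()), forces


# ----------------------------------------------------------------------
# constraints
# ----------------------------------------------------------------------

def shake_constraints(pos: np.ndarray, pos_ref: np.ndarray, pairs: np.ndarray,
                      lengths: np.ndarray, inv_mass: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Iteratively project positions onto the constraint manifold (SHAKE).

    Corrections act along the pre-step bond directions with mass weighting,
    so linear momentum is conserved exactly.  Convergence is on the
    distance error ``| |r_ij| - d |`` (nm).
    """
    if len(pairs) == 0:
        return pos
    i, j = pairs[:, 0], pairs[:, 1]
    s_ref = pos_ref[i] - pos_ref[j]
    w = inv_mass[i] + inv_mass[j]
    d2 = lengths**2
    for _ in range(max_iter):
        s = pos[i] - pos[j]
        diff = np.einsum("ij,ij->i", s, s) - d2
        if np.max(np.abs(np.linalg.norm(s, axis=1) - lengths)) < tol:
            return pos
        g = diff / (2.0 * w * np.einsum("ij,ij->i", s, s_ref))
        corr = g[:, None] * s_ref
        np.add.at(pos, i, -(inv_mass[i] * g)[:, None] * s_ref)
        np.add.at(pos, j, (inv_mass[j] * g)[:, None] * s_ref)
    raise IntegrationError(
        f"SHAKE failed to converge within {max_iter} iterations "
        f"(max error {np.max(np.abs(np.linalg.norm(pos[i] - pos[j], axis=1) - lengths)):.2e} nm)")


def rattle_velocities(vel: np.ndarray, pos: np.ndarray, pairs: np.ndarray,
                      inv_mass: np.ndarray, max_iter: int = 50,
                      tol: float = 1e-10) -> np.ndarray:
    """Project out relative velocity along each constraint (RATTLE)."""
    if len(pairs) == 0:
        return vel
    i, j = pairs[:, 0], pairs[:, 1]
    s = pos[i] - pos[j]
    s2 = np.einsum("ij,ij->i", s, s)
    w = inv_mass[i] + inv_mass[j]
    for _ in range(max_iter):
        vij = vel[i] - vel[j]
        g = np.einsum("ij,ij->i", vij, s) / (s2 * w)
        if np.max(np.abs(g)) < tol:
            break
        np.add.at(vel, i, -(inv_mass[i] * g)[:, None] * s)
        np.add.at(vel, j, (inv_mass[j] * g)[:, None] * s)
    return vel


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------

class Engine:
    """Integrates a :class:`SystemState` in place.

    Parameters
    ----------
    state : the system; anchors (``lower_anchor``/``upper_anchor`` groups)
        are treated as boundary condition beads.
    lj_table : LJ pair parameters by lj_class; ``None`` disables nonbonded
        LJ interactions (bonded-only runs).
    shift : LJ force-switching window.
    coulomb : electrostatics config; ``None`` disables charges.
    integrator : time step / thermostat settings.
    wall : optional harmonic z-walls.
    skin : Verlet-list skin (nm); the pair list is rebuilt whenever any
        bead has moved more than skin/2 since the last build.
    """

    def __init__(self, state: SystemState, lj_table: LJPairTable | None = None,
                 shift: ShiftSpec = ShiftSpec(0.9, 1.2),
                 coulomb: CoulombConfig | None = None,
                 integrator: IntegratorConfig = IntegratorConfig(),
                 wall: WallConfig | None = None, skin: float = 0.3):
        self.state = state
        self.shift = shift
        self.coulomb = coulomb
        self.cfg = integrator
        self.wall = wall
        self.skin = skin
        self.rng = np.random.default_rng(integrator.seed)
        self.time = 0.0
        self._sw12 = _switch_coeffs(12, shift.r_on, shift.r_cut)
        self._sw6 = _switch_coeffs(6, shift.r_on, shift.r_cut)
        self._pbc_box = np.where(state.periodic, state.box, 1.0)
        self._pbc_inv = np.where(state.periodic, 1.0 / state.box, 0.0)

        n = state.n_beads
        self.inv_mass = 1.0 / state.mass
        self._frozen = np.zeros(n, dtype=bool)
        self._driven = np.zeros(n, dtype=bool)
        if "lower_anchor" in state.groups:
            self._frozen |= state.groups["lower_anchor"]
        self.mobile = ~(self._frozen | self._driven)

        # LJ per-type matrices
        self._use_lj = lj_table is not None
        if self._use_lj:
            classes = sorted(set(state.lj_class))
            self._class_index = np.array([classes.index(c) for c in state.lj_class])
            self._eps_m, self._sig_m = lj_table.matrices(classes)
        self._use_coul = coulomb is not None and np.any(state.charge != 0)

        # exclusions: first bonded neighbours and constraint partners
        excl = set()
        for i, j in np.vstack([state.bonds, state.constraints]):
            excl.add((min(i, j), max(i, j)))
        # beads of the same rigid water (satellite-satellite) are excluded too
        con = state.constraints
        if len(con):
            from collections import defaultdict
            partners = defaultdict(set)
            for i, j in con:
                partners[i].add(j)
                partners[j].add(i)
            for center, sats in partners.items():
                for a in sats:
                    for b in sats:
                        if a < b:
                            excl.add((a, b))
        self._excl_codes = np.array(sorted(i * n + j for i, j in excl), dtype=np.int64)

        self._pairs = None
        self._pairs_pos = None
        self._thermo_mask = self._thermostat_mask()
        self._axes_mask = np.zeros(3)
        for ax in self.cfg.thermostat_axes:
            self._axes_mask[_AXES[ax]] = 1.0
        self._nh_xi = 0.0

        self.forces, self.e_pot = self.compute_forces()

    # -- setup helpers ----------------------------------------------
    def _thermostat_mask(self) -> np.ndarray:
        if self.cfg.thermostat == "none":
            return np.zeros(self.state.n_beads, dtype=bool)
        if self.cfg.thermostat_group is None:
            return self.mobile.copy()
        mask = self.state.group_mask(self.cfg.thermostat_group) & self.mobile
        if not mask.any():
            raise ConfigError(
                f"thermostat group {self.cfg.thermostat_group!r} is empty "
                "(or fully frozen)")
        return mask

    @property
    def r_cut(self) -> float:
        rc = self.shift.r_cut if self._use_lj else 0.0
        if self._use_coul:
            rc = max(rc, self.coulomb.r_cut)
        return rc if rc > 0 else 0.0

    # -- neighbour list ----------------------------------------------
    def _build_pairs(self) -> None:
        st = self.state
        n = st.n_beads
        rc = self.r_cut
        if rc == 0.0 or n < 2:
            self._pairs = np.zeros((0, 2), dtype=int)
            self._pairs_pos = st.pos.copy()
            self._pair_data()
            return
        iu, ju = np.triu_indices(n, k=1)
        d = st.pos[iu] - st.pos[ju]
        for ax in range(3):
            if st.periodic[ax]:
                d[:, ax] -= st.box[ax] * np.round(d[:, ax] / st.box[ax])
        r2 = np.einsum("ij,ij->i", d, d)
        keep = r2 < (rc + self.skin) ** 2
        codes = iu * n + ju
        keep &= ~np.isin(codes, self._excl_codes, assume_unique=True)
        self._pairs = np.column_stack([iu[keep], ju[keep]])
        self._pairs_pos = st.pos.copy()
        self._pair_data()

    def _pair_data(self) -> None:
        p = self._pairs
        if self._use_lj:
            ci = self._class_index[p[:, 0]]
            cj = self._class_index[p[:, 1]]
            eps = self._eps_m[ci, cj]
            sig = self._sig_m[ci, cj]
            sig6 = sig**6
            self._c12_p = 4.0 * eps * sig6 * sig6
            self._c6_p = 4.0 * eps * sig6
        if self._use_coul:
            self._qq_p = self.state.charge[p[:, 0]] * self.state.charge[p[:, 1]]
            self._qq_nz = self._qq_p != 0

    def _maybe_rebuild(self) -> None:
        if self._pairs is None:
            self._build_pairs()
            return
        disp = np.abs(self.state.pos - self._pairs_pos).max() if self.state.n_beads else 0.0
        if disp > self.skin / 2.0:
            self._build_pairs()

    # -- force evaluation --------------------------------------------
    def compute_forces(self) -> tuple[np.ndarray, float]:
        st = self.state
        self._maybe_rebuild()
        f = np.zeros_like(st.pos)
        e = 0.0
        p = self._pairs
        if len(p):
            i, j = p[:, 0], p[:, 1]
            d = st.pos[i] - st.pos[j]
            d -= self._pbc_box * np.round(d * self._pbc_inv)
            r2 = np.einsum("ij,ij->i", d, d)
            r = np.sqrt(r2)
            if not r.all():
                bad = p[r == 0][0]
                raise IntegrationError(
                    f"beads {bad[0]} and {bad[1]} at zero separation")
            fmag = np.zeros_like(r)
            if self._use_lj:
                sh = self.shift
                inside = r < sh.r_cut
                if inside.any():
                    ri = r[inside]
                    inv = 1.0 / ri
                    inv2 = inv * inv
                    inv6 = inv2 * inv2 * inv2
                    inv12 = inv6 * inv6
                    dr = ri - sh.r_on
                    np.clip(dr, 0.0, None, out=dr)
                    dr2 = dr * dr
                    dr3 = dr2 * dr
                    dr4 = dr3 * dr
                    A12, B12, C12 = self._sw12
                    A6, B6, C6 = self._sw6
                    c12 = self._c12_p[inside]
                    c6 = self._c6_p[inside]
                    e12 = inv12 - A12 / 3.0 * dr3 - B12 / 4.0 * dr4 - C12
                    e6 = inv6 - A6 / 3.0 * dr3 - B6 / 4.0 * dr4 - C6
                    e += float(c12 @ e12 - c6 @ e6)
                    fm = (c12 * (12.0 * inv12 * inv + A12 * dr2 + B12 * dr3)
                          - c6 * (6.0 * inv6 * inv + A6 * dr2 + B6 * dr3))
                    fmag[inside] = fm
            if self._use_coul:
                nz = self._qq_nz
                if nz.any():
                    ec, fc = _coulomb_pair(r[nz], self._qq_p[nz], self.coulomb)
                    e += float(ec.sum())
                    fmag[nz] += fc
            fvec = (fmag / r)[:, None] * d
            n = st.n_beads
            for c in range(3):
                f[:, c] += np.bincount(i, weights=fvec[:, c], minlength=n)
                f[:, c] -= np.bincount(j, weights=fvec[:, c], minlength=n)
        e += self._bond_forces(f)
        e += self._angle_forces(f)
        e += self._wall_forces(f)
        if not np.all(np.isfinite(f)):
            bad = int(np.argwhere(~np.isfinite(f))[0][0])
            raise IntegrationError(f"non-finite force on bead {bad}")
        return f, e

    def _bond_forces(self, f: np.ndarray) -> float:
        st = self.state
        if not len(st.bonds):
            return 0.0
        i, j = st.bonds[:, 0], st.bonds[:, 1]
        d = st.pos[i] - st.pos[j]
        d -= self._pbc_box * np.round(d * self._pbc_inv)
        r = np.linalg.norm(d, axis=1)
        dr = r - st.bond_r0
        e = float(np.sum(st.bond_k * dr**2))
        fmag = -2.0 * st.bond_k * dr / r
        fvec = fmag[:, None] * d
        n = st.n_beads
        for c in range(3):
            fc = np.bincount(i, weights=fvec[:, c], minlength=n)
            fc -= np.bincount(j, weights=fvec[:, c], minlength=n)
            f[:, c] += fc
        return e

    def _angle_forces(self, f: np.ndarray) -> float:
        st = self.state
        if not len(st.angles):
            return 0.0
        i, j, k = st.angles[:, 0], st.angles[:, 1], st.angles[:, 2]
        u = st.pos[i] - st.pos[j]
        v = st.pos[k] - st.pos[j]
        u -= self._pbc_box * np.round(u * self._pbc_inv)
        v -= self._pbc_box * np.round(v * self._pbc_inv)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cosang = np.clip(cosang, -1.0, 1.0)
        theta = np.arccos(cosang)
        dtheta = theta - st.angle_theta0
        e = float(np.sum(st.angle_k * dtheta**2))
        sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-16))
        coeff = 2.0 * st.angle_k * dtheta / sin
        fi = (coeff / nu)[:, None] * (v / nv[:, None] - cosang[:, None] * u / nu[:, None])
        fk = (coeff / nv)[:, None] * (u / nu[:, None] - cosang[:, None] * v / nv[:, None])
        n = st.n_beads
        fj = -(fi + fk)
        for c in range(3):
            fc = np.bincount(i, weights=fi[:, c], minlength=n)
            fc += np.bincount(k, weights=fk[:, c], minlength=n)
            fc += np.bincount(j, weights=fj[:, c], minlength=n)
            f[:, c] += fc
        return e

    def _wall_forces(self, f: np.ndarray) -> float:
        if self.wall is None:
            return 0.0
        z = self.state.pos[:, 2]
        e = 0.0
        if self.wall.z_lo is not None:
            pen = np.minimum(z - self.wall.z_lo, 0.0)
            e += float(np.sum(self.wall.k * pen**2))
            f[:, 2] += -2.0 * self.wall.k * pen
        if self.wall.z_hi is not None:
            pen = np.maximum(z - self.wall.z_hi, 0.0)
            e += float(np.sum(self.wall.k * pen**2))
            f[:, 2] += -2.0 * self.wall.k * pen
        return e

    # -- thermostats --------------------------------------------------
    def _ou_update(self) -> None:
        """Exact Ornstein-Uhlenbeck velocity update (axis/group restricted).

        v <- c1 v + c2 xi with c1 = exp(-dt/damping) and
        c2 = sqrt(kB T / m (1 - c1^2)); unbiased in the kinetic
        temperature and reduces to pure exponential friction at T = 0.
        """
        st = self.state
        mask = self._thermo_mask
        if not mask.any():
            return
        c1 = math.exp(-self.cfg.dt / self.cfg.damping)
        c2 = np.sqrt(KB * self.cfg.t_target * (1.0 - c1 * c1) / st.mass[mask])
        xi = self.rng.standard_normal((int(mask.sum()), 3))
        new = c1 * st.vel[mask] + c2[:, None] * xi
        ax = self._axes_mask
        st.vel[mask] = st.vel[mask] * (1.0 - ax) + new * ax

    def _nose_hoover_scale(self) -> None:
        mask = self._thermo_mask
        if not mask.any():
            return
        t_inst = kinetic_temperature(self.state.mass[mask], self.state.vel[mask])
        xi_dot = (t_inst / self.cfg.t_target - 1.0) / self.cfg.damping**2
        self._nh_xi += xi_dot * self.cfg.dt
        scale = math.exp(-self._nh_xi * self.cfg.dt)
        self.state.vel[mask] *= scale

    # -- stepping ------------------------------------------------------
    def step(self, drive: "_DriveState | None" = None) -> None:
        st = self.state
        dt = self.cfg.dt
        mob = self.mobile
        f = self.forces
        st.vel[mob] += 0.5 * dt * f[mob] * self.inv_mass[mob, None]
        pos_ref = st.pos.copy()
        st.pos[mob] += dt * st.vel[mob]
        if drive is not None:
            drive.advance_positions(self, dt)
        if len(st.constraints):
            unconstrained = st.pos.copy()
            shake_constraints(st.pos, pos_ref, st.constraints, st.constraint_length,
                              self.inv_mass, self.cfg.shake_tol, self.cfg.shake_max_iter)
            st.vel += (st.pos - unconstrained) / dt
        self.forces, self.e_pot = self.compute_forces()
        if drive is not None:
            drive.integrate_velocity(self, dt)
        f = self.forces
        st.vel[mob] += 0.5 * dt * f[mob] * self.inv_mass[mob, None]
        if self.cfg.thermostat == "langevin":
            self._ou_update()
        if len(st.constraints):
            rattle_velocities(st.vel, st.pos, st.constraints, self.inv_mass)
        if self.cfg.thermostat == "nose-hoover":
            self._nose_hoover_scale()
        st.vel[self._frozen] = 0.0
        self.time += dt

    def run(self, n_steps: int, sample_every: int = 100,
            store_frames: bool = True) -> TrajectoryLog:
        """Integrate ``n_steps`` and log every ``sample_every`` steps."""
        log = TrajectoryLog(box=self.state.box.copy())
        self._log_sample(log, store_frames)
        for s in range(1, n_steps + 1):
            self.step()
            if s % sample_every == 0:
                self._log_sample(log, store_frames)
        return log

    def _log_sample(self, log: TrajectoryLog, store_frames: bool,
                    extra: dict | None = None) -> None:
        st = self.state
        mob = self.mobile
        ke = 0.5 * float(np.sum(st.mass[mob, None] * st.vel[mob] ** 2))
        ndof = 3 * int(mob.sum()) - len(st.constraints)
        temp = 2.0 * ke / (ndof * KB) if ndof > 0 else 0.0
        log.times.append(self.time)
        if store_frames:
            log.frames.append(st.pos.copy())
            log.velocities.append(st.vel.copy())
        log.add_scalar(e_kin=ke, e_pot=self.e_pot, e_total=ke + self.e_pot,
                       temperature=temp, **(extra or {}))

    # -- confined / sliding mode --------------------------------------
    def run_confined(self, load: LoadSlideConfig, n_steps: int,
                     sample_every: int = 100, store_frames: bool = False
                     ) -> TrajectoryLog:
        """Squeeze/slide run: frozen lower anchor, rigid driven upper anchor.

        The upper anchor moves as a rigid body: constant ``v_s`` along x, a
        single z degree of freedom integrating the net normal force
        (interactions + the applied load sigma * A), y fixed.  The log
        records the anchor-sheet gap and the normal/lateral anchor forces.
        """
        st = self.state
        for tag in ("lower_anchor", "upper_anchor"):
            if tag not in st.groups or not st.groups[tag].any():
                raise ConfigError(f"run_confined requires a non-empty {tag!r} group")
        drive = _DriveState(self, load)
        log = TrajectoryLog(box=st.box.copy())
        self._log_sample(log, store_frames, drive.observables(self))
        for s in range(1, n_steps + 1):
            self.step(drive)
            if s % sample_every == 0:
                self._log_sample(log, store_frames, drive.observables(self))
        return log


def step_nve(state: SystemState, dt: float, lj_table: LJPairTable | None = None,
             shift: ShiftSpec = ShiftSpec(0.9, 1.2),
             coulomb: CoulombConfig | None = None, n_steps: int = 1) -> SystemState:
    """One (or a few) microcanonical velocity-Verlet steps on a bare state.

    Convenience wrapper for interactive use; sustained runs should hold an
    :class:`Engine` so the pair list and per-pair coefficients persist.
    """
    eng = Engine(state, lj_table=lj_table, shift=shift, coulomb=coulomb,
                 integrator=IntegratorConfig(dt=dt))
    for _ in range(n_steps):
        eng.step()
    return state


def apply_thermostat(state: SystemState, config: IntegratorConfig,
                     rng: np.random.Generator | None = None) -> SystemState:
    """Apply one thermostat update to the state's velocities in place.

    For ``langevin`` this is the exact Ornstein-Uhlenbeck velocity update
    (axis/group restricted); for ``nose-hoover`` one friction-variable
    update and rescale.  The drawn noise comes from ``rng`` when given
    (otherwise a generator seeded from the config).
    """
    eng = Engine(state, integrator=config)
    if rng is not None:
        eng.rng = rng
    if config.thermostat == "langevin":
        eng._ou_update()
    elif config.thermostat == "nose-hoover":
        eng._nose_hoover_scale()
    return state


def minimize_energy(engine: Engine, max_steps: int = 500, f_tol: float = 10.0,
                    max_disp: float = 0.02) -> float:
    """Damped steepest-descent relaxation of the mobile beads.

    Displacements are capped at ``max_disp`` nm per step with a
    backtracking step size, which tames the hard-core overlaps left by
    random insertion before dynamics starts.  Returns the final potential
    energy.
    """
    st = engine.state
    mob = engine.mobile
    scale = 1e-4
    f, e = engine.compute_forces()
    for _ in range(max_steps):
        if np.abs(f[mob]).max() < f_tol:
            break
        disp = np.clip(scale * f[mob], -max_disp, max_disp)
        old = st.pos.copy()
        st.pos[mob] += disp
        if len(st.constraints):
            shake_constraints(st.pos, old, st.constraints, st.constraint_length,
                              engine.inv_mass, engine.cfg.shake_tol,
                              engine.cfg.shake_max_iter)
        f_new, e_new = engine.compute_forces()
        if e_new > e:
            st.pos = old
            scale *= 0.5
            f_new, e_new = engine.compute_forces()
        else:
            scale = min(scale * 1.2, 1e-2)
        f, e = f_new, e_new
    engine.forces, engine.e_pot = f, e
    st.vel[:] = 0.0
    return e


class _DriveState:
    """Rigid-body state of the driven upper anchor during confined runs."""

    def __init__(self, engine: Engine, load: LoadSlideConfig):
        st = engine.state
        self.upper = st.group_mask("upper_anchor")
        self.lower = st.group_mask("lower_anchor")
        # the upper anchor must not also be integrated as mobile
        engine.mobile &= ~self.upper
        engine._thermo_mask &= engine.mobile
        self.mass = float(st.mass[self.upper].sum())
        self.area = float(st.box[0] * st.box[1])
        self.load_force = -load.sigma * MPA * self.area  # kJ/mol/nm, downward
        self.v_slide = load.v_s * M_PER_S
        self.damping = load.damping
        self.v_z = 0.0
        st.vel[self.upper] = 0.0
        st.vel[self.upper, 0] = self.v_slide

    def advance_positions(self, engine: Engine, dt: float) -> None:
        st = engine.state
        st.pos[self.upper, 0] += self.v_slide * dt
        st.pos[self.upper, 2] += self.v_z * dt

    def integrate_velocity(self, engine: Engine, dt: float) -> None:
        fz = float(engine.forces[self.upper, 2].sum()) + self.load_force
        if self.damping > 0:
            fz -= self.mass * self.v_z / self.damping
        self.v_z += dt * fz / self.mass
        engine.state.vel[self.upper, 2] = self.v_z

    def observables(self, engine: Engine) -> dict:
        st = engine.state
        gap = float(st.pos[self.upper, 2].mean() - st.pos[self.lower, 2].mean())
        return {
            "gap": gap,
            "f_lower_z": float(engine.forces[self.lower, 2].sum()),
            "f_upper_z": float(engine.forces[self.upper, 2].sum()),
            "f_upper_x": float(engine.forces[self.upper, 0].sum()),
        }


def _switched_pow(r: np.ndarray, p: int, shift: ShiftSpec):
    """Energy/force of the switched r^-p term for r < r_cut (vectorized)."""
    A, B, C = _switch_coeffs(p, shift.r_on, shift.r_cut)
    inv = 1.0 / r
    inv_p = inv**p
    inv_p1 = inv_p * inv
    dr = np.maximum(r - shift.r_on, 0.0)
    e = inv_p - A / 3.0 * dr**3 - B / 4.0 * dr**4 - C
    fmag = p * inv_p1 + A * dr**2 + B * dr**3
    return e, fmag


# ----------------------------------------------------------------------
# observables
# ----------------------------------------------------------------------

def _unwrap_molecule(pos: np.ndarray, idx: np.ndarray, bonds: np.ndarray,
                     box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Unwrap one molecule's coordinates by walking its bond graph."""
    import collections

    local = {int(g): l for l, g in enumerate(idx)}
    adj = collections.defaultdict(list)
    for i, j in bonds:
        if int(i) in local and int(j) in local:
            adj[local[int(i)]].append(local[int(j)])
            adj[local[int(j)]].append(local[int(i)])
    out = pos[idx].copy()
    n = len(idx)
    seen = np.zeros(n, dtype=bool)
    queue = collections.deque([0])
    seen[0] = True
    while queue:
        a = queue.popleft()
        for b in adj[a]:
            if not seen[b]:
                d = out[b] - out[a]
                for ax in range(3):
                    if periodic[ax]:
                        d[ax] -= box[ax] * round(d[ax] / box[ax])
                out[b] = out[a] + d
                seen[b] = True
                queue.append(b)
    if not seen.all():
        raise ValueError("molecule bond graph is disconnected; cannot unwrap")
    return out


def radius_of_gyration(pos: np.ndarray, mass: np.ndarray) -> float:
    """Mass-weighted radius of gyration of one set of coordinates, nm."""
    com = mass @ pos / mass.sum()
    d2 = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(mass @ d2 / mass.sum()))


def sample_rg(log: TrajectoryLog, state: SystemState, molecule: int) -> np.ndarray:
    """Per-frame mass-weighted Rg of one molecule, with periodic unwrapping
    along bonds."""
    idx = np.where(state.mol == molecule)[0]
    if len(idx) == 0:
        raise ValueError(f"no molecule with id {molecule}")
    mass = state.mass[idx]
    if len(idx) == 1:
        return np.zeros(len(log.frames))
    out = np.empty(len(log.frames))
    bonds = np.vstack([state.bonds, state.constraints])
    for fi, frame in enumerate(log.frames):
        unwrapped = _unwrap_molecule(frame, idx, bonds, state.box, state.periodic)
        out[fi] = radius_of_gyration(unwrapped, mass)
    return out
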