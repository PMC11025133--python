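"""Builders for coarse-grained molecules, surfaces and assembled systems.

Covers the cationic-guar (CGG) chain with a configurable degree of
substitution, the four-bead SDS surfactant, polarizable three-site water,
hydrated counterions, a simplified grafted monolayer standing in for the
biomimetic hair surface, and the assembly of bulk and confined systems.

Geometry conventions: right-handed coordinates, z is the surface normal,
the lower anchor sheet sits at z = 0.  All builds are deterministic given
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import BeadType
from .units import molarity

__all__ = [
    "MoleculeTemplate",
    "ChainSpec",
    "SurfaceSpec",
    "SystemState",
    "PackingError",
    "build_cgg_chain",
    "build_sds",
    "build_counterion",
    "build_polarizable_water",
    "assemble_bulk",
    "build_graft_surface",
    "make_contact",
    "self_avoiding_walk",
    "GUAR_REPEAT_BEADS",
]

# Default bead typing.  The neutral guar repeat unit maps to 9 beads
# (three sugar units of three beads each: two mannoses and one galactose);
# a functionalized repeat adds a P1 hydroxypropyl bead and a Q0
# trimethylammonium bead carrying +1e.  Bead masses follow the 72 amu
# MARTINI standard (4 heavy atoms per bead); ring beads use the small-bead
# mass 45 amu as in MARTINI saccharides.
RING_BEAD = BeadType("SP", mass=45.0, charge=0.0, lj_class="P4")
P1_BEAD = BeadType("P1", mass=72.0, charge=0.0, lj_class="P1")
Q0_BEAD = BeadType("Q0", mass=72.0, charge=1.0, lj_class="Q0")
QA_BEAD = BeadType("Qa", mass=72.0, charge=-1.0, lj_class="Qa")
QD_BEAD = BeadType("Qd", mass=72.0, charge=1.0, lj_class="Qd")
C1_BEAD = BeadType("C1", mass=72.0, charge=0.0, lj_class="C1")
W_BEAD = BeadType("W", mass=24.0, charge=0.0, lj_class="POL")
WP_BEAD = BeadType("WP", mass=24.0, charge=0.46, lj_class="OFF")
WM_BEAD = BeadType("WM", mass=24.0, charge=-0.46, lj_class="OFF")
GRAFT_BEAD = BeadType("GC1", mass=72.0, charge=0.0, lj_class="C1")
ANCHOR_BEAD = BeadType("ANC", mass=72.0, charge=0.0, lj_class="C1")

GUAR_REPEAT_BEADS = 9

# Default bonded parameters used by the builders (half-included convention,
# kJ/mol/nm^2 and kJ/mol/rad^2).  Stiff, short ring bonds as is typical for
# coarse-grained saccharides; softer inter-unit links.
DEFAULT_BOND = (0.47, 5000.0)
DEFAULT_ANGLE = (120.0, 25.0)
WATER_CONSTRAINT = 0.14
WATER_ANGLE = (0.0, 2.1)


class PackingError(RuntimeError):
    """Raised when random insertion or walk placement exceeds its retry cap."""


@dataclass
class MoleculeTemplate:
    """A molecule blueprint: beads, internal coordinates and bonded terms.

    ``bonds``/``angles`` are index tuples with their harmonic parameters;
    ``constraints`` are rigid-distance pairs handled by SHAKE.
    """

    name: str
    bead_types: list[BeadType]
    positions: np.ndarray  # (n, 3) nm, template frame
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.bead_types)
        if self.positions.shape[0] != n:
            raise ValueError(f"{self.name}: positions/bead_types length mismatch")
        for i, j, *_ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.name}: bond ({i},{j}) references missing bead")
        for i, j, k, *_ in self.angles:
            if not all(0 <= x < n for x in (i, j, k)):
                raise ValueError(f"{self.name}: angle ({i},{j},{k}) references missing bead")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def net_charge(self) -> float:
        return float(sum(b.charge for b in self.bead_types))

    @property
    def mass(self) -> float:
        return float(sum(b.mass for b in self.bead_types))


@dataclass(frozen=True)
class ChainSpec:
    """Specification of a cationic-guar chain build.

    ``ds`` is the degree of substitution: the fraction of monomers carrying
    the cationic hydroxypropyltrimonium group; exactly ``round(ds * n_repeat)``
    monomers are functionalized.
    """

    n_repeat: int = 50
    ds: float = 1.0
    placement: str = "random"  # or "regular"
    step: float = 0.36  # walk step length between consecutive backbone beads, nm
    min_self_distance: float = 0.30  # nm, between non-bonded beads
    seed: int = 0
    max_retry: int = 200

    def __post_init__(self):
        if not (0.0 <= self.ds <= 1.0):
            raise ValueError("degree of substitution must lie in [0, 1]")
        if self.n_repeat < 1:
            raise ValueError("n_repeat must be >= 1")

    @property
    def n_functionalized(self) -> int:
        return int(round(self.ds * self.n_repeat))


@dataclass(frozen=True)
class SurfaceSpec:
    """Simplified grafted-monolayer surface.

    A rigid anchor sheet on a square lattice with linear grafted chains;
    a fraction of graft head beads carries -1e (0 emulates an intact
    fatty-acid monolayer, > 0 an oxidized/bleached surface).
    """

    lx: float = 8.0  # nm
    ly: float = 7.0  # nm
    graft_density: float = 0.5  # nm^-2
    anionic_fraction: float = 0.0
    graft_length: int = 3  # beads per graft chain
    anchor_spacing: float = 0.5  # nm
    graft_bond: tuple[float, float] = (0.35, 5000.0)

    def __post_init__(self):
        if not (0.0 <= self.anionic_fraction <= 1.0):
            raise ValueError("anionic fraction must lie in [0, 1]")
        if self.graft_density < 0:
            raise ValueError("graft density must be >= 0")

    @property
    def area(self) -> float:
        return self.lx * self.ly

    @property
    def n_grafts(self) -> int:
        return int(round(self.graft_density * self.area))


class SystemState:
    """Beads, bonded terms, box and group tags of an assembled system.

    Arrays: ``pos``/``vel`` (N, 3) in nm and nm/ps, ``mass`` amu,
    ``charge`` e, ``type_names`` bead-type labels, ``mol`` molecule ids.
    ``groups`` maps tag names (``lower_anchor``, ``upper_anchor``,
    ``graft_base`` ...) to boolean masks; untagged beads are mobile.
    """

    def __init__(self, box, periodic=(True, True, True)):
        self.box = np.asarray(box, dtype=float).reshape(3)
        self.periodic = np.asarray(periodic, dtype=bool).reshape(3)
        self.pos = np.zeros((0, 3))
        self.vel = np.zeros((0, 3))
        self.mass = np.zeros(0)
        self.charge = np.zeros(0)
        self.type_names: list[str] = []
        self.lj_class: list[str] = []
        self.mol = np.zeros(0, dtype=int)
        self.species: list[str] = []
        self.bonds = np.zeros((0, 2), dtype=int)
        self.bond_r0 = np.zeros(0)
        self.bond_k = np.zeros(0)
        self.angles = np.zeros((0, 3), dtype=int)
        self.angle_theta0 = np.zeros(0)  # radians
        self.angle_k = np.zeros(0)
        self.constraints = np.zeros((0, 2), dtype=int)
        self.constraint_length = np.zeros(0)
        self.groups: dict[str, np.ndarray] = {}

    # -- bookkeeping -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charge.sum())

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.mol)) if self.n_beads else 0

    def group_mask(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"no group {name!r}; known: {sorted(self.groups)}")
        return self.groups[name]

    def anchored_mask(self) -> np.ndarray:
        m = np.zeros(self.n_beads, dtype=bool)
        for tag in ("lower_anchor", "upper_anchor"):
            if tag in self.groups:
                m |= self.groups[tag]
        return m

    def add_group(self, name: str, mask: np.ndarray) -> None:
        self.groups[name] = np.asarray(mask, dtype=bool).copy()

    def copy(self) -> "SystemState":
        out = SystemState(self.box, self.periodic)
        for attr in ("pos", "vel", "mass", "charge", "mol", "bonds", "bond_r0",
                     "bond_k", "angles", "angle_theta0", "angle_k",
                     "constraints", "constraint_length"):
            setattr(out, attr, getattr(self, attr).copy())
        out.type_names = list(self.type_names)
        out.lj_class = list(self.lj_class)
        out.species = list(self.species)
        out.groups = {k: v.copy() for k, v in self.groups.items()}
        return out

    # -- construction ------------------------------------------------
    def add_molecule(self, template: MoleculeTemplate, positions: np.ndarray | None = None,
                     species: str | None = None, groups: dict[str, np.ndarray] | None = None,
                     ) -> np.ndarray:
        """Append one molecule; returns the global indices of its beads."""
        pos = template.positions if positions is None else np.asarray(positions, float)
        if pos.shape != (template.n_beads, 3):
            raise ValueError("positions shape does not match template")
        off = self.n_beads
        mol_id = int(self.mol.max()) + 1 if self.n_beads else 0
        idx = np.arange(off, off + template.n_beads)
        self.pos = np.vstack([self.pos, pos])
        self.vel = np.vstack([self.vel, np.zeros_like(pos)])
        self.mass = np.concatenate([self.mass, [b.mass for b in template.bead_types]])
        self.charge = np.concatenate([self.charge, [b.charge for b in template.bead_types]])
        self.type_names += [b.name for b in template.bead_types]
        self.lj_class += [b.lj_class for b in template.bead_types]
        self.mol = np.concatenate([self.mol, np.full(template.n_beads, mol_id)])
        self.species += [species or template.name] * template.n_beads
        if template.bonds:
            b = np.array([(i + off, j + off) for i, j, _, _ in template.bonds])
            self.bonds = np.vstack([self.bonds, b])
            self.bond_r0 = np.concatenate([self.bond_r0, [t[2] for t in template.bonds]])
            self.bond_k = np.concatenate([self.bond_k, [t[3] for t in template.bonds]])
        if template.angles:
            a = np.array([(i + off, j + off, k + off) for i, j, k, _, _ in template.angles])
            self.angles = np.vstack([self.angles, a])
            self.angle_theta0 = np.concatenate(
                [self.angle_theta0, [math.radians(t0) for *_, t0, _ in template.angles]])
            self.angle_k = np.concatenate([self.angle_k, [k for *_, k in template.angles]])
        if template.constraints:
            c = np.array([(i + off, j + off) for i, j, _ in template.constraints])
            self.constraints = np.vstack([self.constraints, c])
            self.constraint_length = np.concatenate(
                [self.constraint_length, [d for *_, d in template.constraints]])
        # extend all group masks
        for name in self.groups:
            self.groups[name] = np.concatenate(
                [self.groups[name], np.zeros(template.n_beads, dtype=bool)])
        for name, mask in (groups or {}).items():
            if name not in self.groups:
                self.groups[name] = np.zeros(self.n_beads, dtype=bool)
            self.groups[name][idx] = np.asarray(mask, dtype=bool)
        return idx

    def merge(self, other: "SystemState") -> None:
        """Append all beads/terms of ``other`` (boxes must match laterally)."""
        off = self.n_beads
        mol_off = (int(self.mol.max()) + 1) if self.n_beads else 0
        self.pos = np.vstack([self.pos, other.pos])
        self.vel = np.vstack([self.vel, other.vel])
        self.mass = np.concatenate([self.mass, other.mass])
        self.charge = np.concatenate([self.charge, other.charge])
        self.type_names += other.type_names
        self.lj_class += other.lj_class
        self.mol = np.concatenate([self.mol, other.mol + mol_off])
        self.species += other.species
        self.bonds = np.vstack([self.bonds, other.bonds + off])
        self.bond_r0 = np.concatenate([self.bond_r0, other.bond_r0])
        self.bond_k = np.concatenate([self.bond_k, other.bond_k])
        self.angles = np.vstack([self.angles, other.angles + off])
        self.angle_theta0 = np.concatenate([self.angle_theta0, other.angle_theta0])
        self.angle_k = np.concatenate([self.angle_k, other.angle_k])
        self.constraints = np.vstack([self.constraints, other.constraints + off])
        self.constraint_length = np.concatenate(
            [self.constraint_length, other.constraint_length])
        names = set(self.groups) | set(other.groups)
        for name in names:
            a = self.groups.get(name, np.zeros(off, dtype=bool))
            if a.shape[0] < off:  # group created after earlier merges
                a = np.concatenate([a, np.zeros(off - a.shape[0], dtype=bool)])
            b = other.groups.get(name, np.zeros(other.n_beads, dtype=bool))
            self.groups[name] = np.concatenate([a, b])

    def species_mask(self, name: str) -> np.ndarray:
        return np.array([s == name for s in self.species], dtype=bool)

    def concentration(self, species: str) -> float:
        """Molarity (mol/L) of molecules of ``species`` in the box volume."""
        mask = self.species_mask(species)
        n_mol = len(np.unique(self.mol[mask])) if mask.any() else 0
        return molarity(n_mol, float(np.prod(self.box)))


# ----------------------------------------------------------------------
# molecule builders
# ----------------------------------------------------------------------

def build_sds() -> tuple[MoleculeTemplate, MoleculeTemplate]:
    """SDS surfactant and its hydrated sodium counterion.

    A linear four-bead molecule: three apolar C1 tail beads attached to one
    anionic Qa (-1e) head bead, with a Qd (+1e) bead for the hydrated
    sodium ion.  Three bonds, two angles, net charge -1e.
    """
    spacing = 0.47
    pos = np.array([[i * spacing, 0.0, 0.0] for i in range(4)])
    r0, k = DEFAULT_BOND
    t0, ka = (180.0, 25.0)
    sds = MoleculeTemplate(
        name="SDS",
        bead_types=[C1_BEAD, C1_BEAD, C1_BEAD, QA_BEAD],
        positions=pos,
        bonds=[(0, 1, r0, k), (1, 2, r0, k), (2, 3, r0, k)],
        angles=[(0, 1, 2, t0, ka), (1, 2, 3, t0, ka)],
    )
    na = MoleculeTemplate(name="NA", bead_types=[QD_BEAD], positions=np.zeros((1, 3)))
    return sds, na


def build_counterion(sign: int) -> MoleculeTemplate:
    """Hydrated monovalent counterion: Qd (+1e) or Qa (-1e) single bead."""
    if sign > 0:
        return MoleculeTemplate(name="NA", bead_types=[QD_BEAD], positions=np.zeros((1, 3)))
    return MoleculeTemplate(name="CL", bead_types=[QA_BEAD], positions=np.zeros((1, 3)))


def build_polarizable_water() -> MoleculeTemplate:
    """Three-site polarizable water: central LJ bead + two charged satellites.

    Both satellite bonds are rigid constraints of length 0.14 nm; a harmonic
    angle with theta0 = 0 deg and K_theta = 2.1 kJ/mol/rad^2 (half-included)
    controls satellite rotation.  Satellite charges are +-0.46e; net 0.
    """
    d = WATER_CONSTRAINT
    pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0], [-d * 0.5, d * 0.866, 0.0]])
    t0, ka = WATER_ANGLE
    return MoleculeTemplate(
        name="PW",
        bead_types=[W_BEAD, WP_BEAD, WM_BEAD],
        positions=pos,
        constraints=[(0, 1, d), (0, 2, d)],
        angles=[(1, 0, 2, t0, ka)],
    )


def self_avoiding_walk(n: int, step: float, min_dist: float, rng: np.random.Generator,
                       max_retry: int = 200, start=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Place ``n`` points by a self-avoiding random walk of fixed step length.

    Steps violating the minimum self-distance to all previously placed
    non-adjacent points are resampled up to ``max_retry`` times; the walk
    restarts (up to ``max_retry`` restarts) if a step cannot be placed.
    """
    for _ in range(max_retry):
        pts = np.zeros((n, 3))
        pts[0] = start
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(max_retry):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pts[i - 1] + step * u
                prev = pts[: max(i - 1, 0)]  # non-adjacent predecessors
                if prev.shape[0] == 0 or np.min(
                        np.linalg.norm(prev - cand, axis=1)) >= min_dist:
                    pts[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise PackingError(
        f"self-avoiding walk failed after {max_retry} restarts; "
        "increase the step length or lower the minimum self-distance")


def build_cgg_chain(spec: ChainSpec, repeat_beads: int = GUAR_REPEAT_BEADS,
                    bond: tuple[float, float] = DEFAULT_BOND,
                    angle: tuple[float, float] | None = None,
                    ) -> MoleculeTemplate:
    """Build a cationic guar gum chain with the requested degree of substitution.

    The backbone (``repeat_beads`` beads per repeat unit, default 9) is laid
    down by a self-avoiding random walk; each functionalized monomer carries
    a P1 hydroxypropyl bead and a Q0 trimethylammonium bead (+1e) as a
    two-bead side chain on the repeat unit's last backbone bead.  Net charge
    is ``+round(ds * n_repeat)`` e.

    The minimum pairwise distance between non-bonded backbone beads is
    asserted post-build.
    """
    rng = np.random.default_rng(spec.seed)
    n_back = spec.n_repeat * repeat_beads
    backbone = self_avoiding_walk(n_back, spec.step, spec.min_self_distance, rng,
                                  max_retry=spec.max_retry)

    n_func = spec.n_functionalized
    if spec.placement == "regular" and n_func:
        func_idx = np.unique(np.linspace(0, spec.n_repeat - 1, n_func).round().astype(int))
    else:
        func_idx = np.sort(rng.choice(spec.n_repeat, size=n_func, replace=False))
    func_set = set(int(i) for i in func_idx)

    bead_types: list[BeadType] = []
    positions: list[np.ndarray] = []
    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    r0, kb = bond

    index_of_backbone: list[int] = []
    for m in range(spec.n_repeat):
        for b in range(repeat_beads):
            gi = len(bead_types)
            index_of_backbone.append(gi)
            bead_types.append(RING_BEAD)
            positions.append(backbone[m * repeat_beads + b])
            if m * repeat_beads + b > 0:
                bonds.append((gi - 1 if b > 0 else index_of_backbone[-2], gi, r0, kb))
        if m in func_set:
            attach = index_of_backbone[-1]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p1 = len(bead_types)
            bead_types.append(P1_BEAD)
            positions.append(positions[attach] + spec.step * u)
            bonds.append((attach, p1, r0, kb))
            q0 = len(bead_types)
            bead_types.append(Q0_BEAD)
            positions.append(positions[p1] + spec.step * u)
            bonds.append((p1, q0, r0, kb))
    if angle is not None:
        t0, ka = angle
        for a, b, c in zip(index_of_backbone, index_of_backbone[1:], index_of_backbone[2:]):
            angles.append((a, b, c, t0, ka))

    mol = MoleculeTemplate(name="CGG", bead_types=bead_types,
                           positions=np.array(positions), bonds=bonds, angles=angles)

    # post-build self-avoidance assertion on non-bonded backbone pairs
    bb = np.array([positions[i] for i in index_of_backbone])
    if len(bb) > 2:
        d = np.linalg.norm(bb[:, None, :] - bb[None, :, :], axis=-1)
        iu = np.triu_indices(len(bb), k=2)
        dmin = float(d[iu].min())
        if dmin < spec.min_self_distance - 1e-9:
            raise PackingError(
                f"self-avoidance violated post-build: min non-bonded distance "
                f"{dmin:.3f} nm < {spec.min_self_distance} nm")
    return mol


# ----------------------------------------------------------------------
# system assembly
# ----------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _min_image(d: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    for ax in range(3):
        if periodic[ax]:
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def assemble_bulk(templates_counts, box, neutralize: bool = False, seed: int = 0,
                  tol: float = 0.3, max_retry: int = 500,
                  periodic=(True, True, True)) -> SystemState:
    """Randomly insert molecules into a box without overlaps.

    ``templates_counts`` is a list of ``(MoleculeTemplate, count)``.  Each
    molecule is placed with a uniform random rotation and translation and
    rejected if any bead comes within ``tol`` nm of an existing bead
    (minimum-image).  With ``neutralize=True`` hydrated counterions are
    added so the net charge is exactly zero.
    """
    rng = np.random.default_rng(seed)
    state = SystemState(box, periodic)
    jobs = [(tpl, int(cnt)) for tpl, cnt in templates_counts]
    if neutralize:
        q = sum(tpl.net_charge * cnt for tpl, cnt in jobs)
        n_ions = int(round(abs(q)))
        if n_ions:
            jobs.append((build_counterion(-1 if q > 0 else +1), n_ions))
    for tpl, count in jobs:
        local = tpl.positions - tpl.positions.mean(axis=0)
        for _ in range(count):
            for attempt in range(max_retry):
                rot = _random_rotation(rng)
                shift = rng.uniform(0.0, 1.0, size=3) * state.box
                cand = local @ rot.T + shift
                if state.n_beads:
                    d = _min_image(cand[:, None, :] - state.pos[None, :, :],
                                   state.box, state.periodic)
                    if np.min(np.linalg.norm(d, axis=-1)) < tol:
                        continue
                state.add_molecule(tpl, cand)
                break
            else:
                raise PackingError(
                    f"could not insert {tpl.name} after {max_retry} attempts "
                    f"(box {state.box}, tol {tol} nm)")
    if neutralize and abs(state.net_charge) > 1e-9:
        raise PackingError("neutralization bookkeeping failed")  # pragma: no cover
    return state


def build_graft_surface(spec: SurfaceSpec, seed: int = 0) -> SystemState:
    """Rigid anchor sheet plus grafted linear chains.

    Anchor beads (tag ``lower_anchor``) form a square lattice at z = 0.
    ``round(density * area)`` lattice sites carry a grafted linear chain
    rising in +z; graft base beads are tagged ``graft_base`` for
    axis-restricted thermostatting.  A fraction of graft head beads carries
    -1e with a +1e hydrated counterion placed above, so the fragment is net
    neutral.
    """
    rng = np.random.default_rng(seed)
    nx = max(1, int(round(spec.lx / spec.anchor_spacing)))
    ny = max(1, int(round(spec.ly / spec.anchor_spacing)))
    n_sites = nx * ny
    if spec.n_grafts > n_sites:
        raise ValueError(
            f"graft density {spec.graft_density}/nm^2 exceeds lattice capacity "
            f"({spec.n_grafts} grafts > {n_sites} sites)")

    box = np.array([spec.lx, spec.ly, 40.0])
    state = SystemState(box, periodic=(True, True, False))
    xs = (np.arange(nx) + 0.5) * spec.lx / nx
    ys = (np.arange(ny) + 0.5) * spec.ly / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n_sites)])

    anchor = MoleculeTemplate(name="ANCHOR",
                              bead_types=[ANCHOR_BEAD] * n_sites,
                              positions=sites)
    idx = state.add_molecule(anchor, species="anchor")
    state.add_group("lower_anchor", np.zeros(state.n_beads, dtype=bool))
    state.groups["lower_anchor"][idx] = True

    graft_sites = rng.choice(n_sites, size=spec.n_grafts, replace=False)
    n_anionic = int(round(spec.anionic_fraction * spec.n_grafts))
    anionic = set(int(i) for i in rng.choice(spec.n_grafts, size=n_anionic, replace=False))
    r0, kb = spec.graft_bond
    dz = r0
    for g, site in enumerate(graft_sites):
        base = sites[site]
        types = [GRAFT_BEAD] * spec.graft_length
        if g in anionic:
            types[-1] = QA_BEAD
        pos = np.array([base + [0, 0, dz * (i + 1)] for i in range(spec.graft_length)])
        bonds = [(i, i + 1, r0, kb) for i in range(spec.graft_length - 1)]
        tpl = MoleculeTemplate(name="GRAFT", bead_types=types, positions=pos, bonds=bonds)
        gi = state.add_molecule(tpl, species="graft")
        if "graft_base" not in state.groups:
            state.add_group("graft_base", np.zeros(state.n_beads, dtype=bool))
        state.groups["graft_base"][gi[0]] = True
        if g in anionic:
            ion = build_counterion(+1)
            jitter = rng.uniform(-0.1, 0.1, size=2)
            ion_pos = np.array([[base[0] + jitter[0], base[1] + jitter[1],
                                 dz * (spec.graft_length + 1)]])
            state.add_molecule(ion, ion_pos, species="counterion")
    return state


def make_contact(surface_system: SystemState, adsorbate_system: SystemState | None,
                 gap: float) -> SystemState:
    """Confine an adsorbate between a surface and its mirror image.

    The upper surface is the reflection of ``surface_system`` through the
    mid-plane at ``z = z_top + gap/2`` where ``z_top`` is the highest bead
    of the lower surface; its anchor tag becomes ``upper_anchor``.  The
    adsorbate (if any) must match the surface laterally and is placed
    unchanged.
    """
    lower = surface_system.copy()
    z_top = float(lower.pos[:, 2].max())
    upper = surface_system.copy()
    upper.pos[:, 2] = 2.0 * z_top + gap - upper.pos[:, 2]
    if "lower_anchor" in upper.groups:
        upper.groups["upper_anchor"] = upper.groups.pop("lower_anchor")

    out = lower
    if adsorbate_system is not None:
        if not np.allclose(adsorbate_system.box[:2], lower.box[:2]):
            raise ValueError(
                f"lateral dimensions mismatch: surface {lower.box[:2]} vs "
                f"adsorbate {adsorbate_system.box[:2]}")
        ads = adsorbate_system.copy()
        out.merge(ads)
    out.merge(upper)
    out.box[2] = 2.0 * z_top + gap + 2.0  # headroom; z non-periodic
    out.periodic[2] = False
    return out
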