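"""Structure and trajectory I/O.

Writers emit LAMMPS data files (``atom_style full``, LAMMPS *real* units:
angstrom, kcal/mol, fs), GRO coordinate files (nm) and LAMMPS dump
trajectories (angstrom).  Reading of third-party trajectories (LAMMPS dump,
GRO/XTC-style series, data files) goes through MDAnalysis via
:func:`load_trajectory`; the package-native readers below exist so that a
data file written here round-trips with its bonded parameters and group
tags intact, which a generic topology reader cannot preserve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .builder import SystemState
from .units import KJ_TO_KCAL, NM_TO_A, NMPS_TO_AFS

__all__ = [
    "Trajectory",
    "load_trajectory",
    "write_lammps_data",
    "read_lammps_data",
    "write_gro",
    "read_gro",
    "write_lammps_dump",
]


class ParseError(ValueError):
    """Malformed structure file; the message names the offending line."""


@dataclass
class Trajectory:
    """A lightweight coordinate series with atom metadata (internal nm units).

    ``frames`` is a list of (n_atoms, 3) arrays; ``boxes`` a matching list
    of (3,) orthorhombic box lengths (or a single array reused for all
    frames).
    """

    names: list[str]
    resids: np.ndarray
    resnames: list[str]
    masses: np.ndarray
    frames: list[np.ndarray]
    boxes: list[np.ndarray] | None = None
    velocities: list[np.ndarray] | None = field(default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def box(self, frame: int) -> np.ndarray | None:
        if self.boxes is None:
            return None
        return self.boxes[frame if len(self.boxes) > 1 else 0]


_DEFAULT_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45,
}


def guess_mass(atom_name: str) -> float:
    """Guess an atomic mass from the leading element letters of a name."""
    upper = atom_name.upper()
    for sym in ("CL", "NA"):
        if upper.startswith(sym):
            return _DEFAULT_ELEMENT_MASS[sym]
    if upper and upper[0] in _DEFAULT_ELEMENT_MASS:
        return _DEFAULT_ELEMENT_MASS[upper[0]]
    raise ValueError(f"cannot guess a mass for atom name {atom_name!r}")


def load_trajectory(topology: str, trajectory: str | None = None,
                    masses: np.ndarray | None = None) -> Trajectory:
    """Read a trajectory through MDAnalysis and convert to internal units.

    Accepts anything MDAnalysis can parse (GRO, LAMMPS data + dump, XTC...).
    MDAnalysis works in angstrom; coordinates and boxes are converted to nm.
    """
    import MDAnalysis as mda

    kwargs = {}
    if topology.endswith(".dump"):
        kwargs["format"] = kwargs["topology_format"] = "LAMMPSDUMP"
    elif topology.endswith(".data"):
        kwargs["topology_format"] = "DATA"
        kwargs["atom_style"] = "id resid type charge x y z"
    args = (topology,) if trajectory is None else (topology, trajectory)
    u = mda.Universe(*args, **kwargs)
    atoms = u.atoms
    names = [getattr(a, "name", str(a.ix)) for a in atoms]
    try:
        resids = atoms.resids.copy()
        resnames = list(atoms.resnames)
    except Exception:
        resids = np.ones(len(atoms), dtype=int)
        resnames = ["MOL"] * len(atoms)
    if masses is None:
        try:
            masses = atoms.masses.copy()
            if np.any(masses <= 0):
                raise ValueError
        except Exception:
            masses = np.array([guess_mass(n) for n in names])
    frames, boxes = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float) / NM_TO_A)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / NM_TO_A)
    return Trajectory(names=names, resids=np.asarray(resids), resnames=resnames,
                      masses=np.asarray(masses, dtype=float), frames=frames, boxes=boxes)


# ----------------------------------------------------------------------
# LAMMPS data (atom_style full, real units)
# ----------------------------------------------------------------------

def write_lammps_data(state: SystemState) -> str:
    """Serialize a :class:`SystemState` to a LAMMPS data file (real units).

    Bead-type names are recorded as ``#`` comments on the Masses lines;
    rigid constraints are encoded as extra bond types whose Bond Coeffs
    line carries a ``# constraint`` comment, so the file is both readable
    by LAMMPS and exactly invertible by :func:`read_lammps_data`.
    """
    type_labels: list[str] = []
    type_info: dict[str, tuple[float, float, str]] = {}
    for name, m, q, lj in zip(state.type_names, state.mass, state.charge, state.lj_class):
        if name not in type_info:
            type_info[name] = (m, q, lj)
            type_labels.append(name)
    type_id = {name: i + 1 for i, name in enumerate(type_labels)}

    bond_params: list[tuple[float, float, bool]] = []  # (r0, k, is_constraint)
    bond_type_of: dict[tuple[float, float, bool], int] = {}

    def bond_type(r0: float, k: float, constraint: bool) -> int:
        key = (round(r0, 12), round(k, 12), constraint)
        if key not in bond_type_of:
            bond_params.append((r0, k, constraint))
            bond_type_of[key] = len(bond_params)
        return bond_type_of[key]

    bond_rows = [(bond_type(r0, k, False), i + 1, j + 1)
                 for (i, j), r0, k in zip(state.bonds, state.bond_r0, state.bond_k)]
    bond_rows += [(bond_type(d, 0.0, True), i + 1, j + 1)
                  for (i, j), d in zip(state.constraints, state.constraint_length)]

    angle_params: list[tuple[float, float]] = []
    angle_type_of: dict[tuple[float, float], int] = {}
    angle_rows = []
    for (i, j, k), t0, ka in zip(state.angles, state.angle_theta0, state.angle_k):
        key = (round(t0, 12), round(ka, 12))
        if key not in angle_type_of:
            angle_params.append((t0, ka))
            angle_type_of[key] = len(angle_params)
        angle_rows.append((angle_type_of[key], i + 1, j + 1, k + 1))

    L = [f"LAMMPS data file (cgtribo, real units)", ""]
    L.append(f"{state.n_beads} atoms")
    L.append(f"{len(bond_rows)} bonds")
    L.append(f"{len(angle_rows)} angles")
    L.append("")
    L.append(f"{len(type_labels)} atom types")
    if bond_params:
        L.append(f"{len(bond_params)} bond types")
    if angle_params:
        L.append(f"{len(angle_params)} angle types")
    L.append("")
    for ax, lo_name in zip(range(3), ("x", "y", "z")):
        hi = state.box[ax] * NM_TO_A
        L.append(f"0.0 {hi:.6f} {lo_name}lo {lo_name}hi")
    flags = "".join("p" if p else "f" for p in state.periodic)
    L.append(f"# periodicity: {flags}")
    L.append("")
    L.append("Masses")
    L.append("")
    for name in type_labels:
        m, q, lj = type_info[name]
        L.append(f"{type_id[name]} {m:.6f}  # {name} lj_class={lj} charge={float(q)!r}")
    if bond_params:
        L += ["", "Bond Coeffs  # harmonic", ""]
        for t, (r0, k, con) in enumerate(bond_params, start=1):
            k_real = k * KJ_TO_KCAL / NM_TO_A**2
            tail = "  # constraint" if con else ""
            L.append(f"{t} {k_real:.8f} {r0 * NM_TO_A:.6f}{tail}")
    if angle_params:
        L += ["", "Angle Coeffs  # harmonic", ""]
        for t, (t0, ka) in enumerate(angle_params, start=1):
            L.append(f"{t} {ka * KJ_TO_KCAL:.8f} {math.degrees(t0):.6f}")
    L += ["", "Atoms  # full", ""]
    for i in range(state.n_beads):
        x, y, z = state.pos[i] * NM_TO_A
        L.append(f"{i + 1} {state.mol[i] + 1} {type_id[state.type_names[i]]} "
                 f"{float(state.charge[i])!r} {x:.8f} {y:.8f} {z:.8f}")
    L += ["", "Velocities", ""]
    for i in range(state.n_beads):
        vx, vy, vz = state.vel[i] * NMPS_TO_AFS
        L.append(f"{i + 1} {vx:.10e} {vy:.10e} {vz:.10e}")
    if bond_rows:
        L += ["", "Bonds", ""]
        for n, (t, i, j) in enumerate(bond_rows, start=1):
            L.append(f"{n} {t} {i} {j}")
    if angle_rows:
        L += ["", "Angles", ""]
        for n, (t, i, j, k) in enumerate(angle_rows, start=1):
            L.append(f"{n} {t} {i} {j} {k}")
    return "\n".join(L) + "\n"


def read_lammps_data(text: str) -> SystemState:
    """Parse a data file written by :func:`write_lammps_data` back to a state."""
    lines = text.splitlines()
    n_atoms = n_bonds = n_angles = 0
    box = np.zeros(3)
    periodic = np.array([True, True, True])
    section = None
    masses: dict[int, tuple[float, str, str, float]] = {}
    bond_coeffs: dict[int, tuple[float, float, bool]] = {}
    angle_coeffs: dict[int, tuple[float, float]] = {}
    atoms: dict[int, tuple[int, int, float, np.ndarray]] = {}
    vels: dict[int, np.ndarray] = {}
    bond_list: list[tuple[int, int, int]] = []
    angle_list: list[tuple[int, int, int, int]] = []

    known_sections = ("Masses", "Bond Coeffs", "Angle Coeffs", "Atoms",
                      "Velocities", "Bonds", "Angles")
    for lineno, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if lineno <= 1 or not stripped:
            continue
        if stripped.startswith("# periodicity:"):
            flags = stripped.split(":", 1)[1].strip()
            periodic = np.array([c == "p" for c in flags])
            continue
        head = stripped.split("#")[0].strip()
        if not head:
            continue
        if any(head.startswith(s) for s in known_sections):
            section = next(s for s in known_sections if head.startswith(s))
            continue
        fields = head.split()
        if section is None:
            if head.endswith("atoms"):
                n_atoms = int(fields[0])
            elif head.endswith("bonds"):
                n_bonds = int(fields[0])
            elif head.endswith("angles"):
                n_angles = int(fields[0])
            elif head.endswith(("xhi", "yhi", "zhi")):
                ax = "xyz".index(head[-3])
                box[ax] = (float(fields[1]) - float(fields[0])) / NM_TO_A
            elif head.endswith("types"):
                continue
            elif fields and not fields[0].lstrip("-").replace(".", "").isdigit():
                raise ParseError(f"line {lineno}: unknown header {head!r}")
            continue
        comment = raw.split("#", 1)[1] if "#" in raw else ""
        if not fields[0].lstrip("-").replace(".", "").isdigit():
            raise ParseError(f"line {lineno}: unknown section header {head!r}")
        if section == "Masses":
            tid = int(fields[0])
            name, lj, q = f"T{tid}", f"T{tid}", 0.0
            for tok in comment.split():
                if tok.startswith("lj_class="):
                    lj = tok.split("=", 1)[1]
                elif tok.startswith("charge="):
                    q = float(tok.split("=", 1)[1])
                else:
                    name = tok
            masses[tid] = (float(fields[1]), name, lj, q)
        elif section == "Bond Coeffs":
            k = float(fields[1]) / KJ_TO_KCAL * NM_TO_A**2
            r0 = float(fields[2]) / NM_TO_A
            bond_coeffs[int(fields[0])] = (r0, k, "constraint" in comment)
        elif section == "Angle Coeffs":
            angle_coeffs[int(fields[0])] = (math.radians(float(fields[2])),
                                            float(fields[1]) / KJ_TO_KCAL)
        elif section == "Atoms":
            aid, mol, tid = int(fields[0]), int(fields[1]), int(fields[2])
            q = float(fields[3])
            xyz = np.array([float(v) for v in fields[4:7]]) / NM_TO_A
            atoms[aid] = (mol, tid, q, xyz)
        elif section == "Velocities":
            vels[int(fields[0])] = np.array([float(v) for v in fields[1:4]]) / NMPS_TO_AFS
        elif section == "Bonds":
            bond_list.append((int(fields[1]), int(fields[2]), int(fields[3])))
        elif section == "Angles":
            angle_list.append((int(fields[1]), int(fields[2]), int(fields[3]),
                               int(fields[4])))

    if len(atoms) != n_atoms:
        raise ParseError(f"expected {n_atoms} atoms, found {len(atoms)}")
    state = SystemState(box, periodic)
    order = sorted(atoms)
    idx_of = {aid: i for i, aid in enumerate(order)}
    state.pos = np.array([atoms[a][3] for a in order]).reshape(-1, 3)
    state.vel = np.array([vels.get(a, np.zeros(3)) for a in order]).reshape(-1, 3)
    state.mol = np.array([atoms[a][0] - 1 for a in order], dtype=int)
    state.charge = np.array([atoms[a][2] for a in order])
    state.mass = np.array([masses[atoms[a][1]][0] for a in order])
    state.type_names = [masses[atoms[a][1]][1] for a in order]
    state.lj_class = [masses[atoms[a][1]][2] for a in order]
    state.species = list(state.type_names)
    bonds, br0, bk, cons, clen = [], [], [], [], []
    for t, i, j in bond_list:
        r0, k, is_con = bond_coeffs[t]
        if is_con:
            cons.append((idx_of[i], idx_of[j]))
            clen.append(r0)
        else:
            bonds.append((idx_of[i], idx_of[j]))
            br0.append(r0)
            bk.append(k)
    state.bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    state.bond_r0 = np.array(br0)
    state.bond_k = np.array(bk)
    state.constraints = np.array(cons, dtype=int).reshape(-1, 2)
    state.constraint_length = np.array(clen)
    ang, at0, ak = [], [], []
    for t, i, j, k in angle_list:
        t0, kk = angle_coeffs[t]
        ang.append((idx_of[i], idx_of[j], idx_of[k]))
        at0.append(t0)
        ak.append(kk)
    state.angles = np.array(ang, dtype=int).reshape(-1, 3)
    state.angle_theta0 = np.array(at0)
    state.angle_k = np.array(ak)
    return state


# ----------------------------------------------------------------------
# GRO
# ----------------------------------------------------------------------

def write_gro(state: SystemState, title: str = "cgtribo system") -> str:
    """GRO coordinate file (positions nm %8.3f, velocities nm/ps %8.4f)."""
    L = [title, f"{state.n_beads:5d}"]
    for i in range(state.n_beads):
        resid = (state.mol[i] + 1) % 100000
        resname = state.species[i][:5]
        name = state.type_names[i][:5]
        x, y, z = state.pos[i]
        vx, vy, vz = state.vel[i]
        L.append(f"{resid:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}"
                 f"{x:8.3f}{y:8.3f}{z:8.3f}{vx:8.4f}{vy:8.4f}{vz:8.4f}")
    L.append(f"{state.box[0]:10.5f}{state.box[1]:10.5f}{state.box[2]:10.5f}")
    return "\n".join(L) + "\n"


def read_gro(text: str) -> SystemState:
    """Parse a GRO file into a bare state (no bonded terms)."""
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("GRO file too short")
    n = int(lines[1])
    box_fields = lines[2 + n].split()
    state = SystemState(np.array([float(v) for v in box_fields[:3]]))
    pos, vel, mols, names, res = [], [], [], [], []
    for lineno in range(2, 2 + n):
        line = lines[lineno]
        try:
            mols.append(int(line[0:5]) - 1)
            res.append(line[5:10].strip())
            names.append(line[10:15].strip())
            pos.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
            if len(line.rstrip()) >= 68:
                vel.append([float(line[44:52]), float(line[52:60]), float(line[60:68])])
            else:
                vel.append([0.0, 0.0, 0.0])
        except ValueError as exc:
            raise ParseError(f"line {lineno + 1}: malformed GRO atom line") from exc
    state.pos = np.array(pos).reshape(-1, 3)
    state.vel = np.array(vel).reshape(-1, 3)
    state.mol = np.array(mols, dtype=int)
    state.type_names = names
    state.lj_class = list(names)
    state.species = res
    state.mass = np.full(n, 72.0)
    state.charge = np.zeros(n)
    return state


# ----------------------------------------------------------------------
# LAMMPS dump trajectories
# ----------------------------------------------------------------------

def write_lammps_dump(frames, box, path, types=None, velocities=None,
                      periodic=(True, True, True), timesteps=None) -> None:
    """Write a coordinate series as a LAMMPS dump (angstrom) readable by
    MDAnalysis.

    ``frames``: list of (n, 3) nm arrays; ``box``: (3,) nm or list thereof.
    """
    box = np.asarray(box, dtype=float)
    boxes = [box] * len(frames) if box.ndim == 1 else list(box)
    n = frames[0].shape[0]
    t_arr = types if types is not None else np.ones(n, dtype=int)
    flags = " ".join("pp" if p else "ff" for p in periodic)
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            step = timesteps[fi] if timesteps is not None else fi
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
            fh.write(f"ITEM: BOX BOUNDS {flags}\n")
            for ax in range(3):
                fh.write(f"0.0 {boxes[fi][ax] * NM_TO_A:.8f}\n")
            if velocities is not None:
                fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
                for i in range(n):
                    x, y, z = frame[i] * NM_TO_A
                    vx, vy, vz = velocities[fi][i] * NM_TO_A  # A/ps
                    fh.write(f"{i + 1} {t_arr[i]} {x:.6f} {y:.6f} {z:.6f} "
                             f"{vx:.6f} {vy:.6f} {vz:.6f}\n")
            else:
                fh.write("ITEM: ATOMS id type x y z\n")
                for i in range(n):
                    x, y, z = frame[i] * NM_TO_A
                    fh.write(f"{i + 1} {t_arr[i]} {x:.6f} {y:.6f} {z:.6f}\n")
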