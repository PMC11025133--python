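"""Atomistic-to-coarse-grained mapping and Boltzmann-inversion fitting.

Atomistic trajectories are mapped onto beads (mass-weighted centers of the
member atoms, with minimum-image unwrapping), bond/angle samples are pooled
per type, and harmonic parameters are recovered by Gaussian moment matching
of the Boltzmann distribution:

    r0      = <r>,          K       = k_B T / (2 Var(r))
    theta0  = <theta>_w,    K_theta = k_B T / (2 Var_w(theta))

in the half-included convention E = K delta^2.  For angles the equilibrium
distribution of a 3D chain carries a sin(theta) geometric factor; samples
are reweighted by 1/sin(theta) before moment matching (``jacobian=True``,
the default) so the fitted potential is the one that generates the
observed distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .forcefield import (HALF_INCLUDED, BondedParameterTable, convert_convention)
from .io import Trajectory, guess_mass
from .units import KB

__all__ = [
    "BeadDef",
    "MappingScheme",
    "MappedTrajectory",
    "BondedTopology",
    "DistributionSet",
    "MappingError",
    "DegenerateDistributionError",
    "map_trajectory",
    "collect_distributions",
    "fit_harmonic_bond",
    "fit_harmonic_angle",
    "fit_parameter_table",
    "compare_distributions",
    "plot_distributions",
]

logger = logging.getLogger(__name__)


class MappingError(ValueError):
    """An atom referenced by the mapping is missing from the trajectory."""


class DegenerateDistributionError(ValueError):
    """All samples identical: the distribution carries no force-constant
    information.  Consider a rigid constraint instead of a harmonic bond."""


@dataclass(frozen=True)
class BeadDef:
    """One bead of a residue mapping: name, type label and member atoms."""

    name: str
    type_name: str
    atoms: tuple[str, ...]
    masses: tuple[float, ...] | None = None

    def atom_masses(self) -> np.ndarray:
        if self.masses is not None:
            return np.asarray(self.masses, dtype=float)
        return np.array([guess_mass(a) for a in self.atoms])


@dataclass
class MappingScheme:
    """Per-residue bead definitions.

    Every atom of a residue must appear in exactly one bead (hydrogens are
    folded into their heavy atom's bead by listing them as members).  The
    ~4:1 heavy-atom-to-bead ratio of the underlying model is advisory and
    not enforced.
    """

    residues: dict[str, list[BeadDef]] = field(default_factory=dict)

    def __post_init__(self):
        for resname, beads in self.residues.items():
            seen: dict[str, str] = {}
            for bead in beads:
                for atom in bead.atoms:
                    if atom in seen:
                        raise MappingError(
                            f"residue {resname}: atom {atom!r} appears in beads "
                            f"{seen[atom]!r} and {bead.name!r}")
                    seen[atom] = bead.name

    def beads_for(self, resname: str) -> list[BeadDef]:
        try:
            return self.residues[resname]
        except KeyError:
            raise MappingError(f"no mapping for residue {resname!r}") from None

    @classmethod
    def from_yaml(cls, text: str) -> "MappingScheme":
        data = yaml.safe_load(text)
        residues = {}
        for resname, beads in data["residues"].items():
            residues[resname] = [
                BeadDef(name=b["name"], type_name=b.get("type", b["name"]),
                        atoms=tuple(b["atoms"]),
                        masses=tuple(b["masses"]) if "masses" in b else None)
                for b in beads
            ]
        return cls(residues=residues)

    def to_yaml(self) -> str:
        data = {"residues": {
            resname: [
                {"name": b.name, "type": b.type_name, "atoms": list(b.atoms),
                 **({"masses": list(b.masses)} if b.masses is not None else {})}
                for b in beads]
            for resname, beads in self.residues.items()}}
        return yaml.safe_dump(data, sort_keys=False)


@dataclass
class MappedTrajectory:
    """Bead coordinate series produced by :func:`map_trajectory`."""

    bead_names: list[str]
    bead_types: list[str]
    bead_masses: np.ndarray
    frames: list[np.ndarray]
    boxes: list[np.ndarray] | None = None

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def box(self, frame: int) -> np.ndarray | None:
        if self.boxes is None:
            return None
        return self.boxes[frame if len(self.boxes) > 1 else 0]


@dataclass
class BondedTopology:
    """Bond/angle instances over mapped beads, labelled by type."""

    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)

    def validate(self, n_beads: int) -> None:
        for i, j, label in self.bonds:
            if not (0 <= i < n_beads and 0 <= j < n_beads):
                raise ValueError(f"bond {label!r} ({i},{j}) references missing bead")
        for i, j, k, label in self.angles:
            if not all(0 <= x < n_beads for x in (i, j, k)):
                raise ValueError(f"angle {label!r} ({i},{j},{k}) references missing bead")

    @classmethod
    def linear_chain(cls, bead_types: list[str]) -> "BondedTopology":
        """Consecutive bonds/angles of a linear chain, labelled by the
        joined bead-type names."""
        topo = cls()
        for i in range(len(bead_types) - 1):
            topo.bonds.append((i, i + 1, f"{bead_types[i]}-{bead_types[i + 1]}"))
        for i in range(len(bead_types) - 2):
            topo.angles.append(
                (i, i + 1, i + 2,
                 f"{bead_types[i]}-{bead_types[i + 1]}-{bead_types[i + 2]}"))
        return topo


@dataclass
class DistributionSet:
    """Pooled bond/angle samples per type label (bond nm, angle rad)."""

    bonds: dict[str, np.ndarray] = field(default_factory=dict)
    angles: dict[str, np.ndarray] = field(default_factory=dict)
    temperature: float = 300.0

    def histogram(self, label: str, kind: str = "bond",
                  bins="auto") -> tuple[np.ndarray, np.ndarray]:
        """Freedman-Diaconis (default) histogram of one distribution."""
        samples = (self.bonds if kind == "bond" else self.angles)[label]
        bins = "fd" if bins == "auto" else bins
        counts, edges = np.histogram(samples, bins=bins)
        return counts, edges

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, table in (("bond", self.bonds), ("angle", self.angles)):
            for label, s in table.items():
                rows.append({"kind": kind, "type": label, "n": len(s),
                             "mean": float(np.mean(s)), "std": float(np.std(s))})
        return pd.DataFrame(rows)


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def map_trajectory(traj: Trajectory, scheme: MappingScheme,
                   com_mode: str = "mass") -> MappedTrajectory:
    """Map an atomistic trajectory onto beads.

    Each bead position is the (mass- or geometry-) weighted center of its
    member atoms, computed with minimum-image unwrapping relative to the
    bead's first member atom, then wrapped back into the box.

    Raises
    ------
    MappingError
        If a mapped atom name is missing from a residue, listing the
        residue and bead.
    """
    if com_mode not in ("mass", "geometry"):
        raise ValueError(f"unknown com_mode {com_mode!r}")

    # group atoms by residue instance, preserving order of first appearance
    residue_order: list[tuple[int, str]] = []
    atom_index: dict[tuple[int, str], dict[str, int]] = {}
    for i, (rid, rname, aname) in enumerate(zip(traj.resids, traj.resnames, traj.names)):
        key = (int(rid), rname)
        if key not in atom_index:
            atom_index[key] = {}
            residue_order.append(key)
        atom_index[key][aname] = i

    bead_names: list[str] = []
    bead_types: list[str] = []
    bead_masses: list[float] = []
    members: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for rid, rname in residue_order:
        index = atom_index[(rid, rname)]
        for bead in scheme.beads_for(rname):
            try:
                idx = np.array([index[a] for a in bead.atoms])
            except KeyError as exc:
                raise MappingError(
                    f"residue {rname}:{rid}, bead {bead.name!r}: "
                    f"atom {exc.args[0]!r} not found") from None
            m = traj.masses[idx]
            w = m if com_mode == "mass" else np.ones_like(m)
            bead_names.append(f"{rname}{rid}:{bead.name}")
            bead_types.append(bead.type_name)
            bead_masses.append(float(m.sum()))
            members.append(idx)
            weights.append(w / w.sum())

    # vectorize over frames: one pass per bead
    T = traj.n_frames
    stack = np.stack(traj.frames) if T else np.zeros((0, traj.n_atoms, 3))
    boxes = (np.stack([traj.box(fi) for fi in range(T)])
             if traj.boxes is not None else None)
    out = np.empty((T, len(members), 3))
    for b, (idx, w) in enumerate(zip(members, weights)):
        ref = stack[:, idx[0], :]
        d = stack[:, idx, :] - ref[:, None, :]
        if boxes is not None:
            bx = boxes[:, None, :]
            d -= bx * np.round(d / bx)
        com = ref + np.einsum("j,tjk->tk", w, d)
        if boxes is not None:
            com = com % boxes
        out[:, b] = com
    frames_out = list(out)
    return MappedTrajectory(bead_names=bead_names, bead_types=bead_types,
                            bead_masses=np.asarray(bead_masses),
                            frames=frames_out, boxes=traj.boxes)


def collect_distributions(traj: MappedTrajectory, topology: BondedTopology,
                          temperature: float = 300.0) -> DistributionSet:
    """Pool one sample per frame per bond/angle instance, by type label.

    Frames in which an angle's arm vector has zero length are skipped for
    that angle with a logged warning.
    """
    topology.validate(traj.n_beads)
    bonds: dict[str, list[np.ndarray]] = {}
    angles: dict[str, list[np.ndarray]] = {}

    bond_idx = np.array([(i, j) for i, j, _ in topology.bonds], dtype=int).reshape(-1, 2)
    bond_labels = [label for *_, label in topology.bonds]
    ang_idx = np.array([(i, j, k) for i, j, k, _ in topology.angles],
                       dtype=int).reshape(-1, 3)
    ang_labels = [label for *_, label in topology.angles]

    T = traj.n_frames
    stack = np.stack(traj.frames) if T else np.zeros((0, traj.n_beads, 3))
    boxes = (np.stack([traj.box(fi) for fi in range(T)])[:, None, :]
             if traj.boxes is not None else None)

    def mi(d):
        return d if boxes is None else d - boxes * np.round(d / boxes)

    if len(bond_idx):
        d = mi(stack[:, bond_idx[:, 1], :] - stack[:, bond_idx[:, 0], :])
        r = np.linalg.norm(d, axis=2)  # (T, n_bonds)
        for bi, label in enumerate(bond_labels):
            bonds.setdefault(label, []).append(r[:, bi])
    if len(ang_idx):
        u = mi(stack[:, ang_idx[:, 0], :] - stack[:, ang_idx[:, 1], :])
        v = mi(stack[:, ang_idx[:, 2], :] - stack[:, ang_idx[:, 1], :])
        nu = np.linalg.norm(u, axis=2)
        nv = np.linalg.norm(v, axis=2)
        bad = (nu == 0) | (nv == 0)
        if bad.any():
            logger.warning("%d angle sample(s) with zero-length arm skipped",
                           int(bad.sum()))
        cosang = np.einsum("tij,tij->ti", u, v) / np.where(bad, 1.0, nu * nv)
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        for ai, label in enumerate(ang_labels):
            keep = ~bad[:, ai]
            angles.setdefault(label, []).append(theta[keep, ai])
    return DistributionSet(
        bonds={k: np.concatenate(v) for k, v in bonds.items()},
        angles={k: np.concatenate(v) for k, v in angles.items()},
        temperature=temperature)


def _check_samples(samples: np.ndarray) -> np.ndarray:
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2 or np.unique(samples).size < 2:
        raise DegenerateDistributionError(
            "need >= 2 distinct samples; identical samples imply zero variance "
            "(use a rigid constraint rather than a harmonic bond)")
    return samples


def fit_harmonic_bond(samples, temperature: float,
                      convention: str = HALF_INCLUDED) -> tuple[float, float]:
    """Fit (r0 nm, K kJ/mol/nm^2) by Gaussian moment matching.

    r0 is the sample mean; the half-included force constant is
    ``k_B T / (2 Var(r))`` (population variance).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    samples = _check_samples(samples)
    r0 = float(samples.mean())
    var = float(samples.var())
    k_half = KB * temperature / (2.0 * var)
    return r0, convert_convention(k_half, HALF_INCLUDED, convention)


def fit_harmonic_angle(samples, temperature: float, jacobian: bool = True,
                       convention: str = HALF_INCLUDED) -> tuple[float, float]:
    """Fit (theta0 deg, K_theta kJ/mol/rad^2) by (weighted) moment matching.

    With ``jacobian=True`` samples are reweighted by 1/sin(theta) before
    moment matching, undoing the geometric factor of 3D chain statistics;
    samples at exactly 0 or pi are dropped with a warning in that mode.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    samples = np.asarray(samples, dtype=float).ravel()
    if np.any((samples < 0) | (samples > np.pi + 1e-12)):
        raise ValueError("angle samples must lie in [0, pi] (radians)")
    if jacobian:
        s = np.sin(samples)
        keep = s > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} sample(s) at exactly "
                          "0 or pi (1/sin(theta) weight undefined)")
        samples, s = samples[keep], s[keep]
        _check_samples(samples)
        w = 1.0 / s
        w /= w.sum()
        mean = float(w @ samples)
        var = float(w @ (samples - mean) ** 2)
    else:
        samples = _check_samples(samples)
        mean = float(samples.mean())
        var = float(samples.var())
    if var == 0:
        raise DegenerateDistributionError("zero variance after weighting")
    k_half = KB * temperature / (2.0 * var)
    return float(np.degrees(mean)), convert_convention(k_half, HALF_INCLUDED, convention)


def fit_parameter_table(dists: DistributionSet, jacobian: bool = True,
                        convention: str = HALF_INCLUDED) -> BondedParameterTable:
    """Fit every distribution in a set into a :class:`BondedParameterTable`.

    Bond labels of the form ``"A-B"`` / angle labels ``"A-B-C"`` become the
    type tuples of the table.
    """
    table = BondedParameterTable(convention=convention)
    for label, samples in dists.bonds.items():
        r0, k = fit_harmonic_bond(samples, dists.temperature, convention)
        parts = tuple(label.split("-")) if label.count("-") == 1 else (label, label)
        table.bonds[parts] = (r0, k)
    for label, samples in dists.angles.items():
        t0, k = fit_harmonic_angle(samples, dists.temperature, jacobian, convention)
        parts = tuple(label.split("-")) if label.count("-") == 2 else (label,) * 3
        table.angles[parts] = (t0, k)
    return table


def overlap_coefficient(a: np.ndarray, b: np.ndarray, bins: int | str = 60
                        ) -> tuple[float, float]:
    """Overlap (integral of min of the two normalized histograms on a common
    grid) and difference of means."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0, 0.0
    if isinstance(bins, str):
        edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=bins)
    else:
        edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    width = np.diff(edges)
    ovl = float(np.sum(np.minimum(pa, pb) * width))
    return ovl, float(a.mean() - b.mean())


def plot_distributions(ref: DistributionSet, test: DistributionSet | None = None,
                       path: str | None = None):
    """Histogram panel per bond/angle type, optionally overlaying a second
    set (e.g. reference vs resimulated); saves to ``path`` if given.

    Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = [("bond (nm)", label, ref.bonds[label],
               None if test is None else test.bonds.get(label))
              for label in ref.bonds]
    panels += [("angle (rad)", label, ref.angles[label],
                None if test is None else test.angles.get(label))
               for label in ref.angles]
    n = max(len(panels), 1)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 2.8), squeeze=False)
    for ax, (unit, label, a, b) in zip(axes[0], panels):
        edges = np.histogram_bin_edges(a if b is None else np.concatenate([a, b]),
                                       bins=50)
        ax.hist(a, bins=edges, density=True, alpha=0.6, label="reference")
        if b is not None:
            ax.hist(b, bins=edges, density=True, alpha=0.6, histtype="step",
                    lw=1.5, label="test")
        ax.set_title(label, fontsize=9)
        ax.set_xlabel(unit)
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def compare_distributions(ref: DistributionSet, test: DistributionSet,
                          bins: int = 60) -> pd.DataFrame:
    """Per-type overlap coefficient and difference of means.

    Raises
    ------
    ValueError
        If the two sets do not cover the same bond/angle types, listing
        the mismatch.
    """
    rows = []
    for kind, rtab, ttab in (("bond", ref.bonds, test.bonds),
                             ("angle", ref.angles, test.angles)):
        if set(rtab) != set(ttab):
            missing = set(rtab) ^ set(ttab)
            raise ValueError(f"{kind} type sets differ; mismatched: {sorted(missing)}")
        for label in rtab:
            ovl, dmean = overlap_coefficient(rtab[label], ttab[label], bins)
            rows.append({"kind": kind, "type": label, "overlap": ovl,
                         "mean_difference": dmean})
    return pd.DataFrame(rows)
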