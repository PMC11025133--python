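"""Synthetic-data generators with statistically controlled properties.

These stand in for cluster-scale inputs: pseudo-atomistic trajectories
with prescribed bond/angle Boltzmann distributions (for the mapping and
inversion pipeline), confined-film trajectories with prescribed layering
and Couette flow (for the profile analysis), and friction datasets with
known friction coefficient, Derjaguin offset and velocity exponent (for
the friction-law fits).

All generators are deterministic in (spec, seed).  Independent substreams
are derived by ``SeedSequence`` spawning keyed on the item index, so
adding one species or frame type does not perturb the others.

Sampling note: bond lengths are drawn with the r^2 spherical-volume factor
and bending angles with the sin(theta) factor (by rejection against the
plain Gaussian envelope), because those geometric factors are present in
real equilibrium chain statistics; the inversion estimators are designed
against exactly these distributions.  ``gen_boltzmann_samples`` itself is
the plain Gaussian implied by the half-included harmonic Boltzmann factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import FrictionRecord
from .io import Trajectory
from .mapping import BondedTopology, MappingScheme
from .units import KB

__all__ = [
    "gen_boltzmann_samples",
    "BondedTargets",
    "PseudoTrajectory",
    "gen_pseudo_atomistic_traj",
    "LayerSpec",
    "FilmTrajectory",
    "gen_confined_film_traj",
    "gen_friction_dataset",
]


def gen_boltzmann_samples(x0: float, k: float, temperature: float, n: int,
                          seed: int) -> np.ndarray:
    """Draws from the Gaussian implied by the half-included harmonic
    Boltzmann factor exp(-K (x - x0)^2 / k_B T).

    Mean -> x0 and variance -> k_B T / (2 K) as n grows.
    """
    if k <= 0:
        raise ValueError("force constant K must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(KB * temperature / (2.0 * k))
    return rng.normal(x0, sigma, size=n)


def _sample_bond(r0: float, k: float, temperature: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Bond lengths from p(r) ~ r^2 exp(-K (r-r0)^2 / kT), by rejection."""
    sigma = math.sqrt(KB * temperature / (2.0 * k))
    r_max = r0 + 6.0 * sigma
    out = np.empty(0)
    while out.size < n:
        cand = rng.normal(r0, sigma, size=max(n, 256))
        cand = cand[cand > 0]
        accept = rng.random(cand.size) < (cand / r_max) ** 2
        out = np.concatenate([out, cand[accept]])
    return out[:n]


def _sample_angle(theta0: float, k: float, temperature: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Angles from p(theta) ~ sin(theta) exp(-K (theta-theta0)^2 / kT)."""
    sigma = math.sqrt(KB * temperature / (2.0 * k))
    out = np.empty(0)
    while out.size < n:
        cand = rng.normal(theta0, sigma, size=max(n, 256))
        cand = cand[(cand > 0) & (cand < math.pi)]
        accept = rng.random(cand.size) < np.sin(cand)
        out = np.concatenate([out, cand[accept]])
    return out[:n]


@dataclass(frozen=True)
class BondedTargets:
    """Target harmonic parameters per bond/angle type label
    (half-included convention; theta0 in degrees)."""

    bonds: dict  # label -> (r0 nm, K kJ/mol/nm^2)
    angles: dict = field(default_factory=dict)  # label -> (theta0 deg, K kJ/mol/rad^2)
    temperature: float = 300.0


@dataclass
class PseudoTrajectory:
    """Output of :func:`gen_pseudo_atomistic_traj`."""

    trajectory: Trajectory
    skeleton_frames: list[np.ndarray]
    topology: BondedTopology
    bead_types: list[str]


def gen_pseudo_atomistic_traj(scheme: MappingScheme, targets: BondedTargets,
                              n_frames: int, seed: int, n_residues: int = 4,
                              resname: str | None = None,
                              box_size: float = 500.0) -> PseudoTrajectory:
    """Emulate an atomistic trajectory whose mapped bead skeleton follows
    prescribed bond/angle Boltzmann distributions.

    Per frame, a linear bead skeleton is grown in internal coordinates:
    each bond length and bending angle is drawn from its target
    distribution (with the geometric r^2 / sin(theta) factors), the
    azimuth is uniform.  Member atoms are then placed rigidly around each
    bead center with mass-weighted-mean zero offsets, so
    :func:`~cgtribo.mapping.map_trajectory` recovers the skeleton exactly.

    Bond labels are ``"A-B"`` over consecutive bead type names, angle
    labels ``"A-B-C"``; every label of the chain must appear in
    ``targets``.
    """
    if resname is None:
        resname = next(iter(scheme.residues))
    beads = scheme.beads_for(resname)
    bead_types = [b.type_name for b in beads] * n_residues
    topo = BondedTopology.linear_chain(bead_types)
    missing = ({lbl for *_, lbl in topo.bonds} - set(targets.bonds)) | \
              ({lbl for *_, lbl in topo.angles} - set(targets.angles))
    if missing:
        raise ValueError(f"targets missing for bonded types: {sorted(missing)}")

    n_beads = len(bead_types)
    rng_geo = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    rng_chain = np.random.default_rng(np.random.SeedSequence((seed, 1)))

    # pre-draw all internal coordinates, one column per frame
    bond_r = np.empty((n_beads - 1, n_frames))
    for bi, (_, _, lbl) in enumerate(topo.bonds):
        r0, k = targets.bonds[lbl]
        bond_r[bi] = _sample_bond(r0, k, targets.temperature, n_frames, rng_chain)
    ang_t = np.empty((max(n_beads - 2, 0), n_frames))
    for ai, (_, _, _, lbl) in enumerate(topo.angles):
        t0, k = targets.angles[lbl]
        ang_t[ai] = _sample_angle(math.radians(t0), k, targets.temperature,
                                  n_frames, rng_chain)
    phis = rng_chain.uniform(0.0, 2.0 * math.pi, size=(max(n_beads - 2, 0), n_frames))

    # rigid atom offsets per bead (constant across frames, weighted mean zero)
    offsets: list[np.ndarray] = []
    atom_names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    masses: list[float] = []
    for res in range(n_residues):
        for b in beads:
            m = b.atom_masses()
            off = rng_geo.uniform(-0.08, 0.08, size=(len(b.atoms), 3))
            off -= (m @ off) / m.sum()
            offsets.append(off)
            atom_names.extend(b.atoms)
            masses.extend(m)
            resids.extend([res + 1] * len(b.atoms))
            resnames.extend([resname] * len(b.atoms))

    # grow all frames' skeletons at once (the recursion is over beads only)
    center = box_size / 2.0
    T = n_frames
    sk = np.zeros((T, n_beads, 3))
    if n_beads > 1:
        sk[:, 1, 0] = bond_r[0]
    z_hat = np.array([0.0, 0.0, 1.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    for i in range(2, n_beads):
        r = bond_r[i - 1][:, None]
        theta = ang_t[i - 2][:, None]
        phi = phis[i - 2][:, None]
        e1 = sk[:, i - 1] - sk[:, i - 2]
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        ref = np.where(np.abs(e1 @ z_hat)[:, None] > 0.99, y_hat, z_hat)
        e2 = np.cross(e1, ref)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        e3 = np.cross(e1, e2)
        # place so the bending angle at bead i-1 equals theta
        direction = (-np.cos(theta) * e1
                     + np.sin(theta) * (np.cos(phi) * e2 + np.sin(phi) * e3))
        sk[:, i] = sk[:, i - 1] + r * direction
    sk += center - sk.mean(axis=1, keepdims=True)
    skeleton_frames = list(sk)
    bead_of_atom = np.concatenate(
        [np.full(len(beads[bi % len(beads)].atoms), bi)
         for bi in range(n_beads)])
    all_offsets = np.vstack(offsets)
    atoms = sk[:, bead_of_atom, :] + all_offsets[None, :, :]
    atom_frames = list(atoms)

    traj = Trajectory(names=atom_names, resids=np.asarray(resids),
                      resnames=resnames, masses=np.asarray(masses),
                      frames=atom_frames,
                      boxes=[np.full(3, box_size)])
    return PseudoTrajectory(trajectory=traj, skeleton_frames=skeleton_frames,
                            topology=topo, bead_types=bead_types)


# ----------------------------------------------------------------------
# confined-film trajectories
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One species layer of a synthetic confined film.

    ``kind``: ``"slab"`` (uniform in [z_lo, z_hi]) or ``"gauss"``
    (normal around ``center`` with ``sigma``).  ``count`` beads per frame
    of mass ``mass`` (amu) and charge ``charge`` (e).
    """

    species: str
    count: int
    mass: float = 72.0
    charge: float = 0.0
    kind: str = "slab"
    z_lo: float = 0.0
    z_hi: float = 1.0
    center: float = 0.0
    sigma: float = 0.5


@dataclass
class FilmTrajectory:
    """Frames of a synthetic confined film, consumable by the analysis
    profile/hydration functions."""

    species: list[str]
    masses: np.ndarray
    charges: np.ndarray
    frames: list[np.ndarray]
    velocities: list[np.ndarray]
    box: np.ndarray


def gen_confined_film_traj(layers: list[LayerSpec], v_bottom: float = 0.0,
                           v_top: float = 0.0, gap: float = 6.0,
                           lateral: tuple[float, float] = (8.0, 7.0),
                           noise: float = 0.05, n_frames: int = 50,
                           seed: int = 0) -> FilmTrajectory:
    """Confined-film frames with prescribed z-layering and Couette flow.

    Bead z positions follow each layer's density; x-velocities are linear
    in z between ``v_bottom`` and ``v_top`` (nm/ps) plus Gaussian noise of
    width ``noise``.  Layers must lie within the gap; duplicate species
    declarations are rejected.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    if noise < 0:
        raise ValueError("noise width must be >= 0")
    names = [l.species for l in layers]
    if len(set(names)) != len(names):
        raise ValueError(f"overlapping species declarations: {sorted(names)}")
    for l in layers:
        if l.kind == "slab" and not (0 <= l.z_lo < l.z_hi <= gap):
            raise ValueError(f"layer {l.species!r} slab outside the gap")
        if l.kind == "gauss" and not (0 <= l.center <= gap):
            raise ValueError(f"layer {l.species!r} center outside the gap")

    species: list[str] = []
    masses: list[float] = []
    charges: list[float] = []
    for l in layers:
        species += [l.species] * l.count
        masses += [l.mass] * l.count
        charges += [l.charge] * l.count
    box = np.array([lateral[0], lateral[1], gap])
    n = len(species)

    frames, vels = [], []
    for f in range(n_frames):
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        off = 0
        for li, l in enumerate(layers):
            rng = np.random.default_rng(np.random.SeedSequence((seed, li, f)))
            m = l.count
            pos[off:off + m, 0] = rng.uniform(0, lateral[0], m)
            pos[off:off + m, 1] = rng.uniform(0, lateral[1], m)
            if l.kind == "slab":
                pos[off:off + m, 2] = rng.uniform(l.z_lo, l.z_hi, m)
            else:
                z = rng.normal(l.center, l.sigma, m)
                pos[off:off + m, 2] = np.clip(z, 0.0, gap)
            z = pos[off:off + m, 2]
            vel[off:off + m, 0] = (v_bottom + (v_top - v_bottom) * z / gap
                                   + rng.normal(0.0, noise, m) if noise > 0
                                   else v_bottom + (v_top - v_bottom) * z / gap)
            vel[off:off + m, 1] = rng.normal(0.0, noise, m) if noise > 0 else 0.0
            vel[off:off + m, 2] = rng.normal(0.0, noise, m) if noise > 0 else 0.0
            off += m
        frames.append(pos)
        vels.append(vel)
    return FilmTrajectory(species=species, masses=np.asarray(masses),
                          charges=np.asarray(charges), frames=frames,
                          velocities=vels, box=box)


# ----------------------------------------------------------------------
# friction datasets
# ----------------------------------------------------------------------

def gen_friction_dataset(mu: float, tau0: float, alpha: float,
                         sigmas, v_slides, noise: float = 0.0, seed: int = 0,
                         v_ref: float = 1.0) -> FrictionRecord:
    """Friction data with known law tau(sigma, v) on a (sigma, v_s) grid.

    Composition rule: ``tau = (mu * sigma + tau0) * (v_s / v_ref)**alpha``
    times multiplicative lognormal noise ``exp(noise * xi)``.  At
    ``v_s = v_ref`` the noiseless data obey the extended Amontons law
    exactly; at fixed sigma, log tau is linear in log v_s with slope
    alpha.
    """
    if noise < 0:
        raise ValueError("noise standard deviation must be >= 0")
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    v_slides = np.atleast_1d(np.asarray(v_slides, dtype=float))
    if sigmas.size == 0 or v_slides.size == 0:
        raise ValueError("the (sigma, v_s) grid must be non-empty")
    grid_s, grid_v = np.meshgrid(sigmas, v_slides, indexing="ij")
    grid_s, grid_v = grid_s.ravel(), grid_v.ravel()
    rng = np.random.default_rng(seed)
    tau = (mu * grid_s + tau0) * (grid_v / v_ref) ** alpha
    if noise > 0:
        tau = tau * np.exp(noise * rng.standard_normal(tau.shape))
    return FrictionRecord(sigma=grid_s, v_s=grid_v, tau=tau)
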