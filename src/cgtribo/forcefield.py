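"""MARTINI-style functional forms and bonded-parameter bookkeeping.

The model uses 12-6 Lennard-Jones interactions that are force-switched
smoothly to zero between an inner radius ``r_on`` and the cutoff ``r_cut``
(the standard MARTINI 2 shifting scheme), harmonic bonds and angles, and
integer point charges on ionic bead types.

Force constants are stored in the *half-included* convention,

    E_bond(r)      = K (r - r0)^2
    E_angle(theta) = K_theta (theta - theta0)^2

i.e. the factor 1/2 of the textbook harmonic form is already folded into K
(the LAMMPS ``harmonic`` style convention).  The *explicit-half* dialect
E = (K/2) delta^2 is supported through a convention flag; conversion between
the two is an exact factor of two.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HALF_INCLUDED",
    "EXPLICIT_HALF",
    "BeadType",
    "LJPairTable",
    "ShiftSpec",
    "BondedParameterTable",
    "convert_convention",
    "lj_energy",
    "lj_force",
    "lj_shifted_energy",
    "lj_shifted_force",
    "harmonic_bond_energy",
    "harmonic_angle_energy",
    "read_parameter_table",
    "write_parameter_table",
]

HALF_INCLUDED = "half-included"
EXPLICIT_HALF = "explicit-half"
_CONVENTIONS = (HALF_INCLUDED, EXPLICIT_HALF)


class ConventionError(ValueError):
    """Unknown or inconsistent force-constant convention."""


class ParameterTableError(ValueError):
    """Malformed parameter-table text."""


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ConventionError(
            f"unknown force-constant convention {convention!r}; "
            f"expected one of {_CONVENTIONS}"
        )


def convert_convention(k: float, convention_from: str, convention_to: str) -> float:
    """Convert a force constant between the two harmonic-energy dialects.

    The conversion is exact (a factor of two) and an involution.
    """
    _check_convention(convention_from)
    _check_convention(convention_to)
    if convention_from == convention_to:
        return k
    if convention_from == EXPLICIT_HALF:  # (K/2) d^2 -> K' d^2
        return k / 2.0
    return k * 2.0


def _as_half_included(k: float, convention: str) -> float:
    return convert_convention(k, convention, HALF_INCLUDED)


@dataclass(frozen=True)
class BeadType:
    """A coarse-grained interaction site type.

    Parameters
    ----------
    name : short label, e.g. ``"C1"``, ``"Qa"``, ``"Q0"``, ``"P1"``.
    mass : bead mass in amu.
    charge : permanent charge in elementary charges (integer for ionic
        beads; polarizable-water satellites carry fractional charges).
    lj_class : label used to look up the (epsilon, sigma) pair in an
        :class:`LJPairTable`; defaults to ``name``.
    """

    name: str
    mass: float
    charge: float = 0.0
    lj_class: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"bead type {self.name!r}: mass must be > 0")
        if not self.lj_class:
            object.__setattr__(self, "lj_class", self.name)


class LJPairTable:
    """Symmetric mapping (lj_class, lj_class) -> (epsilon kJ/mol, sigma nm)."""

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float]] | None = None):
        self._table: dict[tuple[str, str], tuple[float, float]] = {}
        if entries:
            for (a, b), (eps, sig) in entries.items():
                self.set(a, b, eps, sig)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, epsilon: float, sigma: float) -> None:
        if epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 for pair ({a}, {b})")
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0 for pair ({a}, {b})")
        self._table[self._key(a, b)] = (float(epsilon), float(sigma))

    def get(self, a: str, b: str) -> tuple[float, float]:
        try:
            return self._table[self._key(a, b)]
        except KeyError:
            raise KeyError(f"no LJ parameters for class pair ({a}, {b})") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._table

    def classes(self) -> list[str]:
        out: set[str] = set()
        for a, b in self._table:
            out.update((a, b))
        return sorted(out)

    def matrices(self, classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Dense (epsilon, sigma) matrices over an ordered class list."""
        n = len(classes)
        eps = np.zeros((n, n))
        sig = np.full((n, n), 0.47)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                if (a, b) in self:
                    e, s = self.get(a, b)
                    eps[i, j] = e
                    sig[i, j] = s
        return eps, sig


@dataclass(frozen=True)
class ShiftSpec:
    """Radii of the LJ force-switching window, in nm.

    The force is ramped smoothly to zero between ``r_on`` and ``r_cut``
    with the cubic/quartic polynomial switch; energy follows by
    integration so both are continuous and exactly zero beyond the cutoff.
    """

    r_on: float = 0.9
    r_cut: float = 1.2

    def __post_init__(self):
        if not (0 < self.r_on < self.r_cut):
            raise ValueError(
                f"require 0 < r_on < r_cut, got ({self.r_on}, {self.r_cut})"
            )


def _switch_coeffs(p: int, r_on: float, r_cut: float) -> tuple[float, float, float]:
    """Polynomial coefficients of the force-switched 1/r^p term.

    For r_on <= r < r_cut the pair force on the r^-p potential term is
    F(r) = p r^-(p+1) + A (r - r_on)^2 + B (r - r_on)^3, chosen such that
    F(r_cut) = F'(r_cut) = 0; C shifts the integrated energy to zero at
    the cutoff.
    """
    d = r_cut - r_on
    A = -p * ((p + 4) * r_cut - (p + 1) * r_on) / (r_cut ** (p + 2) * d**2)
    B = p * ((p + 3) * r_cut - (p + 1) * r_on) / (r_cut ** (p + 2) * d**3)
    C = 1.0 / r_cut**p - A / 3.0 * d**3 - B / 4.0 * d**4
    return A, B, C


def _switched_term(r, p: int, shift: ShiftSpec):
    """Energy and force of the switched r^-p term (vectorized over r)."""
    r = np.asarray(r, dtype=float)
    A, B, C = _switch_coeffs(p, shift.r_on, shift.r_cut)
    dr = r - shift.r_on
    inside = r < shift.r_on
    window = (r >= shift.r_on) & (r < shift.r_cut)
    with np.errstate(divide="ignore", over="ignore"):
        inv_p = np.where(r > 0, r, np.nan) ** (-p)
        inv_p1 = np.where(r > 0, r, np.nan) ** (-(p + 1))
    e = np.zeros_like(r)
    f = np.zeros_like(r)
    e = np.where(inside, inv_p - C, e)
    f = np.where(inside, p * inv_p1, f)
    e = np.where(window, inv_p - A / 3.0 * dr**3 - B / 4.0 * dr**4 - C, e)
    f = np.where(window, p * inv_p1 + A * dr**2 + B * dr**3, f)
    return e, f


def lj_energy(r, epsilon: float, sigma: float):
    """Plain (unshifted) 12-6 Lennard-Jones energy, kJ/mol."""
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (sr6**2 - sr6)


def lj_force(r, epsilon: float, sigma: float):
    """Plain 12-6 LJ pair force magnitude, -dE/dr, kJ/mol/nm."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    return 24.0 * epsilon * (2.0 * sr6**2 - sr6) / r


def lj_shifted_energy(r, epsilon: float, sigma: float, shift: ShiftSpec | None = None):
    """Force-switched 12-6 LJ energy.

    With ``shift=None`` the plain 12-6 form is returned.  Energy and force
    are continuous everywhere and exactly zero for ``r >= shift.r_cut``.

    Raises
    ------
    ValueError
        If any separation is <= 0.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("separation r must be > 0")
    if shift is None:
        out = lj_energy(r_arr, epsilon, sigma)
    else:
        e12, _ = _switched_term(r_arr, 12, shift)
        e6, _ = _switched_term(r_arr, 6, shift)
        out = 4.0 * epsilon * (sigma**12 * e12 - sigma**6 * e6)
    return float(out) if np.isscalar(r) else out


def lj_shifted_force(r, epsilon: float, sigma: float, shift: ShiftSpec | None = None):
    """Force magnitude -dE/dr matching :func:`lj_shifted_energy`."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("separation r must be > 0")
    if shift is None:
        out = lj_force(r_arr, epsilon, sigma)
    else:
        _, f12 = _switched_term(r_arr, 12, shift)
        _, f6 = _switched_term(r_arr, 6, shift)
        out = 4.0 * epsilon * (sigma**12 * f12 - sigma**6 * f6)
    return float(out) if np.isscalar(r) else out


def harmonic_bond_energy(r, r0: float, k: float, convention: str = HALF_INCLUDED):
    """Harmonic bond energy, kJ/mol; K in kJ/mol/nm^2 under ``convention``."""
    if k < 0:
        raise ValueError("force constant K must be >= 0")
    k_half = _as_half_included(k, convention)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be > 0")
    e = k_half * (r - r0) ** 2
    return float(e) if e.ndim == 0 else e


def harmonic_angle_energy(theta, theta0: float, k_theta: float,
                          convention: str = HALF_INCLUDED):
    """Harmonic angle energy, kJ/mol; angles in rad, K in kJ/mol/rad^2."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > math.pi + 1e-12)):
        raise ValueError("angle must lie in [0, pi]")
    k_half = _as_half_included(k_theta, convention)
    e = k_half * (theta - theta0) ** 2
    return float(e) if e.ndim == 0 else e


@dataclass
class BondedParameterTable:
    """Harmonic bond/angle parameters keyed by bead-type tuples.

    Bonds map ``(type_i, type_j) -> (r0 nm, K kJ/mol/nm^2)``; angles map
    ``(type_i, type_j, type_k) -> (theta0 deg, K_theta kJ/mol/rad^2)``.
    Lookups are symmetric under tuple reversal.  ``convention`` states
    which harmonic-energy dialect the stored force constants use.
    """

    bonds: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    convention: str = HALF_INCLUDED

    def __post_init__(self):
        _check_convention(self.convention)
        for key, (r0, k) in self.bonds.items():
            self._validate_bond(key, r0, k)
        for key, (t0, k) in self.angles.items():
            self._validate_angle(key, t0, k)

    @staticmethod
    def _validate_bond(key, r0, k):
        if r0 <= 0:
            raise ValueError(f"bond {key}: r0 must be > 0")
        if k < 0:
            raise ValueError(f"bond {key}: K must be >= 0")

    @staticmethod
    def _validate_angle(key, theta0, k):
        if not (0 <= theta0 <= 180):
            raise ValueError(f"angle {key}: theta0 must lie in [0, 180] deg")
        if k < 0:
            raise ValueError(f"angle {key}: K must be >= 0")

    def add_bond(self, type_i: str, type_j: str, r0: float, k: float) -> None:
        self._validate_bond((type_i, type_j), r0, k)
        self.bonds[(type_i, type_j)] = (float(r0), float(k))

    def add_angle(self, ti: str, tj: str, tk: str, theta0: float, k: float) -> None:
        self._validate_angle((ti, tj, tk), theta0, k)
        self.angles[(ti, tj, tk)] = (float(theta0), float(k))

    def bond(self, type_i: str, type_j: str) -> tuple[float, float]:
        for key in ((type_i, type_j), (type_j, type_i)):
            if key in self.bonds:
                return self.bonds[key]
        raise KeyError(f"no bond parameters for ({type_i}, {type_j})")

    def angle(self, ti: str, tj: str, tk: str) -> tuple[float, float]:
        for key in ((ti, tj, tk), (tk, tj, ti)):
            if key in self.angles:
                return self.angles[key]
        raise KeyError(f"no angle parameters for ({ti}, {tj}, {tk})")

    def to_convention(self, convention: str) -> "BondedParameterTable":
        """Return a copy with all force constants converted."""
        _check_convention(convention)
        conv = lambda k: convert_convention(k, self.convention, convention)
        return BondedParameterTable(
            bonds={k: (r0, conv(kk)) for k, (r0, kk) in self.bonds.items()},
            angles={k: (t0, conv(kk)) for k, (t0, kk) in self.angles.items()},
            convention=convention,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": self.convention,
                "bonds": [
                    {"types": list(k), "r0_nm": v[0], "k_kj_mol_nm2": v[1]}
                    for k, v in sorted(self.bonds.items())
                ],
                "angles": [
                    {"types": list(k), "theta0_deg": v[0], "k_kj_mol_rad2": v[1]}
                    for k, v in sorted(self.angles.items())
                ],
            },
            indent=2,
        )


def write_parameter_table(table: BondedParameterTable) -> str:
    """Serialize a parameter table to the ITP-like text dialect.

    Grammar: ``;`` starts a comment; ``[ bonds ]`` / ``[ angles ]`` open
    sections; bond lines are ``type_i type_j r0_nm K``, angle lines
    ``type_i type_j type_k theta0_deg K``.  The force-constant convention
    is recorded in the ``; convention:`` header comment.
    """
    lines = [
        "; cgtribo bonded parameter table",
        f"; convention: {table.convention}",
        "",
        "[ bonds ]",
        "; type_i  type_j  r0(nm)  K(kJ/mol/nm^2)",
    ]
    for (a, b), (r0, k) in table.bonds.items():
        lines.append(f"{a:<8s}{b:<8s}{float(r0)!r:>14s}  {float(k)!r}")
    lines += ["", "[ angles ]", "; type_i  type_j  type_k  theta0(deg)  K(kJ/mol/rad^2)"]
    for (a, b, c), (t0, k) in table.angles.items():
        lines.append(f"{a:<8s}{b:<8s}{c:<8s}{float(t0)!r:>12s}  {float(k)!r}")
    return "\n".join(lines) + "\n"


def read_parameter_table(text: str) -> BondedParameterTable:
    """Parse the ITP-like dialect written by :func:`write_parameter_table`.

    Raises
    ------
    ParameterTableError
        On duplicate entries (naming the line), unknown section headers,
        or conflicting convention declarations.
    """
    table = BondedParameterTable()
    convention: str | None = None
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        comment = ""
        line = raw
        if ";" in line:
            line, comment = line.split(";", 1)
        if "convention:" in comment:
            declared = comment.split("convention:", 1)[1].strip()
            _check_convention(declared)
            if convention is not None and declared != convention:
                raise ParameterTableError(
                    f"line {lineno}: conflicting convention declarations "
                    f"({convention!r} vs {declared!r})"
                )
            convention = declared
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            if section not in ("bonds", "angles", "atomtypes"):
                raise ParameterTableError(f"line {lineno}: unknown section {section!r}")
            continue
        fields = line.split()
        if section == "bonds":
            if len(fields) != 4:
                raise ParameterTableError(f"line {lineno}: expected 4 fields in [ bonds ]")
            a, b, r0, k = fields[0], fields[1], float(fields[2]), float(fields[3])
            if (a, b) in table.bonds or (b, a) in table.bonds:
                raise ParameterTableError(
                    f"line {lineno}: duplicate bond entry for ({a}, {b})"
                )
            table.add_bond(a, b, r0, k)
        elif section == "angles":
            if len(fields) != 5:
                raise ParameterTableError(f"line {lineno}: expected 5 fields in [ angles ]")
            a, b, c = fields[:3]
            t0, k = float(fields[3]), float(fields[4])
            if (a, b, c) in table.angles or (c, b, a) in table.angles:
                raise ParameterTableError(
                    f"line {lineno}: duplicate angle entry for ({a}, {b}, {c})"
                )
            table.add_angle(a, b, c, t0, k)
        elif section is None:
            raise ParameterTableError(f"line {lineno}: data outside any section")
    table.convention = convention or HALF_INCLUDED
    return table
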