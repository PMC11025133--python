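"""Measurement layer: through-film profiles, film thickness, hydration,
coverages and charge ratios, shear stress, friction-law fits and Rg-Mw
scaling.

Profiles are time-averaged binned quantities along the surface normal
(z by default).  Film thickness follows the cumulative-mass definition:
the distance between the 1% and 99% quantiles of the time-averaged
cumulative mass distribution (i.e. the extent containing 98% of the
species' mass), with linear interpolation inside bins.

Friction laws: the shear stress is fitted against sliding velocity with a
power law  tau ~ v_s^alpha  (least squares in log-log space) and against
normal stress with the extended Amontons law  tau = mu * sigma + tau0,
where mu is the friction coefficient and tau0 the Derjaguin offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .units import AMU_NM3_TO_G_CM3

__all__ = [
    "Profile",
    "CoverageReport",
    "FrictionRecord",
    "profile",
    "film_thickness",
    "hydration_fraction",
    "coverages",
    "charge_ratio",
    "shear_stress",
    "fit_powerlaw",
    "fit_amontons",
    "rg_scaling",
    "interdigitation_overlap",
    "block_average",
]

DEFAULT_BIN_WIDTH = 0.1  # nm


@dataclass
class Profile:
    """A binned quantity along one axis.

    ``values`` per bin: mass density (amu/nm^3), charge density (e/nm^3),
    number density (nm^-3) or mean velocity (nm/ps; empty bins are NaN,
    not zero).  ``frames`` counts the frames averaged.
    """

    edges: np.ndarray
    values: np.ndarray
    quantity: str
    selection: str = ""
    axis: int = 2
    frames: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def mass_density_g_cm3(self) -> np.ndarray:
        if self.quantity != "mass":
            raise ValueError("not a mass profile")
        return self.values * AMU_NM3_TO_G_CM3

    def integral(self) -> float:
        """Integral of the profile over the axis (per unit area)."""
        vals = np.nan_to_num(self.values)
        return float(np.sum(vals * self.widths))


@dataclass
class CoverageReport:
    """Areal densities and charge ratios of the confined contact.

    ``rho`` maps species name to areal density (units depend on the
    species convention: water is counted in beads/nm^2, surfactant and
    polymer in molecules/nm^2).  ``r_sds`` is the ratio of surfactant
    anionic charges to polymer cationic charges; ``r_surf`` the magnitude
    of the surface-anion to polymer-cation ratio.
    """

    area: float
    rho: dict[str, float] = field(default_factory=dict)
    r_sds: float = 0.0
    r_surf: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": k, "areal_density_per_nm2": v} for k, v in self.rho.items()]
        rows.append({"species": "R_SDS", "areal_density_per_nm2": self.r_sds})
        rows.append({"species": "|R_surf|", "areal_density_per_nm2": self.r_surf})
        return pd.DataFrame(rows)


class FrictionRecord:
    """(sigma, v_s, tau) data points with their friction-law fit results."""

    def __init__(self, sigma, v_s, tau, tau_se=None):
        self.data = pd.DataFrame({
            "sigma": np.asarray(sigma, float),
            "v_s": np.asarray(v_s, float),
            "tau": np.asarray(tau, float),
            "tau_se": (np.zeros(len(np.atleast_1d(tau)))
                       if tau_se is None else np.asarray(tau_se, float)),
        })
        if np.any(self.data["tau_se"] < 0):
            raise ValueError("tau standard errors must be >= 0")
        self.mu: float | None = None
        self.tau0: float | None = None
        self.alpha: float | None = None
        self.prefactor: float | None = None

    def __len__(self) -> int:
        return len(self.data)


# ----------------------------------------------------------------------
# profiles
# ----------------------------------------------------------------------

def _resolve_selection(frames_obj, selection):
    if isinstance(selection, str) and selection:
        mask = np.array([s == selection for s in frames_obj.species], dtype=bool)
        label = selection
    elif selection is None or (isinstance(selection, str) and not selection):
        mask = np.ones(len(frames_obj.masses), dtype=bool)
        label = "all"
    else:
        mask = np.asarray(selection, dtype=bool)
        label = "mask"
    if not mask.any():
        raise ValueError(f"empty selection {label!r}")
    return mask, label


def profile(frames_obj, selection=None, quantity: str = "mass",
            bins: float | np.ndarray = DEFAULT_BIN_WIDTH, axis: int = 2,
            extent: tuple[float, float] | None = None) -> Profile:
    """Time-averaged binned profile along an axis.

    ``frames_obj`` needs ``frames`` (list of (n,3) positions), ``box``,
    ``masses``, ``charges``, ``species`` and, for velocity profiles,
    ``velocities``.  ``bins`` is a bin width (nm) or an explicit edge
    array.  Velocity bins that never contain a bead are NaN.
    """
    mask, label = _resolve_selection(frames_obj, selection)
    box = np.asarray(frames_obj.box, dtype=float)
    lo, hi = (0.0, box[axis]) if extent is None else extent
    if isinstance(bins, (int, float)):
        if bins <= 0:
            raise ValueError("bin width must be > 0")
        n_bins = max(1, int(round((hi - lo) / bins)))
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    lateral = float(np.prod(np.delete(box, axis)))
    bin_vol = np.diff(edges) * lateral

    acc = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    n_frames = len(frames_obj.frames)
    for fi in range(n_frames):
        x = frames_obj.frames[fi][mask, axis]
        if quantity == "mass":
            w = frames_obj.masses[mask]
        elif quantity == "charge":
            w = frames_obj.charges[mask]
        elif quantity == "number":
            w = np.ones(mask.sum())
        elif quantity == "velocity":
            w = frames_obj.velocities[fi][mask, 0]
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        h, _ = np.histogram(x, bins=edges, weights=w)
        acc += h
        if quantity == "velocity":
            c, _ = np.histogram(x, bins=edges)
            counts += c
    if quantity == "velocity":
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    else:
        values = acc / (n_frames * bin_vol)
    return Profile(edges=edges, values=values, quantity=quantity,
                   selection=label, axis=axis, frames=n_frames)


def film_thickness(prof: Profile, lo: float = 0.01, hi: float = 0.99) -> float:
    """Distance between the ``lo`` and ``hi`` quantiles of the cumulative
    density distribution (default: the extent containing 98% of the mass).

    Linear interpolation is used inside bins.  Raises on zero total mass.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    vals = np.nan_to_num(prof.values)
    if np.any(vals < 0):
        raise ValueError("film thickness requires a non-negative profile")
    w = vals * prof.widths
    total = w.sum()
    if total <= 0:
        raise ValueError("undefined film thickness: profile has zero total mass")
    cum = np.concatenate([[0.0], np.cumsum(w)]) / total
    z_lo = float(np.interp(lo, cum, prof.edges))
    z_hi = float(np.interp(hi, cum, prof.edges))
    return z_hi - z_lo


def film_extent(prof: Profile, lo: float = 0.01, hi: float = 0.99
                ) -> tuple[float, float]:
    """The (z_lo, z_hi) positions of the cumulative-density quantiles."""
    vals = np.nan_to_num(prof.values)
    w = vals * prof.widths
    total = w.sum()
    if total <= 0:
        raise ValueError("undefined film extent: profile has zero total mass")
    cum = np.concatenate([[0.0], np.cumsum(w)]) / total
    return float(np.interp(lo, cum, prof.edges)), float(np.interp(hi, cum, prof.edges))


def hydration_fraction(frames_obj, film_selection, water_selection,
                       bins: float = DEFAULT_BIN_WIDTH) -> float:
    """Mass fraction of water inside the film's z-extent, time-averaged.

    The film extent is the 1-99% cumulative-mass window of the film
    species; the result is (water mass in that window) / (total mass in
    that window), pooled over frames.
    """
    film_prof = profile(frames_obj, film_selection, "mass", bins)
    z_lo, z_hi = film_extent(film_prof)
    wmask, _ = _resolve_selection(frames_obj, water_selection)
    water_mass = 0.0
    total_mass = 0.0
    for fi in range(len(frames_obj.frames)):
        z = frames_obj.frames[fi][:, 2]
        inside = (z >= z_lo) & (z <= z_hi)
        total_mass += float(frames_obj.masses[inside].sum())
        water_mass += float(frames_obj.masses[inside & wmask].sum())
    if total_mass == 0:
        raise ValueError("empty film: no mass inside the film extent")
    return water_mass / total_mass


# ----------------------------------------------------------------------
# coverages and charge ratios
# ----------------------------------------------------------------------

def charge_ratio(rho_sds: float, rho_cgg: float, cations_per_chain: int) -> float:
    """SDS/polymer charge ratio from areal densities, as tabulated:
    (anionic SDS charges per area) / (cationic polymer charges per area)."""
    if rho_cgg <= 0 or cations_per_chain <= 0:
        raise ValueError("undefined charge ratio: no polymer cationic charge")
    return rho_sds / (rho_cgg * cations_per_chain)


def coverages(state, lateral_area: float, species_map: dict[str, str] | None = None,
              z_window: tuple[float, float] | None = None) -> CoverageReport:
    """Areal densities of species inside the contact plus charge ratios.

    ``species_map`` maps report names to state species labels with a
    counting convention: ``{"water": ("PW", "bead"), "SDS": ("SDS", "mol"),
    "CGG": ("CGG", "mol")}``-style entries (bare label strings default to
    molecule counting).  Beads are "inside" by center position within
    ``z_window`` (default: everything).

    Charge ratios: R_SDS = SDS anionic charges / CGG cationic charges;
    R_surf uses the anionic charges of graft/surface species, reported as
    a magnitude.
    """
    if lateral_area <= 0:
        raise ValueError("lateral area must be > 0")
    species_map = species_map or {"water": ("PW", "bead"), "SDS": ("SDS", "mol"),
                                  "CGG": ("CGG", "mol")}
    spec_arr = np.asarray(state.species)
    z = state.pos[:, 2]
    inside = np.ones(len(z), dtype=bool)
    if z_window is not None:
        inside = (z >= z_window[0]) & (z <= z_window[1])

    rho: dict[str, float] = {}
    for name, spec in species_map.items():
        label, mode = spec if isinstance(spec, tuple) else (spec, "mol")
        mask = (spec_arr == label) & inside
        if mode == "bead":
            count = int(mask.sum())
        else:
            count = len(np.unique(state.mol[mask])) if mask.any() else 0
        rho[name] = count / lateral_area

    def _species_charge(label, sign):
        mask = (spec_arr == label) & inside
        q = state.charge[mask]
        return float(np.abs(q[np.sign(q) == sign]).sum())

    cgg_label = species_map.get("CGG", ("CGG", "mol"))
    cgg_label = cgg_label[0] if isinstance(cgg_label, tuple) else cgg_label
    sds_label = species_map.get("SDS", ("SDS", "mol"))
    sds_label = sds_label[0] if isinstance(sds_label, tuple) else sds_label
    cat = _species_charge(cgg_label, +1)
    report = CoverageReport(area=lateral_area, rho=rho)
    sds_an = _species_charge(sds_label, -1)
    surf_an = _species_charge("graft", -1)
    if sds_an or surf_an:
        if cat == 0:
            raise ValueError("charge ratio undefined: polymer carries no "
                             "cationic charge in the contact")
        report.r_sds = sds_an / cat
        report.r_surf = abs(surf_an / cat)
    return report


# ----------------------------------------------------------------------
# shear stress and friction-law fits
# ----------------------------------------------------------------------

def block_average(series: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error (``n_blocks`` equal blocks)."""
    series = np.asarray(series, dtype=float)
    if len(series) < n_blocks:
        raise ValueError(f"need at least {n_blocks} samples for {n_blocks} blocks")
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(series.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def shear_stress(log, lateral_area: float, start_frac: float = 0.0,
                 n_blocks: int = 5) -> tuple[float, float]:
    """Time-averaged lateral force on the driven anchor / area, in MPa.

    ``log`` is a confined-run :class:`~cgtribo.engine.TrajectoryLog`;
    the steady-state window starts at ``start_frac`` of the samples.  The
    standard error comes from block averaging over ``n_blocks`` blocks.
    """
    from .units import MPA

    fx = np.asarray(log.scalars["f_upper_x"], dtype=float)
    fx = fx[int(len(fx) * start_frac):]
    tau_series = -fx / lateral_area / MPA  # reaction force on the film
    mean, se = block_average(tau_series, n_blocks)
    return mean, se


def fit_powerlaw(record: FrictionRecord, v_min: float = 0.0) -> tuple[float, float]:
    """Power-law exponent of shear stress vs sliding velocity.

    Least-squares line in (ln v_s, ln tau) over points with v_s >= v_min;
    returns (alpha, prefactor).  Requires >= 3 points and positive tau.
    """
    d = record.data[record.data["v_s"] >= v_min]
    if len(d) < 3:
        raise ValueError("need at least 3 points with v_s >= v_min")
    if np.any(d["tau"] <= 0):
        raise ValueError("power-law fit requires positive shear stresses")
    res = stats.linregress(np.log(d["v_s"]), np.log(d["tau"]))
    record.alpha = float(res.slope)
    record.prefactor = float(np.exp(res.intercept))
    return record.alpha, record.prefactor


def fit_amontons(record: FrictionRecord) -> tuple[float, float]:
    """Extended Amontons fit tau = mu * sigma + tau0 (ordinary least squares).

    Returns (mu, tau0); tau0 (the Derjaguin offset) is unconstrained in
    sign.  Requires >= 2 distinct normal stresses.
    """
    d = record.data
    if len(np.unique(d["sigma"])) < 2:
        raise ValueError("need at least 2 distinct normal stresses")
    res = stats.linregress(d["sigma"], d["tau"])
    record.mu = float(res.slope)
    record.tau0 = float(res.intercept)
    return record.mu, record.tau0


def rg_scaling(rg_by_mw) -> float:
    """Power-law exponent of <Rg> vs molecular weight.

    ``rg_by_mw``: iterable of (M_w, Rg) pairs (or a 2-column array).
    Entries with identical M_w are averaged before the log-log fit.
    Requires >= 3 distinct chain sizes and positive entries.
    """
    arr = np.asarray(list(rg_by_mw), dtype=float).reshape(-1, 2)
    if np.any(arr <= 0):
        raise ValueError("M_w and Rg entries must be positive")
    df = pd.DataFrame(arr, columns=["mw", "rg"]).groupby("mw", as_index=False).mean()
    if len(df) < 3:
        raise ValueError("need at least 3 distinct chain sizes")
    res = stats.linregress(np.log(df["mw"]), np.log(df["rg"]))
    return float(res.slope)


def interdigitation_overlap(profile_lower: Profile, profile_upper: Profile) -> float:
    """Overlap integral of two density profiles, per unit area (nm^-2).

    ``integral of min(rho_lower, rho_upper) dz`` on their common bin grid;
    zero iff the supports are disjoint.
    """
    if (profile_lower.edges.shape != profile_upper.edges.shape
            or not np.allclose(profile_lower.edges, profile_upper.edges)):
        raise ValueError("profiles are on different bin grids")
    a = np.nan_to_num(profile_lower.values)
    b = np.nan_to_num(profile_upper.values)
    return float(np.sum(np.minimum(a, b) * profile_lower.widths))
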