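"""Internal unit system and physical constants.

Everything inside the package uses GROMACS-style units: length nm, time ps,
mass amu, energy kJ/mol, charge in elementary charges, temperature K.
File writers convert to LAMMPS "real" units (angstrom, fs, kcal/mol) on
export; the conversion factors live here and nowhere else.
"""

# Boltzmann constant, kJ mol^-1 K^-1 (CODATA via k_B * N_A)
KB = 0.00831446261815324

# Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_COULOMB = 138.935458

# 1 MPa expressed in kJ mol^-1 nm^-3  (1e6 Pa * 1e-27 m^3 * N_A / 1000)
MPA = 0.602214076

# 1 m/s in nm/ps
M_PER_S = 1.0e-3

# 1 amu/nm^3 in g/cm^3
AMU_NM3_TO_G_CM3 = 1.66053906660e-3

# Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

# kJ/mol -> kcal/mol
KJ_TO_KCAL = 1.0 / 4.184

# nm -> angstrom
NM_TO_A = 10.0

# nm/ps -> angstrom/fs
NMPS_TO_AFS = 0.01


def molarity(count: int, volume_nm3: float) -> float:
    """Concentration in mol/L of ``count`` particles in ``volume_nm3`` nm^3."""
    litres = volume_nm3 * 1.0e-24
    return count / (N_AVOGADRO * litres)
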