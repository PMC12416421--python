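"""Physical constants and unit conversions.

Internal convention: atomic units (Hartree) inside the mean-field solver,
eV / fs / cm at every module interface.
"""

# Energy
HARTREE_EV = 27.211386245988  # 1 Ha in eV
RYDBERG_EV = 13.605693122994  # 1 Ry in eV

# Length
BOHR_CM = 0.529177210903e-8  # Bohr radius in cm
BOHR_A = 0.529177210903  # Bohr radius in Angstrom

# Time
ATOMIC_TIME_FS = 2.4188843265857e-2 / 1000.0  # 1 a.u. of time in fs (2.4189e-17 s)
AU_TIME_S = 2.4188843265857e-17

# Electron
ELECTRON_MASS_EV = 510998.95  # m_e c^2 in eV
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5 * 1e15 / 1e15  # placeholder, see below
C_CM_PER_FS = 2.99792458e-5  # speed of light in cm/fs

# hbar
HBAR_EV_FS = 0.6582119569  # hbar in eV fs

# Avogadro
N_AVOGADRO = 6.02214076e23
AMU_G = 1.66053906660e-24  # atomic mass unit in grams

# Fine structure
ALPHA_FS = 7.2973525693e-3

# Classical cross-section scale
A0_SQ_CM2 = BOHR_CM**2  # a0^2 in cm^2 = 2.8003e-17


def electron_speed_cm_fs(energy_ev: float):
    """Non-relativistic electron speed v = sqrt(2 eps / m) in cm/fs."""
    import numpy as np

    e = np.asarray(energy_ev, dtype=float)
    return C_CM_PER_FS * np.sqrt(2.0 * np.clip(e, 0.0, None) / ELECTRON_MASS_EV)


# Mean atomic masses (amu) for elements used in biomolecular targets.
ATOMIC_MASS_AMU = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948,
    19: 39.098, 20: 40.078, 21: 44.956, 22: 47.867, 23: 50.942, 24: 51.996,
    25: 54.938, 26: 55.845, 27: 58.933, 28: 58.693, 29: 63.546, 30: 65.38,
    31: 69.723, 32: 72.630, 33: 74.922, 34: 78.971, 35: 79.904, 36: 83.798,
    37: 85.468, 38: 87.62, 39: 88.906, 40: 91.224, 41: 92.906, 42: 95.95,
    44: 101.07, 45: 102.91, 46: 106.42, 47: 107.87, 48: 112.41, 49: 114.82,
    50: 118.71, 51: 121.76, 52: 127.60, 53: 126.90, 54: 131.29, 55: 132.91,
    56: 137.33, 57: 138.91, 58: 140.12, 59: 140.91, 60: 144.24, 62: 150.36,
    63: 151.96, 64: 157.25, 65: 158.93, 66: 162.50, 67: 164.93, 68: 167.26,
    69: 168.93, 70: 173.05, 71: 174.97, 72: 178.49, 73: 180.95, 74: 183.84,
    75: 186.21, 76: 190.23, 77: 192.22, 78: 195.08, 79: 196.97, 80: 200.59,
    81: 204.38, 82: 207.2, 83: 208.98, 90: 232.04, 92: 238.03,
}

ELEMENT_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 21: "Sc", 22: "Ti",
    23: "V", 24: "Cr", 25: "Mn", 26: "Fe", 27: "Co", 28: "Ni", 29: "Cu",
    30: "Zn", 31: "Ga", 32: "Ge", 33: "As", 34: "Se", 35: "Br", 36: "Kr",
    37: "Rb", 38: "Sr", 39: "Y", 40: "Zr", 41: "Nb", 42: "Mo", 43: "Tc",
    44: "Ru", 45: "Rh", 46: "Pd", 47: "Ag", 48: "Cd", 49: "In", 50: "Sn",
    51: "Sb", 52: "Te", 53: "I", 54: "Xe", 55: "Cs", 56: "Ba", 57: "La",
    58: "Ce", 59: "Pr", 60: "Nd", 61: "Pm", 62: "Sm", 63: "Eu", 64: "Gd",
    65: "Tb", 66: "Dy", 67: "Ho", 68: "Er", 69: "Tm", 70: "Yb", 71: "Lu",
    72: "Hf", 73: "Ta", 74: "W", 75: "Re", 76: "Os", 77: "Ir", 78: "Pt",
    79: "Au", 80: "Hg", 81: "Tl", 82: "Pb", 83: "Bi", 84: "Po", 85: "At",
    86: "Rn", 87: "Fr", 88: "Ra", 89: "Ac", 90: "Th", 91: "Pa", 92: "U",
}

SYMBOL_TO_Z = {v: k for k, v in ELEMENT_SYMBOLS.items()}
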