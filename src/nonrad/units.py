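"""Unit conversions.

All dynamics run in Hartree atomic units (hbar = m_e = e = a0 = 1);
fs / angstrom / eV / kcal/mol appear only at interfaces.
"""

HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

AU_TIME_TO_FS = 0.02418884326586
FS_TO_AU_TIME = 1.0 / AU_TIME_TO_FS

KCALMOL_TO_HARTREE = 1.0 / 627.509474063
AMU_TO_AU_MASS = 1822.888486209

# Boltzmann constant
KB_HARTREE_PER_K = 3.166811563e-6
KB_EV_PER_K = 8.617333262e-5


def force_constant_to_au(k_kcalmol_ang2: float) -> float:
    """kcal/mol/A^2 -> hartree/bohr^2."""
    return k_kcalmol_ang2 * KCALMOL_TO_HARTREE * BOHR_TO_ANGSTROM**2
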