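"""Unit conventions and physical constants.

Internal units throughout the package are kcal/mol (energy), Å (length),
fs (time), K (temperature) and amu (mass).  Electron-volt quantities appear
only at the file-format boundary (extended-XYZ files that declare eV) and in
validation reports, which use meV per atom / meV per Å as is conventional for
machine-learning potential benchmarks.

Every conversion constant used anywhere in the package is defined here, once.
"""

# energy
EV_TO_KCAL = 23.0605          # 1 eV in kcal/mol
KCAL_TO_MEV = 1000.0 / EV_TO_KCAL   # = 43.3641 meV per kcal/mol

# Boltzmann constant, kcal/mol/K
KB = 0.0019872041

# Coulomb constant e^2/(4 pi eps0) in kcal/mol * Å / e^2
COULOMB = 332.0637

# Avogadro constant, 1/mol (density arithmetic in fixtures)
N_AVOGADRO = 6.02214076e23

# velocity^2 * mass -> energy: 1 amu * (Å/fs)^2 in kcal/mol.
# amu * N_A = 1 g to within 4e-10 relative, so the factor is 1e7 J/mol / 4184 J/kcal.
KE_CONV = 1.0e7 / 4184.0  # = 2390.0573... kcal/mol per amu Å^2/fs^2

# atomic masses (amu); "Me" is a united-atom methyl group
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Mg": 24.305,
    "Pd": 106.42,
    "Me": 15.035,
}

# molar masses used for solvent density arithmetic (g/mol)
MOLAR_MASS_WATER_LIKE = 18.015
MOLAR_MASS_NITRILE_LIKE = 41.05


def mass_of(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {symbol!r}") from None
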