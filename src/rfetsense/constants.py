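"""Physical constants (CODATA 2018) and unit helpers.

SI internally; user-facing quantities are nm, V, eV, molar and kcal/mol.
"""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
EPSILON_0 = 8.8541878128e-12  # F/m
AVOGADRO = 6.02214076e23  # 1/mol
PLANCK = 6.62607015e-34  # J s
HBAR = 1.054571817e-34  # J s
ELECTRON_MASS = 9.1093837015e-31  # kg

#: Gas constant in kcal/(mol K) — the convention of binding free energies.
R_KCAL_PER_MOL_K = 1.9872e-3

NM = 1e-9  # m per nm
ANGSTROM = 1e-10  # m per Å
CM2_PER_NM2 = 1e-14  # cm² per nm²


def thermal_voltage(temperature: float) -> float:
    """kT/q in volts at ``temperature`` kelvin."""
    return BOLTZMANN * temperature / ELEMENTARY_CHARGE
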