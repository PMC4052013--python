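"""Physical constants and unit conventions.

Internal units are fixed throughout the package: mean molecular area in
Å²/molecule, surface pressure in mN/m, energies in J/mol.  One unit of the
product A·π (Å² · mN/m) equals 1e-23 J per molecule.
"""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant, J/K."""

AVOGADRO = 6.02214076e23
"""Avogadro constant, 1/mol."""

MNM_A2_TO_J = 1e-23
"""1 mN/m · Å² expressed in joules (per molecule)."""

DG_SCALE = AVOGADRO * MNM_A2_TO_J
"""Converts an excess-area integral ∫ΔA dπ [Å² · mN/m] to J/mol (≈ 6.022)."""

SUBPHASE_TEMPERATURE_C = 37.0
"""Default subphase temperature, °C (physiological)."""

DEFAULT_MEMBRANE_RATIO = 0.428
"""Cholesterol:POPC mole ratio of the prostate-cancer model membrane."""


def thermal_constant(temperature_c: float = SUBPHASE_TEMPERATURE_C) -> float:
    """k_B·T expressed in mN/m·Å² — the 2-D ideal-gas constant π·A.

    At 37 °C this is ≈ 428.21 mN/m·Å².
    """
    return BOLTZMANN * (temperature_c + 273.15) / MNM_A2_TO_J


THERMAL_CONSTANT_37C = thermal_constant(37.0)
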