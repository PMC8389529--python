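"""Physical constants and unit conventions.

Internal units throughout the package: length nm, energy kcal/mol,
time ps, mass amu, temperature K.  File readers convert from Å (PDB)
on input; volumes are reported in Å^3 to match the standard-state
convention.
"""

from __future__ import annotations

import math

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23

#: 1 kcal/mol expressed in amu nm^2 / ps^2 (the natural MD energy unit).
KCAL_TO_MD = 4.184

#: Default simulation temperature (K).
T_DEFAULT = 300.0

ANGSTROM_PER_NM = 10.0


def kt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy k_B * T in kcal/mol."""
    return KB_KCAL * temperature


def standard_volume() -> float:
    """Volume per molecule at 1 M standard concentration, in Å^3.

    1 litre / (1 mol * N_A) = 1e27 Å^3 / N_A ≈ 1660.5 Å^3, conventionally
    quoted as 1661 Å^3.
    """
    return 1.0e27 / N_AVOGADRO


def nm_to_angstrom(x):
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x):
    return x / ANGSTROM_PER_NM


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used for printed tables."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
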