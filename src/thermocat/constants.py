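"""Physical constants (CODATA 2018) and unit conversions used across the package.

Canonical internal units: kelvin, seconds, s^-1 (rates), mM, nm, Angstrom,
kJ mol^-1 (energies), kJ mol^-1 K^-1 (heat capacities and entropies).
"""

from scipy import constants as _sc

#: Boltzmann constant, J K^-1
K_B = _sc.k
#: Planck constant, J s
H_PLANCK = _sc.h
#: Molar gas constant, J mol^-1 K^-1
R_GAS = _sc.R

#: Offset between Celsius and Kelvin scales
CELSIUS_OFFSET = 273.15

#: kJ mol^-1 -> J mol^-1
KJ_TO_J = 1e3

#: min^-1 -> s^-1
PER_MIN_TO_PER_S = 1.0 / 60.0


def celsius_to_kelvin(t_celsius):
    """Exact conversion K = degC + 273.15."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    return t_kelvin - CELSIUS_OFFSET
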