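"""Physical constants and unit helpers shared across the package.

Energies are kcal/mol throughout, rates per minute, temperatures kelvin
internally (degrees Celsius only at user-facing interfaces).
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: 0 degrees Celsius in kelvin.
T_CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T_CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - T_CELSIUS_OFFSET
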