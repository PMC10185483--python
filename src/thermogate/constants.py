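"""Physical constants used throughout the package.

These are fixed CODATA values, never user-settable: the gas constant is the
natural unit of molar entropy in the two-state gating model, and the Faraday
constant couples the gating charge to the transmembrane voltage.
"""

#: Universal gas constant, J mol^-1 K^-1 (CODATA 2018).
R = 8.314462618

#: Faraday constant, C mol^-1 (CODATA 2018).
F = 96485.332

#: Offset between degrees Celsius and kelvin.
ZERO_C = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from degrees Celsius to kelvin."""
    return t_celsius + ZERO_C


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature from kelvin to degrees Celsius."""
    return t_kelvin - ZERO_C
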