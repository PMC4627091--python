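"""Physical constants and unit conversions.

All model math runs in kelvin and kcal/mol; Celsius appears only at the
I/O boundary.  Energies are kcal/mol throughout the package.
"""

#: Molar gas constant in kcal/(mol K).
R_KCAL: float = 1.987e-3

#: Offset between the Celsius and kelvin scales.
KELVIN_OFFSET: float = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from Celsius to kelvin."""
    return t_celsius + KELVIN_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert a temperature (scalar or array) from kelvin to Celsius."""
    return t_kelvin - KELVIN_OFFSET
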