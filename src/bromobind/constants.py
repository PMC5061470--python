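"""Physical constants and unit conversions used across all assays.

A single gas constant in kcal/(mol K) is used everywhere so that melt-curve
free energies and ITC binding thermodynamics are on the same scale.
"""

#: Gas constant, kcal/(mol K).
R_KCAL = 1.9872e-3

#: Additive offset from degrees Celsius to kelvin.
CELSIUS_OFFSET = 273.15

#: Microcalories per kilocalorie.
KCAL_TO_UCAL = 1e9


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET
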