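"""Physical constants and unit conventions.

All internal energies are kcal/mol, distances Å, temperatures K.
°C and cal/(mol·K) appear only at report boundaries.
"""

#: Universal gas constant, kcal/(mol·K).
R_KCAL: float = 1.987204e-3

#: Universal gas constant, cal/(mol·K) — used in the melting-temperature formula.
R_CAL: float = 1.987204

#: 37 °C, the conventional reporting temperature for nucleic-acid hybridization.
T_37C: float = 310.15

#: Kelvin ↔ Celsius offset.
KELVIN_OFFSET: float = 273.15

#: Histogram-overlap floor for adjacent umbrella windows.
OVERLAP_THRESHOLD: float = 0.20
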