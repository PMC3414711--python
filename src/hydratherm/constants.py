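"""Physical constants and conventions used throughout the package.

Association enthalpies/entropies are stored with their thermodynamic sign
(negative for exothermic water attachment); report tables print the negated
magnitudes.
"""

#: Molar gas constant, J/(mol K), CODATA 2018.
GAS_CONSTANT = 8.314462618

#: Standard-state pressure for the dimensionless equilibrium constant, mbar.
STANDARD_PRESSURE_MBAR = 1000.0

#: Temperature at which free energies are reported, K.
REPORT_TEMPERATURE = 298.15
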