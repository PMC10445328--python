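"""Unit conversions (CODATA values, truncated to the precision used throughout)."""

#: 1 Debye in atomic units of dipole moment (e * Bohr).
DEBYE_TO_AU = 0.393430

#: 1 Bohr in nanometres.
BOHR_IN_NM = 0.0529177

#: 1 Bohr in angstrom.
BOHR_IN_ANGSTROM = BOHR_IN_NM * 10.0

#: 1 Hartree in electronvolt.
HARTREE_IN_EV = 27.2114

#: 1 Bohr^3 in angstrom^3 (polarizability volume conversion).
BOHR3_IN_ANGSTROM3 = BOHR_IN_ANGSTROM**3
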