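"""Physical constants and unit conversions used across the package."""

#: Elementary charge in coulomb.
E_CHARGE_C = 1.602176634e-19

#: Conversion factor: a charge flux of 1 e/ps equals this many pA.
#: 1 e/ps = 1.602176634e-19 C / 1e-12 s = 1.602176634e-7 A = 1.602176634e5 pA.
E_PER_PS_TO_PA = 1.602176634e5

#: Number density of a 1 mol/L solution in particles per cubic angstrom.
#: 1 M = 6.02214076e23 / (1e27 A^3/L) = 6.02214076e-4 A^-3.
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Recognised particle species labels.
SPECIES = ("WAT", "K", "CL", "PROT", "OTHER")

#: Charge (in e) that a species must carry, where fixed by convention.
SPECIES_CHARGE = {"K": 1.0, "CL": -1.0, "WAT": 0.0}

#: Ion species contributing to the ionic current by default.
ION_SPECIES = ("K", "CL")
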