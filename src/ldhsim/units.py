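"""Physical constants and unit conventions.

Internal units: length in angstrom, energy in kcal/mol, charge in
elementary charges, temperature in kelvin.
"""

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872041

#: Coulomb constant, kcal angstrom / (mol e^2)
COULOMB_KCAL = 332.0637

#: Coulomb constant, eV angstrom / e^2 (used by charge equilibration)
COULOMB_EV = 14.399645

#: kcal/mol per eV
EV_TO_KCAL = 23.060548

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: N2 molecular cross section at 77 K, m^2 (BET convention)
N2_CROSS_SECTION_M2 = 0.162e-18

#: molar volume of liquid N2 at 77 K, cm^3/mol (Gurvich convention)
N2_LIQUID_MOLAR_VOLUME = 34.67

#: Cu K-alpha wavelength, angstrom
CU_KALPHA = 1.5406

#: atomic masses (g/mol) for the elements handled by the package
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "S": 32.06,
    "Cl": 35.45,
    "Fe": 55.845,
}
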