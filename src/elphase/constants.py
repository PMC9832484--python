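"""Physical constants and per-residue lookup tables.

All lengths in Å, energies in kcal/mol, masses in Da unless stated
otherwise.  Temperatures mix conventions downstream (experiments are
quoted in °C, formulas need K); 37 °C is always converted as 310 K.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Coulomb constant in MD units: kcal·Å/(mol·e²), CHARMM/NAMD convention.
COULOMB_KCAL_A_E2 = 332.0636

#: Mass of one water molecule added on peptide-bond condensation, Da.
WATER_MASS_DA = 18.015

#: Canonical one-letter amino-acid alphabet.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Average (isotope-abundance-weighted) residue masses in Da, i.e. the
#: mass each residue contributes inside a peptide chain (monomer mass
#: minus one water).  Values from the standard ExPASy table.
AVERAGE_RESIDUE_MASS_DA = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

#: Kyte–Doolittle hydropathy scale (dimensionless; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8,
    "R": -4.5,
    "N": -3.5,
    "D": -3.5,
    "C": 2.5,
    "E": -3.5,
    "Q": -3.5,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "L": 3.8,
    "K": -3.9,
    "M": 1.9,
    "F": 2.8,
    "P": -1.6,
    "S": -0.8,
    "T": -0.7,
    "W": -0.9,
    "Y": -1.3,
    "V": 4.2,
}

#: Atomic masses (Da) for elements that occur in peptide/water systems.
ATOMIC_MASS_DA = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
}

#: van der Waals radii (Å) used for solvent-accessible surface area,
#: element-keyed (Bondi-style set commonly used with a 1.4 Å probe).
VDW_RADIUS_A = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "NA": 2.27,
    "CL": 1.75,
}
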