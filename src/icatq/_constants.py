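"""Physico-chemical constant tables used across the package.

All tables are embedded as versioned constants so that results are
reproducible without any network access or external tool. Residue masses
are the standard amino-acid residue (i.e. water-subtracted) masses; pKa
values follow the Bjellqvist-style convention common in pI calculators.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic residue masses, Da
MONO_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Average residue masses, Da
AVG_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.0153

# Bjellqvist-style pKa set: side chains plus free termini.
# Acidic groups lose a proton above their pKa; basic groups hold one below.
PKA_NTERM = 7.50
PKA_CTERM = 3.55
PKA_ACIDIC: dict[str, float] = {"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}
PKA_BASIC: dict[str, float] = {"H": 5.98, "K": 10.00, "R": 12.00}

# Background amino-acid frequencies (Swiss-Prot-like, percent scale) used by
# the proteome simulator; the Cys entry is replaced by the requested Cys
# probability and the rest renormalised.
AA_BACKGROUND_FREQ: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

# Cleavable ICAT reagent masses per labeled cysteine, Da
ICAT_LIGHT_MASS = 227.127
ICAT_HEAVY_MASS = 236.157
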