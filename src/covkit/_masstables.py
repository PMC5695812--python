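"""Pinned atomic and amino-acid residue mass constants.

All masses in daltons (Da). The monoisotopic values are masses of the most
abundant isotope (CODATA/IUPAC); the average values are standard atomic
weights. These tables are frozen so downstream arithmetic is bit-stable:
do not update them without bumping the package version.

Convention: exact-mass arithmetic in this package never applies an
electron-mass correction. Ionic m/z values are computed from sums of
*atomic* masses, which matches the "calcd" convention of high-resolution
MS reports for small molecules (e.g. an [M+Na]+ calcd value is the neutral
monoisotopic mass plus the sodium atomic mass). A bare-proton charge
carrier (1.00727646688 Da) is also available under the symbol "H+" for
strict peptide m/z arithmetic; the two differ by one electron mass
(~0.00055 Da), which is below the tolerance of every value handled here.
"""

from __future__ import annotations

# element symbol -> (monoisotopic Da, average Da)
ELEMENT_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.00794),
    "C": (12.0, 12.0107),
    "N": (14.0030740048, 14.0067),
    "O": (15.9949146196, 15.9994),
    "P": (30.97376163, 30.973762),
    "S": (31.97207100, 32.065),
    "Cl": (34.96885268, 35.453),
    "Na": (22.9897692809, 22.98976928),
    "K": (38.96370668, 39.0983),
    "F": (18.99840322, 18.9984032),
    "Br": (78.9183371, 79.904),
    "I": (126.904473, 126.90447),
    "Se": (79.9165213, 78.96),
    "Fe": (55.9349375, 55.845),
}

#: mass of a bare proton (H nucleus), Da
PROTON_MASS: float = 1.00727646688

#: symbol accepted by ion specs for a bare proton charge carrier
PROTON_SYMBOL = "H+"

# one-letter code -> (monoisotopic residue mass, average residue mass)
# residue mass = amino acid minus one water; peptide neutral mass adds
# one water back per chain.
RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    "G": (57.02146373, 57.0519),
    "A": (71.03711379, 71.0788),
    "S": (87.03202841, 87.0782),
    "P": (97.05276385, 97.1167),
    "V": (99.06841391, 99.1326),
    "T": (101.04767847, 101.1051),
    "C": (103.00918448, 103.1388),
    "L": (113.08406398, 113.1594),
    "I": (113.08406398, 113.1594),
    "N": (114.04292744, 114.1038),
    "D": (115.02694302, 115.0886),
    "Q": (128.05857751, 128.1307),
    "K": (128.09496302, 128.1741),
    "E": (129.04259309, 129.1155),
    "M": (131.04048491, 131.1926),
    "H": (137.05891186, 137.1411),
    "F": (147.06841391, 147.1766),
    "R": (156.10111102, 156.1875),
    "Y": (163.06332853, 163.1760),
    "W": (186.07931295, 186.2132),
}
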