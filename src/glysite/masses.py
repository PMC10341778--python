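"""Monoisotopic mass constants.

All masses are neutral monoisotopic values in Da. Amino-acid masses are
*residue* masses (the chain contribution, i.e. the free amino acid minus
water); a peptide's neutral mass is the residue sum plus one water.
Monosaccharide masses are likewise glycosidic *residue* masses, so glycan
attachment is purely additive — the condensation water loss is already
encoded.
"""

#: Monoisotopic mass of water, Da.
WATER = 18.0105646863

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue masses of the 20 canonical amino acids, Da.
AA_RESIDUE_MASS = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841390,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406396,
    "I": 113.08406396,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048508,
    "H": 137.05891185,
    "F": 147.06841390,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}

#: Monosaccharide glycosidic residue masses, Da.
HEXNAC = 203.07937253  # N-acetylhexosamine, C8H13NO5
HEX = 162.05282343     # hexose, C6H10O5
FUC = 146.05790880     # deoxyhexose (fucose), C6H10O4
NEUAC = 291.09541653   # N-acetylneuraminic acid, C11H17NO8
NEUGC = 307.09033115   # N-glycolylneuraminic acid, C11H17NO9

#: Elemental formulas of the monosaccharide residues (for documentation and
#: for callers that want to rebuild the masses from atomic compositions).
MONOSACCHARIDE_FORMULA = {
    "hexnac": "C8H13NO5",
    "hex": "C6H10O5",
    "fuc": "C6H10O4",
    "neuac": "C11H17NO8",
    "neugc": "C11H17NO9",
}

CANONICAL_RESIDUES = frozenset(AA_RESIDUE_MASS)

#: Default fixed modifications: carbamidomethyl on every Cys.
DEFAULT_FIXED_MODS = {"C": CARBAMIDOMETHYL}
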