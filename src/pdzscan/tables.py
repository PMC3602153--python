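"""Per-residue and per-atom lookup tables used across the package.

All tables are plain module-level dicts so they can be monkey-patched or
replaced wholesale by callers that want a different physical model.
"""

# 20 standard amino acids, 3-letter -> 1-letter
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Fixed amino-acid alphabet for all sparse encodings and PWM rows:
# alphabetical by 1-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

# Chothia (1976) van der Waals radii by element, Angstrom.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "H": 1.00,
    "P": 1.90,
}

# Maximum solvent-accessible area of residue X in an extended Gly-X-Gly
# tripeptide (Miller et al. 1987), Angstrom^2.  Used for relative
# accessibility; the binary "accessible" feature applies a 7% threshold
# to area / reference.
GXG_REFERENCE_AREA = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

# Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Partial charges (elementary charge units) on titratable side-chain
# atoms at neutral pH.  Charges are split over symmetric atoms.
PARTIAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("HIS", "ND1"): 0.05,
    ("HIS", "NE2"): 0.05,
}

# Side-chain hydrogen-bond donors: (residue, atom) -> antecedent heavy
# atom used for the geometric angle criterion when hydrogens are absent.
SIDECHAIN_DONORS = {
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1",
    ("CYS", "SG"): "CB",
}

# Side-chain hydrogen-bond acceptors: set of (residue, atom).
SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}

# Backbone atom names (everything else in a residue counts as side chain).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Representative side-chain atom name for the single pseudo-atom used by
# the synthetic structure fixtures (carries the charge / donor /
# acceptor identity of the real side chain).
REPRESENTATIVE_SIDECHAIN_ATOM = {
    "ALA": ("CB", "C"), "ARG": ("NH1", "N"), "ASN": ("OD1", "O"),
    "ASP": ("OD1", "O"), "CYS": ("SG", "S"), "GLN": ("OE1", "O"),
    "GLU": ("OE1", "O"), "GLY": None, "HIS": ("NE2", "N"),
    "ILE": ("CD1", "C"), "LEU": ("CD1", "C"), "LYS": ("NZ", "N"),
    "MET": ("SD", "S"), "PHE": ("CZ", "C"), "PRO": ("CG", "C"),
    "SER": ("OG", "O"), "THR": ("OG1", "O"), "TRP": ("NE1", "N"),
    "TYR": ("OH", "O"), "VAL": ("CG1", "C"),
}

# Coulomb constant in kcal * Angstrom / (mol * e^2); used with the
# distance-dependent dielectric eps = 4r.
COULOMB_KCAL = 332.0637
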