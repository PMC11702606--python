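"""Chemical constant tables used by the surface and contact detectors.

Radii are single-atom van der Waals radii (Bondi); hydrogen-bond donor and
acceptor atoms follow standard amino-acid chemistry. All atom names are PDB
v3 names. Hydrogens are never part of these tables: heavy-atom criteria are
primary because X-ray depositions usually lack hydrogens.
"""

from __future__ import annotations

# van der Waals radii in Angstrom, keyed by element symbol (upper case).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Default probe radius (water) in Angstrom.
PROBE_RADIUS = 1.4

#: Default number of sphere sample points per atom.
N_SPHERE_POINTS = 960

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_LETTERS = frozenset(ONE_TO_THREE)

# --- Hydrogen bonds -------------------------------------------------------
# Side-chain donor heavy atoms with the antecedent atom used for the
# antecedent-donor-acceptor angle criterion when no hydrogens are present.
SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "LYS": [("NZ", "CE")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "TRP": [("NE1", "CD1")],
    "ASN": [("ND2", "CG")],
    "GLN": [("NE2", "CD")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
}

# Backbone amide N donates for every residue except proline; CA is used as
# the angle antecedent (the carbonyl C of the previous residue is not
# guaranteed to be present in subset models).
BACKBONE_DONOR = ("N", "CA")

SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
}

BACKBONE_ACCEPTORS = ("O", "OXT")

# --- Salt bridges ---------------------------------------------------------
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def donor_atoms(res_name: str) -> list[tuple[str, str]]:
    """(donor, antecedent) heavy-atom name pairs for a residue type."""
    pairs = [] if res_name == "PRO" else [BACKBONE_DONOR]
    pairs += SIDECHAIN_DONORS.get(res_name, [])
    return pairs


def acceptor_atoms(res_name: str) -> list[str]:
    names = list(BACKBONE_ACCEPTORS)
    names += SIDECHAIN_ACCEPTORS.get(res_name, [])
    return names
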