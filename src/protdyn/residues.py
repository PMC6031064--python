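"""Amino-acid reference data: codes, masses, radii, idealized side-chain
internal coordinates for single-rotamer mutant building."""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = set(ONE_TO_THREE)

# Common non-standard residues mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "CME": "CYS",
}

# Total residue masses (Da), amino-acid residue within a chain.
RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

# van der Waals radii (Å) by element for SASA.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Idealized side-chain construction: each heavy atom is placed by NeRF from
# three previously known atoms as (name, (ref_a, ref_b, ref_c), bond Å,
# angle deg (b-c-new), dihedral deg (a-b-c-new)).  Single most-common
# rotamer, chi1 = -60 unless geometry dictates otherwise; ring geometry is
# idealized planar.  CB is placed with the L-configuration improper.
_CB = ("CB", ("C", "N", "CA"), 1.53, 110.5, 122.6)

SIDECHAIN_ICOORDS: dict[str, list[tuple]] = {
    "ALA": [_CB],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, -60.0),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, -60.0),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, 120.0),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, -60.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, -20.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, 160.0),
    ],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 114.0, -60.0)],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, -60.0),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, 120.0),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, -20.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, 160.0),
    ],
    "GLY": [],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, -75.0),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, 105.0),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, -60.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, 62.0),
        ("CD1", ("CA", "CB", "CG1"), 1.53, 113.9, 170.0),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.53, 110.5, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.53, 110.5, 60.0),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
        ("SD", ("CA", "CB", "CG"), 1.81, 112.7, 180.0),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, 180.0),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 104.0, 30.0),
        ("CD", ("CA", "CB", "CG"), 1.50, 105.0, -35.0),
    ],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 110.8, -60.0)],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, -60.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, 62.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, -90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.40, 107.2, 180.0),
        ("CE3", ("NE1", "CE2", "CD2"), 1.40, 133.9, 180.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CE2", "CD2", "CE3"), 1.39, 118.6, 0.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.51, 113.8, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 121.1, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 121.1, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 175.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -63.0),
    ],
}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB atom name (heavy atoms only)."""
    name = atom_name.strip()
    if name[:2] in ("SE",):
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"
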