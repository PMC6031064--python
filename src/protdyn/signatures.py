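"""Graph-based structural signatures and wild-type residue environment
features: pharmacophore labelling, cutoff-scan atom-pair counts, mutation
pharmacophore deltas, relative solvent accessibility, residue depth and a
three-class secondary-structure assignment.

The cutoff-scan signature counts heavy-atom pairs around a residue,
stratified by pharmacophore class pair and cumulative distance bin — the
structural fingerprint used as consensus evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import dihedral
from .residues import BACKBONE_ATOMS, ONE_TO_THREE, SIDECHAIN_ICOORDS
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, shrake_rupley
from .structure import Residue, Structure, make_toy_structure

__all__ = [
    "PHARMACOPHORE_CLASSES",
    "SignatureVector",
    "EnvironmentFeatures",
    "atom_pharmacophores",
    "assign_pharmacophores",
    "cutoff_scan_signature",
    "mutation_pharmacophore_delta",
    "relative_solvent_accessibility",
    "residue_depth",
    "secondary_structure",
]

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "positive", "negative", "acceptor",
    "donor", "aromatic", "sulfur", "neutral",
)

_AROMATIC_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

# side-chain special cases: residue -> atom -> classes
_SPECIAL = {
    "LYS": {"NZ": {"positive", "donor"}},
    "ARG": {"NE": {"positive", "donor"}, "NH1": {"positive", "donor"},
            "NH2": {"positive", "donor"}},
    "HIS": {"ND1": {"donor", "acceptor"}, "NE2": {"donor", "acceptor"}},
    "ASP": {"OD1": {"negative", "acceptor"}, "OD2": {"negative", "acceptor"}},
    "GLU": {"OE1": {"negative", "acceptor"}, "OE2": {"negative", "acceptor"}},
    "ASN": {"OD1": {"acceptor"}, "ND2": {"donor"}},
    "GLN": {"OE1": {"acceptor"}, "NE2": {"donor"}},
    "SER": {"OG": {"donor", "acceptor"}},
    "THR": {"OG1": {"donor", "acceptor"}},
    "TYR": {"OH": {"donor", "acceptor"}},
    "CYS": {"SG": {"sulfur"}},
    "MET": {"SD": {"sulfur"}},
    "TRP": {"NE1": {"donor"}},
}


def atom_pharmacophores(residue_name: str, atom_name: str) -> frozenset[str]:
    """Pharmacophore classes of one heavy atom from the fixed lookup table.

    Carbons are hydrophobic (plus aromatic inside rings); backbone N is a
    donor and backbone O an acceptor; atoms absent from the table are
    neutral.
    """
    classes: set[str] = set()
    special = _SPECIAL.get(residue_name, {}).get(atom_name)
    if special:
        classes |= special
    ring = _AROMATIC_RING.get(residue_name)
    if ring and atom_name in ring:
        classes.add("aromatic")
        if atom_name.startswith("C"):
            classes.add("hydrophobic")
    if not classes:
        if atom_name == "N":
            classes.add("donor")
        elif atom_name in ("O", "OXT"):
            classes.add("acceptor")
        elif atom_name.startswith("C"):
            classes.add("hydrophobic")
        else:
            classes.add("neutral")
    return frozenset(classes)


def assign_pharmacophores(structure: Structure) -> list[frozenset[str]]:
    """Per-atom pharmacophore classes, aligned with ``structure.atoms``."""
    return [atom_pharmacophores(a.residue_name, a.name) for a in structure.atoms]


_CLASS_PAIRS = tuple(
    itertools.combinations_with_replacement(PHARMACOPHORE_CLASSES, 2)
)
_PAIR_INDEX = {p: k for k, p in enumerate(_CLASS_PAIRS)}


@dataclass
class SignatureVector:
    """Cumulative (class-pair × distance-bin) atom-pair counts."""

    counts: np.ndarray              # (n_class_pairs, n_bins)
    bin_edges: tuple[float, ...]    # cumulative upper edges, Å
    class_pairs: tuple = _CLASS_PAIRS

    def flat(self) -> np.ndarray:
        return self.counts.reshape(-1)

    @staticmethod
    def feature_names(bin_edges=(2.0, 4.0, 6.0, 8.0, 10.0)) -> list[str]:
        return [
            f"sig_{a}:{b}_{edge:g}A"
            for (a, b) in _CLASS_PAIRS
            for edge in bin_edges
        ]


def cutoff_scan_signature(
    structure: Structure,
    chain_id: str,
    residue_number: int,
    insertion_code: str = "",
    labels: list[frozenset[str]] | None = None,
    radius: float = 10.0,
    bin_edges: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0),
) -> SignatureVector:
    """Cutoff-scan signature centred on one residue.

    Heavy atoms within ``radius`` of any atom of the centre residue form the
    local environment; every unordered atom pair contributes one count per
    shared (class-pair, cumulative bin) cell for each bin edge ≥ its
    distance.
    """
    res = structure.get_residue(chain_id, residue_number, insertion_code)
    if res is None:
        raise KeyError(f"residue {chain_id}/{residue_number}{insertion_code}")
    if labels is None:
        labels = assign_pharmacophores(structure)
    heavy = [(i, a) for i, a in enumerate(structure.atoms) if a.element != "H"]
    coords = np.array([a.coords for _, a in heavy])
    center = np.array([a.coords for a in res.atoms if a.element != "H"])
    counts = np.zeros((len(_CLASS_PAIRS), len(bin_edges)), dtype=int)
    if radius <= 0 or len(center) == 0:
        return SignatureVector(counts=counts, bin_edges=tuple(bin_edges))
    tree = cKDTree(coords)
    env_idx = sorted(set(itertools.chain.from_iterable(
        tree.query_ball_point(c, radius) for c in center
    )))
    env_coords = coords[env_idx]
    env_labels = [labels[heavy[i][0]] for i in env_idx]
    max_edge = max(bin_edges)
    pair_tree = cKDTree(env_coords)
    edges = np.asarray(bin_edges)
    for a, b in pair_tree.query_pairs(max_edge):
        d = float(np.linalg.norm(env_coords[a] - env_coords[b]))
        bin_mask = edges >= d
        for ca in env_labels[a]:
            for cb in env_labels[b]:
                pair = (ca, cb) if (ca, cb) in _PAIR_INDEX else (cb, ca)
                counts[_PAIR_INDEX[pair]] += bin_mask
    return SignatureVector(counts=counts, bin_edges=tuple(bin_edges))


# formal charge is carried by one group, not by each resonance-equivalent atom
_GROUP_CHARGES = {"D": ("negative", 1), "E": ("negative", 1),
                  "K": ("positive", 1), "R": ("positive", 1)}


@lru_cache(maxsize=None)
def _sidechain_class_counts(aa: str) -> tuple[int, ...]:
    """Pharmacophore class counts over the heavy side-chain atoms of one
    amino acid (multi-class atoms count once per class; charged classes are
    counted once per charged group)."""
    res3 = ONE_TO_THREE[aa]
    counts = dict.fromkeys(PHARMACOPHORE_CLASSES, 0)
    for name, *_ in SIDECHAIN_ICOORDS[res3]:
        for cls in atom_pharmacophores(res3, name):
            counts[cls] += 1
    if aa in _GROUP_CHARGES:
        cls, n = _GROUP_CHARGES[aa]
        counts[cls] = n
    return tuple(counts[c] for c in PHARMACOPHORE_CLASSES)


def mutation_pharmacophore_delta(wild_aa: str, mutant_aa: str) -> np.ndarray:
    """Per-class side-chain pharmacophore count change, mutant − wild type,
    ordered as PHARMACOPHORE_CLASSES."""
    w = np.array(_sidechain_class_counts(wild_aa))
    m = np.array(_sidechain_class_counts(mutant_aa))
    return m - w


@dataclass
class EnvironmentFeatures:
    rsa: float
    depth: float
    ss_class: str


def _heavy(structure: Structure):
    atoms = [a for a in structure.atoms if a.element != "H"]
    coords = np.array([a.coords for a in atoms])
    elements = [a.element for a in atoms]
    return atoms, coords, elements


def _residue_frame(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame anchored on the residue's N–CA–C backbone.

    Expressing all coordinates in this frame before sphere sampling makes
    RSA and depth exactly invariant under rigid transforms of the input
    (the sampling directions co-rotate with the residue).
    """
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        return np.zeros(3), np.eye(3)
    x = n.coords - ca.coords
    x = x / np.linalg.norm(x)
    z = np.cross(x, c.coords - ca.coords)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    return ca.coords.copy(), np.column_stack([x, y, z])


def _frame_coords(coords: np.ndarray, res: Residue) -> np.ndarray:
    origin, rot = _residue_frame(res)
    return (coords - origin) @ rot


@lru_cache(maxsize=None)
def _reference_sasa(aa: str, probe: float, n_points: int) -> float:
    """SASA of residue X in an extended Gly-X-Gly tripeptide, computed by
    the same algorithm used for structures (so RSA ≲ 1 by construction)."""
    tri = make_toy_structure("extended_chain", 3, sequence=f"G{aa}G")
    atoms, coords, elements = _heavy(tri)
    mid = tri.get_residue("A", 2)
    areas = shrake_rupley(_frame_coords(coords, mid), elements, probe=probe,
                          n_points=n_points)
    return float(sum(ar for ar, a in zip(areas, atoms) if a.residue_number == 2))


def relative_solvent_accessibility(
    structure: Structure,
    chain_id: str,
    residue_number: int,
    insertion_code: str = "",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Residue SASA divided by its extended Gly-X-Gly reference SASA."""
    res = structure.get_residue(chain_id, residue_number, insertion_code)
    if res is None:
        raise KeyError(f"residue {chain_id}/{residue_number}{insertion_code}")
    atoms, coords, elements = _heavy(structure)
    areas = shrake_rupley(_frame_coords(coords, res), elements, probe=probe,
                          n_points=n_points)
    key = (res.chain_id, res.number, res.insertion_code.strip())
    sasa = sum(
        ar for ar, a in zip(areas, atoms)
        if (a.chain_id, a.residue_number, a.insertion_code.strip()) == key
    )
    ref = _reference_sasa(res.one_letter, probe, n_points)
    return float(sasa / ref) if ref > 0 else 0.0


def residue_depth(
    structure: Structure,
    chain_id: str,
    residue_number: int,
    insertion_code: str = "",
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Mean distance (Å) of the residue's heavy atoms to the nearest
    accessible-surface dot of the whole structure."""
    res = structure.get_residue(chain_id, residue_number, insertion_code)
    if res is None:
        raise KeyError(f"residue {chain_id}/{residue_number}{insertion_code}")
    _, coords, elements = _heavy(structure)
    framed = _frame_coords(coords, res)
    _, surface = shrake_rupley(framed, elements, probe=probe,
                               n_points=n_points, return_surface_dots=True)
    if len(surface) == 0:
        return 0.0
    res_coords = _frame_coords(
        np.array([a.coords for a in res.atoms if a.element != "H"]), res)
    tree = cKDTree(surface)
    d, _ = tree.query(res_coords)
    return float(np.mean(d))


def _phi_psi(structure: Structure, residues: list[Residue], i: int):
    res = residues[i]
    needed = {"N", "CA", "C"}
    if not needed.issubset({a.name for a in res.atoms}):
        return None, None
    phi = psi = None
    if i > 0 and residues[i - 1].chain_id == res.chain_id:
        prev_c = residues[i - 1].atom("C")
        if prev_c is not None:
            phi = dihedral(prev_c.coords, res.atom("N").coords,
                           res.atom("CA").coords, res.atom("C").coords)
    if i + 1 < len(residues) and residues[i + 1].chain_id == res.chain_id:
        next_n = residues[i + 1].atom("N")
        if next_n is not None:
            psi = dihedral(res.atom("N").coords, res.atom("CA").coords,
                           res.atom("C").coords, next_n.coords)
    return phi, psi


def secondary_structure(
    structure: Structure,
    chain_id: str,
    residue_number: int,
    insertion_code: str = "",
) -> str:
    """Three-class secondary structure from backbone φ/ψ windows:
    helix for φ∈(−100°,−30°) ∧ ψ∈(−80°,−5°); strand for φ∈(−180°,−90°) ∧
    ψ∈(90°,180°); otherwise coil. Terminal or incomplete residues are coil.
    """
    residues = structure.residues()
    idx = None
    icode = (insertion_code or "").strip()
    for i, r in enumerate(residues):
        if (r.chain_id == chain_id and r.number == residue_number
                and r.insertion_code.strip() == icode):
            idx = i
            break
    if idx is None:
        raise KeyError(f"residue {chain_id}/{residue_number}{insertion_code}")
    phi, psi = _phi_psi(structure, residues, idx)
    if phi is None or psi is None:
        return "coil"
    if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
        return "helix"
    if -180.0 < phi < -90.0 and 90.0 < psi < 180.0:
        return "strand"
    return "coil"
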