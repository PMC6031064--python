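"""Protein structure handling: PDB input/output, coarse-grained models,
idealized mutant building and synthetic fixture structures.

Structures are lightweight dataclass views; parsing and writing go through
gemmi. Author residue numbering (1-based, with insertion codes) is kept
verbatim; internal site indices are 0-based and contiguous.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._geometry import place_atom
from .residues import (
    BACKBONE_ATOMS,
    NONSTANDARD_PARENT,
    ONE_TO_THREE,
    RESIDUE_MASS,
    SIDECHAIN_ICOORDS,
    STANDARD_AA,
    THREE_TO_ONE,
    element_of,
)


class PDBFormatError(ValueError):
    """Raised when PDB content cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no protein atoms."""


class MutationError(ValueError):
    """Raised for invalid or mismatched mutation specifications."""


class TooFewSitesError(ValueError):
    """Raised when a coarse model would have fewer than two sites."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    altloc: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def copy(self) -> "Atom":
        new = dataclasses.replace(self)
        new.coords = self.coords.copy()
        return new


@dataclass
class Residue:
    """Grouped view over a Structure's atoms; shares Atom objects."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        name = NONSTANDARD_PARENT.get(self.name, self.name)
        return THREE_TO_ONE.get(name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


@dataclass
class Structure:
    atoms: list[Atom] = field(default_factory=list)
    het_atoms: list[Atom] = field(default_factory=list)
    model_id: int = 1
    name: str = ""

    def residues(self, chains: Iterable[str] | None = None) -> list[Residue]:
        wanted = set(chains) if chains is not None else None
        out: list[Residue] = []
        for (ch, num, icode, rname), grp in itertools.groupby(
            self.atoms,
            key=lambda a: (a.chain_id, a.residue_number, a.insertion_code, a.residue_name),
        ):
            if wanted is not None and ch not in wanted:
                continue
            out.append(Residue(ch, num, icode, rname, list(grp)))
        return out

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.residues([chain_id]))

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        icode = (icode or "").strip()
        for r in self.residues([chain_id]):
            if r.number == number and r.insertion_code.strip() == icode:
                return r
        return None

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def copy(self) -> "Structure":
        return Structure(
            atoms=[a.copy() for a in self.atoms],
            het_atoms=[a.copy() for a in self.het_atoms],
            model_id=self.model_id,
            name=self.name,
        )


@dataclass
class Site:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    coord: np.ndarray
    mass: float


@dataclass
class CoarseModel:
    """One site per amino-acid residue with a Cα atom, in chain order."""

    sites: list[Site]
    source: Structure | None = None
    skipped: list[tuple[str, int, str]] = field(default_factory=list)
    mass_scheme: str = "residue"

    def __len__(self) -> int:
        return len(self.sites)

    def coords(self) -> np.ndarray:
        return np.array([s.coord for s in self.sites])

    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites])

    def site_index(self, chain_id: str, residue_number: int, icode: str = "") -> int:
        icode = (icode or "").strip()
        for i, s in enumerate(self.sites):
            if (
                s.chain_id == chain_id
                and s.residue_number == residue_number
                and s.insertion_code.strip() == icode
            ):
                return i
        raise KeyError(f"no site {chain_id}/{residue_number}{icode}")


@dataclass(frozen=True)
class MutationSpec:
    chain_id: str
    wild_aa: str
    residue_number: int
    mutant_aa: str
    insertion_code: str = ""

    def __post_init__(self):
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in STANDARD_AA:
                raise MutationError(f"non-standard amino acid code {aa!r}")

    @classmethod
    def parse(cls, text: str, chain_id: str) -> "MutationSpec":
        """Parse strings like 'A17G' or 'A17aG' (insertion code 'a')."""
        text = text.strip()
        if len(text) < 3:
            raise MutationError(f"mutation string too short: {text!r}")
        wild, mut = text[0].upper(), text[-1].upper()
        middle = text[1:-1]
        icode = ""
        if middle and middle[-1].isalpha():
            icode, middle = middle[-1], middle[:-1]
        try:
            num = int(middle)
        except ValueError:
            raise MutationError(f"cannot parse residue number in {text!r}") from None
        return cls(chain_id=chain_id, wild_aa=wild, residue_number=num,
                   mutant_aa=mut, insertion_code=icode)

    def reverse(self) -> "MutationSpec":
        return MutationSpec(self.chain_id, self.mutant_aa, self.residue_number,
                            self.wild_aa, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.wild_aa}{self.residue_number}{self.insertion_code}{self.mutant_aa}"


def _is_protein_resname(name: str) -> bool:
    return name in THREE_TO_ONE or name in NONSTANDARD_PARENT


def read_structure(source: str | Path, model: int = 1,
                   altloc_policy: str = "highest_occupancy") -> Structure:
    """Read one model from PDB text or a PDB file.

    Altlocs are resolved per policy (default: keep the highest-occupancy
    location, ties broken by alphabetical altloc id). HETATM ligands and
    waters are kept in `het_atoms`, never among protein atoms.
    """
    text_input = isinstance(source, str) and "\n" in source
    try:
        if text_input:
            st = gemmi.read_pdb_string(source)
        else:
            path = Path(source)
            if not path.exists():
                raise PDBFormatError(f"no such file: {path}")
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB input: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError("no models in input")
    model_idx = None
    for i, m in enumerate(st):
        if m.num == model:
            model_idx = i
            break
    if model_idx is None:
        if model == 1:
            model_idx = 0
        else:
            raise PDBFormatError(f"model {model} not present")
    gmodel = st[model_idx]

    atoms: list[Atom] = []
    het: list[Atom] = []
    for chain in gmodel:
        for res in chain:
            protein = _is_protein_resname(res.name)
            # altloc resolution within one residue, per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in res:
                by_name.setdefault(a.name, []).append(a)
            for name, group in by_name.items():
                if len(group) == 1:
                    chosen = group[0]
                else:
                    chosen = sorted(
                        group, key=lambda a: (-a.occ, a.altloc or "~")
                    )[0]
                atom = Atom(
                    serial=chosen.serial,
                    name=name,
                    element=chosen.element.name.upper() or element_of(name),
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    chain_id=chain.name,
                    altloc=(chosen.altloc or "").strip(),
                    coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                    occupancy=chosen.occ,
                    bfactor=chosen.b_iso,
                )
                if not np.all(np.isfinite(atom.coords)):
                    raise PDBFormatError(
                        f"non-finite coordinates at atom serial {atom.serial}"
                    )
                (atoms if protein else het).append(atom)

    if not atoms:
        raise EmptyStructureError("input contains no protein atoms")
    order = {}
    # keep original chain/residue order as encountered
    result = Structure(atoms=atoms, het_atoms=het, model_id=model)
    del order
    return result


def _structure_to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "protdyn"
    gmodel = gemmi.Model(structure.model_id)
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in structure.residues():
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
        gres.het_flag = "A"
        for a in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            ga.serial = serial
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a fixed-column PDB file."""
    st = _structure_to_gemmi(structure)
    st.write_pdb(str(path))


def structure_to_pdb_string(structure: Structure) -> str:
    return _structure_to_gemmi(structure).make_pdb_string()


def extract_coarse_grain(
    structure: Structure,
    chains: Iterable[str] | None = None,
    mass_scheme: str = "residue",
) -> CoarseModel:
    """Cα-level coarse-grained model: one site per amino-acid residue with a
    Cα atom. Residues lacking a Cα (or unmappable names) are skipped and
    reported in `skipped`. mass_scheme: 'residue' (total residue mass by
    type) or 'unit'."""
    if mass_scheme not in ("residue", "unit"):
        raise ValueError(f"unknown mass scheme {mass_scheme!r}")
    sites: list[Site] = []
    skipped: list[tuple[str, int, str]] = []
    for res in structure.residues(chains):
        one = res.one_letter
        ca = res.atom("CA")
        if ca is None or one == "X":
            skipped.append(res.key)
            continue
        mass = 1.0 if mass_scheme == "unit" else RESIDUE_MASS[one]
        sites.append(
            Site(res.chain_id, res.number, res.insertion_code,
                 res.name, ca.coords.copy(), mass)
        )
    if len(sites) < 2:
        raise TooFewSitesError(
            f"coarse model needs >= 2 sites with CA, got {len(sites)}"
        )
    return CoarseModel(sites=sites, source=structure, skipped=skipped,
                       mass_scheme=mass_scheme)


def build_mutant(structure: Structure, mutation: MutationSpec) -> Structure:
    """Model a point mutant by idealized side-chain replacement.

    Backbone atoms (N, CA, C, O) and the Cβ are preserved where present;
    the new side chain is placed from idealized internal coordinates with a
    single common rotamer and no minimization.
    """
    res = structure.get_residue(mutation.chain_id, mutation.residue_number,
                                mutation.insertion_code)
    if res is None:
        raise MutationError(
            f"residue {mutation.chain_id}/{mutation.residue_number}"
            f"{mutation.insertion_code} not found"
        )
    if res.one_letter != mutation.wild_aa:
        raise MutationError(
            f"wild-type mismatch at {mutation.chain_id}/{mutation.residue_number}: "
            f"expected {mutation.wild_aa}, structure has {res.name} ({res.one_letter})"
        )
    target3 = ONE_TO_THREE[mutation.mutant_aa]
    known: dict[str, np.ndarray] = {}
    for name in BACKBONE_ATOMS:
        a = res.atom(name)
        if a is not None:
            known[name] = a.coords.copy()
    for name in ("N", "CA", "C"):
        if name not in known:
            raise MutationError(
                f"cannot rebuild side chain: backbone atom {name} missing at "
                f"{mutation.chain_id}/{mutation.residue_number}"
            )
    cb = res.atom("CB")
    if cb is not None and target3 != "GLY":
        known["CB"] = cb.coords.copy()

    placed: list[tuple[str, np.ndarray]] = []
    for name, (ra, rb, rc), bond, ang, dih in SIDECHAIN_ICOORDS[target3]:
        if name in known:
            continue
        pos = place_atom(known[ra], known[rb], known[rc], bond, ang, dih)
        known[name] = pos
        placed.append((name, pos))

    keep_names = set(BACKBONE_ATOMS)
    if target3 != "GLY":
        keep_names.add("CB")
    sidechain_names = [name for name, *_ in SIDECHAIN_ICOORDS[target3]]

    mutant = structure.copy()
    mres = mutant.get_residue(mutation.chain_id, mutation.residue_number,
                              mutation.insertion_code)
    assert mres is not None
    template = mres.atoms[0]
    new_atoms: list[Atom] = []
    for a in mres.atoms:
        if a.name in keep_names:
            a.residue_name = target3
            new_atoms.append(a)
    existing = {a.name for a in new_atoms}
    for name in sidechain_names:
        if name in existing:
            continue
        new_atoms.append(
            Atom(
                serial=0,
                name=name,
                element=element_of(name),
                residue_name=target3,
                residue_number=template.residue_number,
                insertion_code=template.insertion_code,
                chain_id=template.chain_id,
                altloc="",
                coords=known[name].copy(),
                occupancy=1.0,
                bfactor=template.bfactor,
            )
        )
    # splice the rebuilt residue back in place
    old_ids = {id(a) for a in mres.atoms}
    out: list[Atom] = []
    inserted = False
    for a in mutant.atoms:
        if id(a) in old_ids:
            if not inserted:
                out.extend(new_atoms)
                inserted = True
            continue
        out.append(a)
    mutant.atoms = out
    for i, a in enumerate(mutant.atoms, start=1):
        a.serial = i
    return mutant


def write_mode_trajectory(
    model: CoarseModel,
    mode: np.ndarray,
    amplitude: float,
    n_frames: int,
    path: str | Path,
) -> None:
    """Write a multi-model PDB animating displacement along one mode.

    Frame k (k = 1..n_frames) places each site at
    coord + amplitude * sin(2πk / n_frames) * mode_vector.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.shape != (len(model.sites), 3):
        raise ValueError(
            f"mode shape {mode.shape} does not match {len(model.sites)} sites"
        )
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    st = gemmi.Structure()
    st.name = "mode-trajectory"
    base = model.coords()
    for k in range(1, n_frames + 1):
        phase = np.sin(2.0 * np.pi * k / n_frames)
        coords = base + amplitude * phase * mode
        gmodel = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}
        for i, site in enumerate(model.sites):
            ch = chains.get(site.chain_id)
            if ch is None:
                ch = gemmi.Chain(site.chain_id)
                chains[site.chain_id] = ch
            res = gemmi.Residue()
            res.name = site.residue_name
            res.seqid = gemmi.SeqId(site.residue_number, site.insertion_code or " ")
            res.het_flag = "A"
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(*coords[i])
            a.occ = 1.0
            a.serial = i + 1
            res.add_atom(a)
            ch.add_residue(res)
        for ch in chains.values():
            gmodel.add_chain(ch)
        st.add_model(gmodel)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Synthetic fixture structures

_BACKBONE_GEOM = dict(
    n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
    ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7, ang_ca_c_o=120.8,
)


def _build_backbone(n_residues: int, phi: float, psi: float,
                    omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Idealized backbone (N, CA, C, O) for a chain with uniform torsions."""
    g = _BACKBONE_GEOM
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    theta = np.deg2rad(g["ang_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], g["c_n"],
                       g["ang_ca_c_n"], psi)
        ca = place_atom(prev["CA"], prev["C"], n, g["n_ca"],
                        g["ang_c_n_ca"], omega)
        c = place_atom(prev["C"], n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            # carbonyl O anti to the next N
            r["O"] = place_atom(res[i + 1]["N"], r["CA"], r["C"], g["c_o"],
                                g["ang_ca_c_o"], 180.0)
        else:
            r["O"] = place_atom(r["N"], r["CA"], r["C"], g["c_o"],
                                g["ang_ca_c_o"], psi + 180.0)
    return res


def _add_sidechain(coords: dict[str, np.ndarray], resname3: str) -> dict[str, np.ndarray]:
    out = dict(coords)
    for name, (ra, rb, rc), bond, ang, dih in SIDECHAIN_ICOORDS[resname3]:
        if name not in out:
            out[name] = place_atom(out[ra], out[rb], out[rc], bond, ang, dih)
    return out


_ATOM_ORDER = ["N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "OG", "OG1",
               "SG", "CD", "CD1", "CD2", "OD1", "OD2", "ND1", "ND2", "SD",
               "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
               "CZ", "CZ2", "CZ3", "NZ", "CH2", "NH1", "NH2", "OH"]


def _residue_atoms(coords: dict[str, np.ndarray], resname3: str, number: int,
                   chain_id: str, serial_start: int) -> list[Atom]:
    atoms = []
    serial = serial_start
    for name in _ATOM_ORDER:
        if name in coords:
            atoms.append(Atom(serial=serial, name=name, element=element_of(name),
                              residue_name=resname3, residue_number=number,
                              insertion_code="", chain_id=chain_id, altloc="",
                              coords=np.asarray(coords[name], dtype=float)))
            serial += 1
    return atoms


def make_toy_structure(
    kind: str,
    n_residues: int,
    sequence: str | None = None,
    seed: int = 0,
    chain_id: str = "A",
) -> Structure:
    """Deterministic synthetic structures for testing and examples.

    kind:
      - 'ideal_helix': canonical α-helix torsions (φ=-57°, ψ=-47°;
        rise ≈ 1.5 Å, ≈ 100°/residue).
      - 'extended_chain': β-strand-like torsions giving ~3.8 Å Cα spacing
        along an axis.
      - 'cluster': compact cubic lattice of rigid idealized residues with
        seeded Gaussian positional noise and random orientations.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    for aa in sequence:
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown amino acid {aa!r} in sequence")

    atoms: list[Atom] = []
    if kind == "ideal_helix" or kind == "extended_chain":
        phi, psi = (-57.0, -47.0) if kind == "ideal_helix" else (-140.0, 145.0)
        backbone = _build_backbone(n_residues, phi, psi)
        serial = 1
        for i, (bb, aa) in enumerate(zip(backbone, sequence), start=1):
            resname3 = ONE_TO_THREE[aa]
            coords = _add_sidechain(bb, resname3)
            res_atoms = _residue_atoms(coords, resname3, i, chain_id, serial)
            serial += len(res_atoms)
            atoms.extend(res_atoms)
    elif kind == "cluster":
        rng = np.random.default_rng(seed)
        side = int(np.ceil(n_residues ** (1.0 / 3.0)))
        spacing = 5.5
        lattice = []
        for ix in range(side):
            for iy in range(side):
                for iz in range(side):
                    lattice.append(np.array([ix, iy, iz], dtype=float) * spacing)
        lattice = lattice[:n_residues]
        # order lattice points by distance to the centroid so that low
        # residue numbers are the most buried (useful for burial fixtures)
        center = np.mean(lattice, axis=0)
        lattice.sort(key=lambda p: float(np.linalg.norm(p - center)))
        serial = 1
        for i, aa in enumerate(sequence):
            resname3 = ONE_TO_THREE[aa]
            bb = _build_backbone(1, -57.0, -47.0)[0]
            coords = _add_sidechain(bb, resname3)
            names = list(coords)
            pts = np.array([coords[n] for n in names])
            pts -= pts.mean(axis=0)
            # seeded random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            pts = pts @ q.T
            origin = lattice[i] + rng.normal(scale=0.3, size=3)
            coords = {n: pts[j] + origin for j, n in enumerate(names)}
            res_atoms = _residue_atoms(coords, resname3, i + 1, chain_id, serial)
            serial += len(res_atoms)
            atoms.extend(res_atoms)
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")

    return Structure(atoms=atoms, model_id=1, name=f"toy-{kind}")
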