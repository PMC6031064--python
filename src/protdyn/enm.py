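"""Elastic-network models at Cα resolution and their normal modes.

Two force fields are provided:

* ``anm`` — the anisotropic network model: a uniform spring of constant
  gamma between every pair of sites closer than a cutoff.
* ``encom`` — a sequence-dependent variant: stretch/angle/dihedral terms
  along the Cα trace plus a long-range pair term whose force constant is
  modulated by the number of heavy-atom contacts between the two residues,
  weighted by an element-pair interaction matrix. This makes the network
  sensitive to side-chain identity, which is what lets a point mutation
  change the vibrational spectrum.

Every bonded term is harmonic in an internal coordinate q with its rest
value taken from the input geometry, so the input structure is an exact
energy minimum and the Hessian contribution is k · ∇q ∇qᵀ (the q·∇²q term
vanishes at q = 0). This keeps translational invariance exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from ._geometry import angle_gradients, dihedral_gradients
from .structure import CoarseModel, Structure

__all__ = [
    "Hessian",
    "NormalModeSet",
    "EncomParams",
    "build_anm_hessian",
    "build_encom_hessian",
    "solve_modes",
    "count_trivial_modes",
]


@dataclass
class Spring:
    i: int
    j: int
    rest_length: float
    force_constant: float


@dataclass
class Hessian:
    matrix: np.ndarray
    model: CoarseModel
    springs: list[Spring]
    forcefield_name: str
    warnings: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.model)


@dataclass
class NormalModeSet:
    """Eigen-decomposition of a (mass-weighted) ENM Hessian.

    eigenvalues are ascending; eigenvectors are orthonormal columns in
    mass-weighted coordinates. The first ``n_trivial`` modes are the
    rigid-body (zero-frequency) modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    masses: np.ndarray
    n_trivial: int
    mass_weighted: bool
    forcefield_name: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.masses)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def nontrivial_indices(self) -> np.ndarray:
        return np.arange(self.n_trivial, self.n_modes)

    @property
    def frequencies(self) -> np.ndarray:
        """ν_k ∝ sqrt(λ_k) for the non-trivial modes."""
        lam = self.eigenvalues[self.n_trivial:]
        return np.sqrt(np.clip(lam, 0.0, None))

    def displacement(self, mode_index: int) -> np.ndarray:
        """Cartesian per-site displacement (N, 3) of one mode, undoing the
        mass weighting."""
        vec = self.eigenvectors[:, mode_index].reshape(-1, 3)
        if self.mass_weighted:
            vec = vec / np.sqrt(self.masses)[:, None]
        return vec


@dataclass
class EncomParams:
    """Parameters of the sequence-dependent force field.

    Bonded constants follow the common coarse-grained Go-like weighting
    (stretch ≫ angle ≫ dihedral); the long-range pair constant is
    k_longrange · (base_weight + weight_scale · w_ij) where w_ij sums the
    element-pair weights over heavy-atom contacts closer than
    contact_distance. All values are configurable.
    """

    k_stretch: float = 100.0
    k_angle: float = 20.0
    k_dihedral: float = 1.0
    k_longrange: float = 1.0
    base_weight: float = 1.0
    weight_scale: float = 1.0
    contact_distance: float = 4.5
    longrange_cutoff: float = 18.0
    min_sequence_separation: int = 3
    interaction_matrix: dict = field(default_factory=lambda: dict(_DEFAULT_EPS))


# Element-pair contact weights (symmetric, keyed by frozenset of elements).
_DEFAULT_EPS = {
    frozenset(["C"]): 1.0,
    frozenset(["C", "N"]): 1.1,
    frozenset(["C", "O"]): 1.1,
    frozenset(["C", "S"]): 1.2,
    frozenset(["N"]): 1.2,
    frozenset(["N", "O"]): 1.3,
    frozenset(["N", "S"]): 1.1,
    frozenset(["O"]): 1.2,
    frozenset(["O", "S"]): 1.1,
    frozenset(["S"]): 1.3,
}


def _add_pair_superelement(h: np.ndarray, i: int, j: int, rhat: np.ndarray,
                           k: float) -> None:
    """Accumulate the ANM super-element −k·r̂r̂ᵀ at (i, j) plus diagonal."""
    block = k * np.outer(rhat, rhat)
    sl_i = slice(3 * i, 3 * i + 3)
    sl_j = slice(3 * j, 3 * j + 3)
    h[sl_i, sl_j] -= block
    h[sl_j, sl_i] -= block
    h[sl_i, sl_i] += block
    h[sl_j, sl_j] += block


def _add_gradient_term(h: np.ndarray, indices: list[int],
                       grads: list[np.ndarray], k: float) -> None:
    """Accumulate k · g gᵀ for an internal coordinate with gradient g."""
    n3 = h.shape[0]
    g = np.zeros(n3)
    for idx, gi in zip(indices, grads):
        g[3 * idx: 3 * idx + 3] += gi
    h += k * np.outer(g, g)


def _connectivity_warning(n: int, springs: list[Spring]) -> list[str]:
    if not springs:
        return [f"network has no springs ({n} isolated sites)"]
    rows = [s.i for s in springs] + [s.j for s in springs]
    cols = [s.j for s in springs] + [s.i for s in springs]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        return [f"network is disconnected: {n_comp} components"]
    return []


def build_anm_hessian(model: CoarseModel, cutoff: float = 15.0,
                      gamma: float = 1.0) -> Hessian:
    """Cutoff-based anisotropic network model Hessian.

    A spring of constant gamma joins every site pair at distance ≤ cutoff;
    the off-diagonal 3×3 block of pair (i, j) is −γ·r̂r̂ᵀ and diagonal
    blocks make every row-block sum to zero.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(model)
    coords = model.coords()
    h = np.zeros((3 * n, 3 * n))
    springs: list[Spring] = []
    dists = squareform(pdist(coords))
    for i in range(n):
        for j in range(i + 1, n):
            d = dists[i, j]
            if d <= cutoff and d > 0:
                rhat = (coords[j] - coords[i]) / d
                _add_pair_superelement(h, i, j, rhat, gamma)
                springs.append(Spring(i, j, d, gamma))
    warnings = _connectivity_warning(n, springs)
    return Hessian(matrix=h, model=model, springs=springs,
                   forcefield_name="anm", warnings=warnings)


def _chain_runs(model: CoarseModel) -> list[list[int]]:
    """Indices of consecutive sites grouped by chain (the Cα trace)."""
    runs: list[list[int]] = []
    current: list[int] = []
    prev_chain = None
    for i, s in enumerate(model.sites):
        if s.chain_id != prev_chain:
            if current:
                runs.append(current)
            current = []
            prev_chain = s.chain_id
        current.append(i)
    if current:
        runs.append(current)
    return runs


def residue_contact_weights(structure: Structure, model: CoarseModel,
                            params: EncomParams) -> dict[tuple[int, int], float]:
    """w_ij: element-pair-weighted heavy-atom contact counts between the
    residues of each coarse site pair."""
    site_of = {}
    for idx, s in enumerate(model.sites):
        site_of[(s.chain_id, s.residue_number, s.insertion_code.strip())] = idx
    atom_site = []
    atom_coords = []
    atom_elem = []
    for a in structure.atoms:
        if a.element == "H":
            continue
        key = (a.chain_id, a.residue_number, a.insertion_code.strip())
        idx = site_of.get(key)
        if idx is None:
            continue
        atom_site.append(idx)
        atom_coords.append(a.coords)
        atom_elem.append("S" if a.element == "SE" else a.element)
    atom_coords = np.array(atom_coords)
    tree = cKDTree(atom_coords)
    pairs = tree.query_pairs(params.contact_distance)
    weights: dict[tuple[int, int], float] = {}
    eps = params.interaction_matrix
    for a, b in pairs:
        si, sj = atom_site[a], atom_site[b]
        if si == sj:
            continue
        key = (min(si, sj), max(si, sj))
        w = eps.get(frozenset([atom_elem[a], atom_elem[b]]), 1.0)
        weights[key] = weights.get(key, 0.0) + w
    return weights


def build_encom_hessian(structure: Structure, model: CoarseModel,
                        params: EncomParams | None = None) -> Hessian:
    """Sequence-dependent elastic network from an all-atom structure.

    Four harmonic terms: covalent-neighbour stretch, three-site angle and
    four-site dihedral terms along the Cα trace, plus a long-range
    ANM-style pair term with force constant
    k_longrange · (base_weight + weight_scale · w_ij), where w_ij counts
    heavy-atom contacts between residues i and j (≤ contact_distance)
    weighted by an element-pair interaction matrix.
    """
    if params is None:
        params = EncomParams()
    n = len(model)
    coords = model.coords()
    h = np.zeros((3 * n, 3 * n))
    springs: list[Spring] = []

    for run in _chain_runs(model):
        if params.k_stretch != 0.0:
            for a, b in zip(run, run[1:]):
                d = coords[b] - coords[a]
                ln = np.linalg.norm(d)
                rhat = d / ln
                _add_pair_superelement(h, a, b, rhat, params.k_stretch)
                springs.append(Spring(a, b, ln, params.k_stretch))
        if params.k_angle != 0.0:
            for a, b, c in zip(run, run[1:], run[2:]):
                grads = angle_gradients(coords[a], coords[b], coords[c])
                _add_gradient_term(h, [a, b, c], list(grads), params.k_angle)
        if params.k_dihedral != 0.0:
            for a, b, c, d in zip(run, run[1:], run[2:], run[3:]):
                grads = dihedral_gradients(coords[a], coords[b], coords[c],
                                           coords[d])
                _add_gradient_term(h, [a, b, c, d], list(grads),
                                   params.k_dihedral)

    if params.k_longrange != 0.0:
        weights = residue_contact_weights(structure, model, params)
        seq_pos = {}
        for run_id, run in enumerate(_chain_runs(model)):
            for pos, idx in enumerate(run):
                seq_pos[idx] = (run_id, pos)
        dists = squareform(pdist(coords))
        for i in range(n):
            for j in range(i + 1, n):
                ri, pi = seq_pos[i]
                rj, pj = seq_pos[j]
                if ri == rj and abs(pi - pj) < params.min_sequence_separation:
                    continue
                d = dists[i, j]
                if d > params.longrange_cutoff or d == 0:
                    continue
                w = weights.get((i, j), 0.0)
                k = params.k_longrange * (params.base_weight
                                          + params.weight_scale * w)
                if k == 0.0:
                    continue
                rhat = (coords[j] - coords[i]) / d
                _add_pair_superelement(h, i, j, rhat, k)
                springs.append(Spring(i, j, d, k))

    warnings = _connectivity_warning(n, springs)
    return Hessian(matrix=h, model=model, springs=springs,
                   forcefield_name="encom", warnings=warnings)


def _is_collinear(coords: np.ndarray, tol: float = 1e-8) -> bool:
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[1] <= tol * max(sv[0], 1.0)


def solve_modes(hessian: Hessian, mass_weighting: bool = True,
                trivial_tol: float = 1e-8) -> NormalModeSet:
    """Solve the (mass-weighted) symmetric eigenproblem of an ENM Hessian.

    Trivial (rigid-body) modes are identified by |λ| ≤ trivial_tol·max(λ)
    with a floor of 6 for non-collinear connected networks (5 for collinear
    site sets); disconnected networks yield more. Eigenvector signs are
    fixed by making each column's largest-magnitude component positive.
    """
    h = hessian.matrix
    scale = max(np.abs(h).max(), 1.0)
    if np.abs(h - h.T).max() > 1e-8 * scale:
        raise ValueError("Hessian is not symmetric within tolerance")
    masses = hessian.model.masses()
    if mass_weighting:
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
        hw = h * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    else:
        hw = h
        masses = np.ones_like(masses)
    hw = 0.5 * (hw + hw.T)
    eigenvalues, eigenvectors = linalg.eigh(hw)

    # sign convention: largest-|component| positive
    for k in range(eigenvectors.shape[1]):
        col = eigenvectors[:, k]
        imax = np.argmax(np.abs(col))
        if col[imax] < 0:
            eigenvectors[:, k] = -col

    lam_max = eigenvalues[-1] if eigenvalues.size else 0.0
    if lam_max <= 0:
        n_trivial = len(eigenvalues)
    else:
        near_zero = int(np.sum(eigenvalues <= trivial_tol * lam_max))
        floor = 5 if _is_collinear(hessian.model.coords()) else 6
        n_trivial = min(max(near_zero, floor), len(eigenvalues))

    return NormalModeSet(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                         masses=masses, n_trivial=n_trivial,
                         mass_weighted=mass_weighting,
                         forcefield_name=hessian.forcefield_name)


def count_trivial_modes(modes: NormalModeSet) -> int:
    """Number of zero-frequency rigid-body modes (6; 5 for collinear sets;
    more for disconnected networks)."""
    return modes.n_trivial
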