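"""Mode-derived analyses: fluctuations, cross-correlations, deformation
energy, porcupine vectors, vibrational entropy and mutation ΔΔS/ΔΔG.

All quantities are computed from a NormalModeSet over its non-trivial modes.
The vibrational entropy uses the classical harmonic-oscillator limit
S = −k_B Σ ln ν_k + const; the additive constant is shared by systems with
equal mode counts and cancels in every reported difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enm import (EncomParams, Hessian, NormalModeSet, build_anm_hessian,
                  build_encom_hessian, solve_modes)
from .structure import (CoarseModel, MutationSpec, Structure, build_mutant,
                        extract_coarse_grain)

__all__ = [
    "KB_KCAL",
    "EntropyResult",
    "MutationDynamicsResult",
    "mean_square_fluctuations",
    "cross_correlation",
    "deformation_energy",
    "deformation_energy_of_displacement",
    "porcupine_vectors",
    "vibrational_entropy",
    "mutation_dynamics",
]

# Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872

T_STANDARD = 298.15


@dataclass
class EntropyResult:
    """Vibrational entropy in kcal/mol/K, defined up to an additive constant
    shared between systems with the same number of non-trivial modes."""

    s_vib: float
    n_modes_used: int


@dataclass
class MutationDynamicsResult:
    dds_vib: float          # S_vib(mutant) - S_vib(wild type), kcal/mol/K
    enm_ddg: float          # -alpha * T * dds_vib, kcal/mol
    msf_ratio_site: float   # mutant/wild-type fluctuation at the mutated site
    forcefield: str = ""
    details: dict = field(default_factory=dict)


def _selected_modes(modes: NormalModeSet, n_modes: int | None):
    """Indices of the non-trivial modes to use (clipped with a warning)."""
    avail = modes.n_modes - modes.n_trivial
    if avail < 1:
        raise ValueError("no non-trivial modes available")
    if n_modes is None or n_modes > avail:
        n_modes = avail
    return np.arange(modes.n_trivial, modes.n_trivial + n_modes)


def mean_square_fluctuations(modes: NormalModeSet,
                             n_modes: int | None = None) -> np.ndarray:
    """Per-site mean-square fluctuation msf_i = Σ_k |u_k,i|² / λ_k over the
    selected non-trivial modes, with displacements mapped back from
    mass-weighted coordinates (uniform k_B·T scale omitted)."""
    sel = _selected_modes(modes, n_modes)
    lam = modes.eigenvalues[sel]
    vecs = modes.eigenvectors[:, sel].reshape(modes.n_sites, 3, -1)
    per_site = np.sum(vecs ** 2, axis=1)          # (N, K)
    msf = per_site @ (1.0 / lam)
    if modes.mass_weighted:
        msf = msf / modes.masses
    return msf


def cross_correlation(modes: NormalModeSet,
                      n_modes: int | None = None) -> np.ndarray:
    """Normalized residue motion cross-correlation matrix.

    C_ij = cov_ij / sqrt(cov_ii · cov_jj) with
    cov_ij = Σ_k (1/λ_k) u_k,i · u_k,j over the selected modes. Sites with
    zero variance get NaN rows/columns.
    """
    sel = _selected_modes(modes, n_modes)
    lam = modes.eigenvalues[sel]
    n = modes.n_sites
    vecs = modes.eigenvectors[:, sel].reshape(n, 3, -1)
    if modes.mass_weighted:
        vecs = vecs / np.sqrt(modes.masses)[:, None, None]
    weighted = vecs / lam[None, None, :]
    cov = np.einsum("iak,jak->ij", weighted, vecs)
    var = np.diag(cov).copy()
    bad = var <= 0
    var[bad] = 1.0
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, np.where(bad, np.nan, 1.0))
    return corr


def deformation_energy_of_displacement(hessian: Hessian,
                                       displacement: np.ndarray) -> np.ndarray:
    """Per-site elastic energy of an arbitrary Cartesian displacement field:
    ½·k·(Δlength)² per spring, split half to each endpoint. Rigid-body
    fields give identically zero."""
    disp = np.asarray(displacement, dtype=float)
    n = hessian.n_sites
    if disp.shape != (n, 3):
        raise ValueError(f"displacement shape {disp.shape} != ({n}, 3)")
    coords = hessian.model.coords()
    energy = np.zeros(n)
    for s in hessian.springs:
        r = coords[s.j] - coords[s.i]
        rhat = r / np.linalg.norm(r)
        dl = float(rhat @ (disp[s.j] - disp[s.i]))
        e = 0.5 * s.force_constant * dl * dl
        energy[s.i] += 0.5 * e
        energy[s.j] += 0.5 * e
    return energy


def deformation_energy(modes: NormalModeSet, hessian: Hessian,
                       mode_index: int) -> np.ndarray:
    """Per-site deformation energy of one non-trivial mode, normalized to
    sum to 1 (relative scale)."""
    if mode_index < modes.n_trivial:
        raise ValueError(
            f"mode {mode_index} is trivial (n_trivial={modes.n_trivial})"
        )
    disp = modes.displacement(mode_index)
    energy = deformation_energy_of_displacement(hessian, disp)
    total = energy.sum()
    if total > 0:
        energy = energy / total
    return energy


def porcupine_vectors(modes: NormalModeSet, mode_index: int | None = None,
                      scale: float = 1.0) -> np.ndarray:
    """Per-site displacement arrows of one mode (default: first non-trivial),
    scaled so the largest vector norm equals ``scale``."""
    if mode_index is None:
        mode_index = modes.n_trivial
    disp = modes.displacement(mode_index)
    norms = np.linalg.norm(disp, axis=1)
    mx = norms.max()
    if mx > 0:
        disp = disp * (scale / mx)
    return disp


def vibrational_entropy(modes: NormalModeSet) -> EntropyResult:
    """Classical-limit vibrational entropy S = −k_B Σ_k ln ν_k over the
    non-trivial modes, ν_k = sqrt(λ_k), in kcal/mol/K up to an additive
    constant."""
    lam = modes.eigenvalues[modes.n_trivial:]
    if lam.size < 1:
        raise ValueError("no non-trivial modes")
    if np.any(lam <= 0):
        raise ValueError(
            "non-positive eigenvalue among non-trivial modes; "
            "trivial-mode classification looks wrong"
        )
    s = -KB_KCAL * float(np.sum(np.log(np.sqrt(lam))))
    return EntropyResult(s_vib=s, n_modes_used=int(lam.size))


def _build_hessian(structure: Structure, model: CoarseModel, forcefield: str,
                   anm_cutoff: float = 15.0, anm_gamma: float = 1.0,
                   encom_params: EncomParams | None = None) -> Hessian:
    if forcefield == "anm":
        return build_anm_hessian(model, cutoff=anm_cutoff, gamma=anm_gamma)
    if forcefield == "encom":
        return build_encom_hessian(structure, model, encom_params)
    raise ValueError(f"unknown forcefield {forcefield!r}; use 'anm' or 'encom'")


def mutation_dynamics(
    wt: Structure,
    mutation: MutationSpec,
    forcefield: str = "encom",
    mut: Structure | None = None,
    alpha: float = 1.0,
    temperature: float = T_STANDARD,
    mass_scheme: str = "residue",
    anm_cutoff: float = 15.0,
    anm_gamma: float = 1.0,
    encom_params: EncomParams | None = None,
) -> MutationDynamicsResult:
    """Vibrational-entropy impact of a point mutation.

    Builds the mutant by idealized side-chain replacement when not supplied,
    constructs wild-type and mutant Hessians with identical parameters,
    solves both eigenproblems and returns ΔΔS_vib = S_mut − S_wt, an
    ENM stability estimate ΔΔG = −α·T·ΔΔS (positive = stabilizing), and the
    mutant/wild-type fluctuation ratio at the mutated site.
    """
    if mut is None:
        mut = build_mutant(wt, mutation)
    cm_wt = extract_coarse_grain(wt, mass_scheme=mass_scheme)
    cm_mut = extract_coarse_grain(mut, mass_scheme=mass_scheme)
    if len(cm_wt) != len(cm_mut):
        raise ValueError(
            f"site count mismatch: wild-type {len(cm_wt)} vs mutant "
            f"{len(cm_mut)} (a point mutation must not add/remove residues)"
        )
    kwargs = dict(anm_cutoff=anm_cutoff, anm_gamma=anm_gamma,
                  encom_params=encom_params)
    h_wt = _build_hessian(wt, cm_wt, forcefield, **kwargs)
    h_mut = _build_hessian(mut, cm_mut, forcefield, **kwargs)
    m_wt = solve_modes(h_wt)
    m_mut = solve_modes(h_mut)
    s_wt = vibrational_entropy(m_wt)
    s_mut = vibrational_entropy(m_mut)
    if s_wt.n_modes_used != s_mut.n_modes_used:
        raise ValueError(
            f"mode count mismatch: wild-type {s_wt.n_modes_used} vs mutant "
            f"{s_mut.n_modes_used} non-trivial modes"
        )
    dds = s_mut.s_vib - s_wt.s_vib
    site = cm_wt.site_index(mutation.chain_id, mutation.residue_number,
                            mutation.insertion_code)
    msf_wt = mean_square_fluctuations(m_wt)
    msf_mut = mean_square_fluctuations(m_mut)
    ratio = float(msf_mut[site] / msf_wt[site])
    return MutationDynamicsResult(
        dds_vib=dds,
        enm_ddg=-alpha * temperature * dds,
        msf_ratio_site=ratio,
        forcefield=forcefield,
        details={
            "s_vib_wt": s_wt.s_vib,
            "s_vib_mut": s_mut.s_vib,
            "n_modes": s_wt.n_modes_used,
            "site_index": site,
        },
    )
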