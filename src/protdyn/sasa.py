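"""Deterministic solvent-accessible surface area (Shrake–Rupley with a fixed
Fibonacci sphere point set) and accessible-surface dot extraction."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .residues import DEFAULT_VDW, VDW_RADII

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 128


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(elements: list[str]) -> np.ndarray:
    return np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])


def shrake_rupley(
    coords: np.ndarray,
    elements: list[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    return_surface_dots: bool = False,
):
    """Per-atom SASA (Å²); optionally also the accessible vdW-surface dots.

    Accessibility of each sample direction is tested on the probe-expanded
    sphere; returned dots sit on the van der Waals surface so that distances
    to them measure burial depth directly.
    """
    coords = np.asarray(coords, dtype=float)
    m = len(coords)
    radii = atom_radii(elements)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = radii.max() + probe
    areas = np.zeros(m)
    dots: list[np.ndarray] = []
    for i in range(m):
        ri = radii[i] + probe
        test_pts = coords[i] + ri * sphere
        neigh = tree.query_ball_point(coords[i], ri + max_reach)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)] + probe
            d2 = ((test_pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
        else:
            buried = np.zeros(n_points, dtype=bool)
        frac = 1.0 - buried.mean()
        areas[i] = 4.0 * np.pi * ri * ri * frac
        if return_surface_dots and not buried.all():
            dots.append(coords[i] + radii[i] * sphere[~buried])
    if return_surface_dots:
        surface = np.vstack(dots) if dots else np.empty((0, 3))
        return areas, surface
    return areas
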