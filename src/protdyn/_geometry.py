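"""Small internal-coordinate geometry kernel (NeRF placement, torsions)."""

from __future__ import annotations

import numpy as np


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Position atom D given atoms A-B-C, the C-D bond length, the B-C-D
    angle and the A-B-C-D dihedral (natural extension reference frame)."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle A-B-C in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral A-B-C-D in degrees (IUPAC convention)."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def angle_gradients(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Gradients of the A-B-C angle (radians) w.r.t. the three positions.

    Returned gradients sum to zero (translation invariance) and are
    perpendicular to the overall rotation only in the harmonic sense.
    """
    u = a - b
    v = c - b
    lu = np.linalg.norm(u)
    lv = np.linalg.norm(v)
    uh = u / lu
    vh = v / lv
    cos_t = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
    ga = (cos_t * uh - vh) / (lu * sin_t)
    gc = (cos_t * vh - uh) / (lv * sin_t)
    gb = -(ga + gc)
    return ga, gb, gc


def dihedral_gradients(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Gradients of the A-B-C-D dihedral (radians) w.r.t. the four positions."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    ga = (lb2 / n1sq) * n1
    gd = -(lb2 / n2sq) * n2
    s12 = np.dot(b1, b2) / (lb2 * lb2)
    s32 = np.dot(b3, b2) / (lb2 * lb2)
    gb = -(1.0 + s12) * ga + s32 * gd
    gc = s12 * ga - (1.0 + s32) * gd
    return ga, gb, gc, gd
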