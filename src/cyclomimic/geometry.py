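"""Low-level vector geometry used throughout the package.

Everything here operates on plain ``numpy`` arrays of Cartesian coordinates
in Angstrom.  The analytic dihedral/angle gradients are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "nerf_place",
    "bond_lengths",
    "bond_angles",
    "dihedrals",
    "dihedral_gradients",
    "angle_gradients",
    "rotate_about_axis",
]

_EPS = 1e-12


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D bonded to ``c`` using internal coordinates.

    Natural extension reference frame: ``r`` is the C-D bond length (A),
    ``theta`` the B-C-D angle (rad) and ``phi`` the A-B-C-D dihedral (rad).
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        # a,b,c collinear: pick any perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < _EPS:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    # local displacement: bond along bc flipped by the angle
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        -r * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_lengths(x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def bond_angles(x: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angles i-j-k in radians for an (m, 3) index array."""
    u = x[triples[:, 0]] - x[triples[:, 1]]
    v = x[triples[:, 2]] - x[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(c, -1.0, 1.0))


def dihedrals(x: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (rad) for an (m, 4) index array."""
    p0, p1, p2, p3 = (x[quads[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / np.maximum(b2n, _EPS)[:, None])
    xx = np.einsum("ij,ij->i", n1, n2)
    yy = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(yy, xx)


def dihedral_gradients(x: np.ndarray, quads: np.ndarray):
    """Return (phi, dphi) with dphi of shape (m, 4, 3).

    Standard rigid-rotation-consistent gradient of the signed dihedral with
    respect to each of the four atom positions.
    """
    p0, p1, p2, p3 = (x[quads[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), _EPS)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), _EPS)

    m1 = np.cross(n1, b2 / b2n[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                     np.einsum("ij,ij->i", n1, n2))

    g0 = (b2n / n1sq)[:, None] * n1
    g3 = -(b2n / n2sq)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1.0 + s32) * g3
    return phi, np.stack([g0, g1, g2, g3], axis=1)


def angle_gradients(x: np.ndarray, triples: np.ndarray):
    """Return (theta, dtheta) with dtheta of shape (m, 3, 3)."""
    u = x[triples[:, 0]] - x[triples[:, 1]]
    v = x[triples[:, 2]] - x[triples[:, 1]]
    nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.maximum(np.sqrt(1.0 - c ** 2), 1e-8)
    gi = (c[:, None] * uh - vh) / (nu * s)[:, None]
    gk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    gj = -(gi + gk)
    return theta, np.stack([gi, gj, gk], axis=1)


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``coords`` about a line through ``origin``."""
    k = axis / np.linalg.norm(axis)
    v = coords - origin
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    rotated = (v * cos_a
               + np.cross(k, v) * sin_a
               + np.outer(v @ k, k) * (1.0 - cos_a))
    return rotated + origin
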