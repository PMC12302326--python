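"""Small geometry toolkit: internal-coordinate atom placement, angles, rotations."""

from __future__ import annotations

import numpy as np


def place_atom(pa, pb, pc, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D from reference atoms A, B, C (natural extension frame).

    ``bond`` is |C-D| in Å, ``angle`` the B-C-D angle and ``torsion`` the
    A-B-C-D dihedral, both in degrees.
    """
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bcx, bcy, bcz = pc[0] - pb[0], pc[1] - pb[1], pc[2] - pb[2]
    inv = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * np.cos(theta)
    d1 = bond * np.sin(theta) * np.cos(phi)
    d2 = bond * np.sin(theta) * np.sin(phi)
    return np.array([
        pc[0] + d0 * bcx + d1 * mx + d2 * nx,
        pc[1] + d0 * bcy + d1 * my + d2 * ny,
        pc[2] + d0 * bcz + d1 * mz + d2 * nz,
    ])


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_point_in_sphere(center, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random point in a sphere of given radius around ``center``."""
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(p, p) <= 1.0:
            return np.asarray(center) + radius * p
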