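"""Low-level vector geometry: internal-coordinate atom placement, dihedrals,
reference frames and rigid superposition.

All routines are vectorized over a leading batch dimension so the kinematics
solvers can evaluate many chains at once. Coordinates are in Angstrom, angles
in radians.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(v * v, axis=-1, keepdims=True))


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / _norm(v)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Component-wise cross product; avoids np.cross's axis bookkeeping."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def place_atom(a, b, c, bond, angle, dihedral):
    """Place atom D given three reference atoms using internal coordinates.

    D is positioned so that |C-D| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral (IUPAC sign convention). Inputs may carry
    arbitrary leading batch dimensions; ``bond``/``angle``/``dihedral`` are
    scalars or arrays broadcastable to those batch dimensions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bond = np.asarray(bond, dtype=float)
    angle = np.asarray(angle, dtype=float)
    dihedral = np.asarray(dihedral, dtype=float)

    bc = _unit(c - b)
    n = _unit(_cross(b - a, bc))
    m = _cross(n, bc)
    sa = np.sin(angle)
    x = (-bond * np.cos(angle))[..., None]
    y = (bond * sa * np.cos(dihedral))[..., None]
    z = (bond * sa * np.sin(dihedral))[..., None]
    return c + x * bc + y * m + z * n


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral angle of four points (batched), IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m1 = _cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return -np.arctan2(y, x)


def bond_angle(a, b, c):
    """Angle at vertex b (batched)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = _unit(a - b)
    v = _unit(c - b)
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.arccos(cosang)


def frame_from_atoms(origin, p1, p2):
    """Right-handed orthonormal frame from an origin and two directions.

    Column 0 is the unit vector origin->p1; column 1 the Gram-Schmidt
    orthogonalized origin->p2 direction; column 2 their cross product.
    Batched over leading dimensions; returns (R, origin) with R columns the
    frame axes.

    Raises ValueError for degenerate (collinear) geometry.
    """
    origin = np.asarray(origin, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    e1 = _unit(p1 - origin)
    a = p2 - origin
    a_perp = a - np.sum(a * e1, axis=-1, keepdims=True) * e1
    norms = np.linalg.norm(a_perp, axis=-1)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate frame: reference atoms are collinear")
    e2 = a_perp / norms[..., None]
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=-1)
    return R, origin


def to_local(R, origin, points):
    """World -> frame-local coordinates."""
    return (np.asarray(points) - origin) @ R


def to_world(R, origin, local):
    """Frame-local -> world coordinates. Batched over leading dims of R."""
    return np.einsum("...ij,...kj->...ki", R, np.asarray(local)) + origin[..., None, :]


def rotation_error(R_a: np.ndarray, R_b: np.ndarray) -> float:
    """Geodesic angle (rad) between two rotation matrices."""
    return float(
        Rotation.from_matrix(R_a.T @ R_b).magnitude()
    )


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares rigid superposition (Kabsch).

    Returns (R, t, transformed) such that ``mobile @ R.T + t`` best fits
    ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - cm @ R.T
    return R, t, mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unsuperposed) coordinate RMSD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of ``a`` onto ``b``."""
    if len(a) == 1:
        return 0.0
    _, _, moved = superpose(a, b)
    return rmsd(moved, b)


def random_rotation_small(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Rotation about a uniform random axis by an angle uniform in [0, max_angle]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform random point in a ball of given radius."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return r * v
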