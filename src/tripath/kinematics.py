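"""6R inverse kinematics between consecutive particle frames and all-atom
backbone reconstruction from a coarse state.

With the particle frame attached at a residue's N atom (triad from N->CA and
N->C), a tripeptide's base frame fixes N, CA and C of its first residue, and
the next particle fixes N, CA and C of the following tripeptide's first
residue. The six free torsions of the closure problem are therefore

    (psi_r, phi_{r+1}, psi_{r+1}, phi_{r+2}, psi_{r+2}, phi_{r+3})

for a tripeptide starting at residue r — six revolute axes, the classic 6R
chain with at most 16 discrete solutions.

Two solver routes are provided, both verified against forward kinematics:

* :func:`solve_ik` — enumeration. The problem is reduced analytically to
  three unknowns (the first and last torsion plus the rotation of the rigid
  middle peptide unit about its CA-CA axis); a batched multistart
  Levenberg-Marquardt over a torsion grid finds all roots, which are then
  deduplicated and verified.
* seeded polish — the planner fast path. Small interpolation steps keep the
  previous torsions an excellent initial guess; a batched Gauss-Newton on the
  full 6-torsion closure residual converges in a few iterations for every
  tripeptide simultaneously.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .internal import ChainGeometry
from .structure import (CoarseState, ProteinConformation,
                        decompose_tripeptides, frame_of_residue)
from .collision import (IncrementalClashChecker, StericModel, atom_radii,
                        backbone_exclusions)

#: closure tolerances: position (Angstrom) and orientation (rad)
POSITION_TOLERANCE = 1e-4
ORIENTATION_TOLERANCE = 1e-6
#: torsion-space deduplication resolution (rad)
DEDUP_TOLERANCE = 1e-3
#: default threshold for accepting the solution closest to the previous one
SOLUTION_THRESHOLD = 0.5
MAX_IK_SOLUTIONS = 16


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi


def _rotate_about(axis, angle, x):
    """Rodrigues rotation of x about unit axis (batched)."""
    angle = np.asarray(angle)[..., None]
    c = np.cos(angle)
    s = np.sin(angle)
    return (x * c + geometry._cross(axis, x) * s
            + axis * np.sum(axis * x, axis=-1, keepdims=True) * (1 - c))


def _axis_frame(u):
    """Right-handed orthonormal triad (u, e2, e3) on unit axis u (batched).

    The second axis is the lab z direction orthogonalized against u (lab x
    where u is nearly parallel to z), which keeps the construction smooth and
    well conditioned everywhere except a measure-zero flip set.
    """
    z = np.array([0.0, 0.0, 1.0])
    xhat = np.array([1.0, 0.0, 0.0])
    uz = np.abs(np.sum(u * z, axis=-1))
    ref = np.where(uz[..., None] < 0.9, z, xhat)
    e2 = ref - np.sum(ref * u, axis=-1, keepdims=True) * u
    e2 = e2 / np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = geometry._cross(u, e2)
    return e2, e3


# ---------------------------------------------------------------------------
# Per-tripeptide geometry
# ---------------------------------------------------------------------------

@dataclass
class TripeptideGeometry:
    """Frozen internal coordinates of one tripeptide's 6R segment.

    Covers residues r, r+1, r+2 and the closure onto residue r+3 (the next
    particle's residue). ``params`` maps names to length-3 arrays indexed by
    the position within the tripeptide.
    """

    base_ca_local: np.ndarray
    base_c_local: np.ndarray
    end_ca_local: np.ndarray
    end_c_local: np.ndarray
    b_cn: np.ndarray       # C(x)-N(x+1), x = r..r+2
    a_cacn: np.ndarray
    a_cnca: np.ndarray
    omega: np.ndarray
    b_nca: np.ndarray      # N-CA of residues r+1..r+3
    a_ncac: np.ndarray     # N-CA-C of residues r+1..r+3
    b_cac: np.ndarray      # CA-C of residues r+1..r+3
    b_co: np.ndarray       # O placement, residues r..r+2
    a_caco: np.ndarray
    d_o: np.ndarray

    def max_reach(self) -> float:
        """Loose upper bound on the base->end origin distance."""
        return float(np.sum(self.b_cn) + np.sum(self.b_nca) + np.sum(self.b_cac)
                     + np.linalg.norm(self.base_c_local))


def tripeptide_geometry(geom: ChainGeometry, start: int) -> TripeptideGeometry:
    """Extract the 6R segment geometry for the tripeptide starting at ``start``."""
    r = start
    sl = slice(r, r + 3)
    ca_b, c_b = geom.base_local_ca_c(r)
    ca_e, c_e = geom.base_local_ca_c(r + 3)
    return TripeptideGeometry(
        ca_b, c_b, ca_e, c_e,
        geom.b_cn[sl].copy(), geom.a_cacn[sl].copy(), geom.a_cnca[sl].copy(),
        geom.omega[sl].copy(),
        geom.b_nca[r + 1:r + 4].copy(), geom.a_ncac[r + 1:r + 4].copy(),
        geom.b_cac[r + 1:r + 4].copy(),
        geom.b_co[sl].copy(), geom.a_caco[sl].copy(), geom.d_o[sl].copy(),
    )


def _stack_params(geoms: list[TripeptideGeometry]) -> dict:
    keys = ("base_ca_local", "base_c_local", "end_ca_local", "end_c_local",
            "b_cn", "a_cacn", "a_cnca", "omega", "b_nca", "a_ncac", "b_cac",
            "b_co", "a_caco", "d_o")
    return {k: np.stack([getattr(g, k) for g in geoms]) for k in keys}


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _fk_atoms(torsions, base_R, base_o, prm):
    """Batched forward kinematics of the 6R segment.

    ``torsions`` has shape (..., 6); ``base_R`` (..., 3, 3); ``base_o``
    (..., 3); entries of ``prm`` broadcast against the batch shape. Returns a
    dict of atom positions, each (..., 3).
    """
    t = np.asarray(torsions, dtype=float)
    N1 = base_o
    CA1 = base_o + np.einsum("...ij,...j->...i", base_R, prm["base_ca_local"])
    C1 = base_o + np.einsum("...ij,...j->...i", base_R, prm["base_c_local"])

    N2 = geometry.place_atom(N1, CA1, C1, prm["b_cn"][..., 0],
                             prm["a_cacn"][..., 0], t[..., 0])
    O1 = geometry.place_atom(N2, CA1, C1, prm["b_co"][..., 0],
                             prm["a_caco"][..., 0], prm["d_o"][..., 0])
    CA2 = geometry.place_atom(CA1, C1, N2, prm["b_nca"][..., 0],
                              prm["a_cnca"][..., 0], prm["omega"][..., 0])
    C2 = geometry.place_atom(C1, N2, CA2, prm["b_cac"][..., 0],
                             prm["a_ncac"][..., 0], t[..., 1])
    N3 = geometry.place_atom(N2, CA2, C2, prm["b_cn"][..., 1],
                             prm["a_cacn"][..., 1], t[..., 2])
    O2 = geometry.place_atom(N3, CA2, C2, prm["b_co"][..., 1],
                             prm["a_caco"][..., 1], prm["d_o"][..., 1])
    CA3 = geometry.place_atom(CA2, C2, N3, prm["b_nca"][..., 1],
                              prm["a_cnca"][..., 1], prm["omega"][..., 1])
    C3 = geometry.place_atom(C2, N3, CA3, prm["b_cac"][..., 1],
                             prm["a_ncac"][..., 1], t[..., 3])
    N4 = geometry.place_atom(N3, CA3, C3, prm["b_cn"][..., 2],
                             prm["a_cacn"][..., 2], t[..., 4])
    O3 = geometry.place_atom(N4, CA3, C3, prm["b_co"][..., 2],
                             prm["a_caco"][..., 2], prm["d_o"][..., 2])
    CA4 = geometry.place_atom(CA3, C3, N4, prm["b_nca"][..., 2],
                              prm["a_cnca"][..., 2], prm["omega"][..., 2])
    C4 = geometry.place_atom(C3, N4, CA4, prm["b_cac"][..., 2],
                             prm["a_ncac"][..., 2], t[..., 5])
    return {"N1": N1, "CA1": CA1, "C1": C1, "O1": O1,
            "N2": N2, "CA2": CA2, "C2": C2, "O2": O2,
            "N3": N3, "CA3": CA3, "C3": C3, "O3": O3,
            "N4": N4, "CA4": CA4, "C4": C4}


def forward_kinematics(geom: TripeptideGeometry, torsions, base_rotation,
                       base_origin):
    """Build one tripeptide segment; returns (atoms dict, (end_R, end_origin)).

    The end frame is the particle frame of the next tripeptide's first
    residue, computed from the placed N4, CA4, C4 atoms.
    """
    prm = {k: np.asarray(getattr(geom, k)) for k in (
        "base_ca_local", "base_c_local", "b_cn", "a_cacn", "a_cnca", "omega",
        "b_nca", "a_ncac", "b_cac", "b_co", "a_caco", "d_o")}
    atoms = _fk_atoms(np.asarray(torsions, dtype=float),
                      np.asarray(base_rotation, dtype=float),
                      np.asarray(base_origin, dtype=float), prm)
    end_R, end_o = geometry.frame_from_atoms(atoms["N4"], atoms["CA4"],
                                             atoms["C4"])
    return atoms, (end_R, end_o)


def closure_error(geom: TripeptideGeometry, torsions, base_rotation,
                  base_origin, end_rotation, end_origin):
    """(position, orientation) error of a torsion vector against an end frame."""
    _, (R, o) = forward_kinematics(geom, torsions, base_rotation, base_origin)
    return (float(np.linalg.norm(o - end_origin)),
            geometry.rotation_error(R, np.asarray(end_rotation)))


# ---------------------------------------------------------------------------
# Seeded polish (batched Gauss-Newton on the 6-torsion closure residual)
# ---------------------------------------------------------------------------

def _end_targets(prm, end_R, end_o):
    """Target N4/CA4/C4 positions from the next particle frame (batched)."""
    n4 = end_o
    ca4 = end_o + np.einsum("...ij,...j->...i", end_R, prm["end_ca_local"])
    c4 = end_o + np.einsum("...ij,...j->...i", end_R, prm["end_c_local"])
    return n4, ca4, c4


def _residual6(t, base_R, base_o, prm, n4t, ca4t, c4t):
    a = _fk_atoms(t, base_R, base_o, prm)
    return np.concatenate([a["N4"] - n4t, a["CA4"] - ca4t, a["C4"] - c4t],
                          axis=-1)


def polish_ik(seeds, base_R, base_o, end_R, end_o, prm,
              max_iter: int = 40, tol: float = 1e-16):
    """Batched Gauss-Newton solve of m independent closure problems.

    ``seeds`` (m, 6); frames (m, 3, 3) / (m, 3). Returns (torsions (m, 6),
    converged (m,) bool, squared residual norms (m,)). ``tol`` is on the
    squared residual norm.
    """
    t = wrap_angle(np.array(seeds, dtype=float))
    m = t.shape[0]
    n4t, ca4t, c4t = _end_targets(prm, end_R, end_o)
    eps = 1e-7
    eye = np.eye(6)
    lam = np.full(m, 1e-8)
    r = _residual6(t, base_R, base_o, prm, n4t, ca4t, c4t)
    err = np.sum(r * r, axis=-1)
    stalled = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        active = (err > tol) & ~stalled
        if not np.any(active):
            break
        err_before = err.copy()
        # numeric Jacobian via forward differences, batched over a 7-wide axis
        t_batch = np.repeat(t[:, None, :], 7, axis=1)
        for d in range(6):
            t_batch[:, d + 1, d] += eps
        rb = _residual6(
            t_batch, base_R[:, None], base_o[:, None],
            {k: v[:, None] for k, v in prm.items()},
            n4t[:, None], ca4t[:, None], c4t[:, None])
        J = np.transpose((rb[:, 1:, :] - rb[:, :1, :]) / eps, (0, 2, 1))
        JtJ = J.transpose(0, 2, 1) @ J
        Jtr = np.einsum("mij,mi->mj", J, r)
        # adaptive damping: retry the step with stiffer lambda until the
        # residual decreases (vectorized over the batch)
        improved = ~active
        for _ in range(6):
            todo = ~improved
            if not np.any(todo):
                break
            A = JtJ + lam[:, None, None] * eye
            try:
                step = np.linalg.solve(A, Jtr[..., None])[..., 0]
            except np.linalg.LinAlgError:
                lam = np.where(todo, lam * 10.0, lam)
                continue
            t_try = np.where(todo[:, None], wrap_angle(t - step), t)
            r_try = _residual6(t_try, base_R, base_o, prm, n4t, ca4t, c4t)
            err_try = np.sum(r_try * r_try, axis=-1)
            good = todo & (err_try < err)
            t = np.where(good[:, None], t_try, t)
            r = np.where(good[:, None], r_try, r)
            err = np.where(good, err_try, err)
            lam = np.where(good, np.maximum(lam * 0.3, 1e-12),
                           np.where(todo, lam * 10.0, lam))
            improved |= good
        # rows at their least-squares minimum stop making progress; freeze
        # them so off-manifold targets do not burn the whole budget
        no_gain = active & (err_before - err <= 1e-3 * np.maximum(err, 1e-30))
        stalled |= no_gain
    converged = err <= tol
    return t, converged, err


# ---------------------------------------------------------------------------
# Enumerating solver: 3-variable reduction + multistart
# ---------------------------------------------------------------------------

@dataclass
class IKSolutionSet:
    torsions: np.ndarray             # (n_sol, 6)
    closure_residuals: np.ndarray    # (n_sol,) position error, Angstrom

    def __len__(self):
        return len(self.torsions)


def _middle_unit(geom: TripeptideGeometry):
    """Canonical coordinates of the rigid middle peptide unit.

    The unit {CA2, C2, N3, CA3} is rigid because the peptide torsion omega of
    the middle residue is frozen; its internal geometry fixes the CA2-CA3
    distance d_mid. Coordinates are canonicalized so CA2 sits at the origin
    and CA3 on the +x axis, which lets the unit be placed between two world
    anchor points by a single rotation angle about their connecting axis.
    """
    ca2 = np.zeros(3)
    c2 = np.array([geom.b_cac[0], 0.0, 0.0])
    n3 = geometry.place_atom(np.array([0.0, 1.0, 0.0]), ca2, c2,
                             geom.b_cn[1], geom.a_cacn[1], 0.0)
    ca3 = geometry.place_atom(ca2, c2, n3, geom.b_nca[1], geom.a_cnca[1],
                              geom.omega[1])
    d_mid = float(np.linalg.norm(ca3 - ca2))
    # rotate so ca3 lies on +x
    ex = ca3 / d_mid
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ey = ref - (ref @ ex) * ex
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    M = np.stack([ex, ey, ez])            # world->canonical rows
    return M @ c2, M @ n3, d_mid


def _reduced_residual(x, base_atoms, end_atoms, geom, mid):
    """Residual of the 3-variable closure system, batched over x (s, 3)."""
    t0 = x[..., 0]
    t1 = x[..., 1]
    alpha = x[..., 2]
    shape = x.shape[:-1] + (3,)
    N1, CA1, C1 = (np.broadcast_to(a, shape) for a in base_atoms)
    N4, CA4, C4 = (np.broadcast_to(a, shape) for a in end_atoms)

    N2 = geometry.place_atom(N1, CA1, C1, geom.b_cn[0], geom.a_cacn[0], t0)
    CA2 = geometry.place_atom(CA1, C1, N2, geom.b_nca[0], geom.a_cnca[0],
                              geom.omega[0])
    C3 = geometry.place_atom(C4, CA4, N4, geom.b_cn[2], geom.a_cnca[2], t1)
    CA3 = geometry.place_atom(CA4, N4, C3, geom.b_cac[1], geom.a_cacn[2],
                              geom.omega[2])

    c2u, n3u, d_mid = mid
    dvec = CA3 - CA2
    dist = np.linalg.norm(dvec, axis=-1)
    u = dvec / np.maximum(dist, 1e-12)[..., None]
    e2, e3 = _axis_frame(u)

    def _place(local):
        base = local[0] * u + local[1] * e2 + local[2] * e3
        return CA2 + _rotate_about(u, alpha, base)

    C2 = _place(c2u)
    N3 = _place(n3u)

    rho = np.stack([
        dist - d_mid,
        np.cos(geometry.bond_angle(N2, CA2, C2)) - np.cos(geom.a_ncac[0]),
        np.cos(geometry.bond_angle(N3, CA3, C3)) - np.cos(geom.a_ncac[1]),
    ], axis=-1)
    atoms = {"N2": N2, "CA2": CA2, "C2": C2, "N3": N3, "CA3": CA3, "C3": C3}
    return rho, atoms


def solve_ik(geom: TripeptideGeometry, base_rotation, base_origin,
             end_rotation, end_origin, n_grid: int = 6,
             position_tolerance: float = POSITION_TOLERANCE,
             orientation_tolerance: float = ORIENTATION_TOLERANCE
             ) -> IKSolutionSet:
    """Enumerate the 6R closure solutions between two particle frames.

    Multistart Levenberg-Marquardt over an ``n_grid``^3 torsion grid of the
    reduced 3-variable system; every candidate is verified against forward
    kinematics before being returned. An empty set means the end frame is
    unreachable.
    """
    base_R = np.asarray(base_rotation, dtype=float)
    base_o = np.asarray(base_origin, dtype=float)
    end_R = np.asarray(end_rotation, dtype=float)
    end_o = np.asarray(end_origin, dtype=float)

    if np.linalg.norm(end_o - base_o) > geom.max_reach():
        return IKSolutionSet(np.empty((0, 6)), np.empty(0))

    N1 = base_o
    CA1 = base_o + base_R @ geom.base_ca_local
    C1 = base_o + base_R @ geom.base_c_local
    N4 = end_o
    CA4 = end_o + end_R @ geom.end_ca_local
    C4 = end_o + end_R @ geom.end_c_local
    base_atoms = (N1, CA1, C1)
    end_atoms = (N4, CA4, C4)
    mid = _middle_unit(geom)

    g = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    x = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)

    # batched LM on the reduced system; a first short phase over the whole
    # grid, then a longer one on the promising seeds only
    eps = 1e-7
    def _lm(x, n_iter):
        for _ in range(n_iter):
            rho, _ = _reduced_residual(x, base_atoms, end_atoms, geom, mid)
            err = np.sum(rho * rho, axis=-1)
            if np.all(err < 1e-22):
                break
            xb = np.repeat(x[:, None, :], 4, axis=1)
            for d in range(3):
                xb[:, d + 1, d] += eps
            rb, _ = _reduced_residual(xb, base_atoms, end_atoms, geom, mid)
            J = np.transpose((rb[:, 1:, :] - rb[:, :1, :]) / eps, (0, 2, 1))
            JtJ = J.transpose(0, 2, 1) @ J
            Jtr = np.einsum("sij,si->sj", J, rho)
            lam = (1e-8 + 1e-4 * err)[:, None, None] * np.eye(3)
            try:
                step = np.linalg.solve(JtJ + lam, Jtr[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
            x = wrap_angle(x - step)
        return x

    x = _lm(x, 12)
    rho, _ = _reduced_residual(x, base_atoms, end_atoms, geom, mid)
    err = np.sum(rho * rho, axis=-1)
    keep = err < 1e-2
    if not np.any(keep):
        keep = np.argsort(err)[:16]
    x = _lm(x[keep], 50)

    rho, atoms = _reduced_residual(x, base_atoms, end_atoms, geom, mid)
    err = np.sqrt(np.sum(rho * rho, axis=-1))
    good = err < 1e-8
    if not np.any(good):
        return IKSolutionSet(np.empty((0, 6)), np.empty(0))

    # read the full torsion 6-vectors off the converged geometries
    sel = {kk: v[good] for kk, v in atoms.items()}
    t0 = x[good, 0]
    t1f = geometry.dihedral_angle(np.broadcast_to(C1, sel["N2"].shape),
                                  sel["N2"], sel["CA2"], sel["C2"])
    t2f = geometry.dihedral_angle(sel["N2"], sel["CA2"], sel["C2"], sel["N3"])
    t3f = geometry.dihedral_angle(sel["C2"], sel["N3"], sel["CA3"], sel["C3"])
    t4f = geometry.dihedral_angle(sel["N3"], sel["CA3"], sel["C3"],
                                  np.broadcast_to(N4, sel["N3"].shape))
    t5 = x[good, 1]
    cand = np.stack([t0, t1f, t2f, t3f, t4f, t5], axis=-1)

    # deduplicate in torsion space
    unique: list[np.ndarray] = []
    for c in cand:
        if not any(np.max(np.abs(wrap_angle(c - u))) < DEDUP_TOLERANCE
                   for u in unique):
            unique.append(c)

    # verify against the forward-kinematics oracle
    solutions, residuals = [], []
    for c in unique:
        pos_err, ori_err = closure_error(geom, c, base_R, base_o, end_R, end_o)
        if pos_err <= position_tolerance and ori_err <= orientation_tolerance:
            solutions.append(c)
            residuals.append(pos_err)
    if len(solutions) > MAX_IK_SOLUTIONS:
        order = np.argsort(residuals)[:MAX_IK_SOLUTIONS]
        solutions = [solutions[i] for i in order]
        residuals = [residuals[i] for i in order]
    if not solutions:
        return IKSolutionSet(np.empty((0, 6)), np.empty(0))
    return IKSolutionSet(np.array(solutions), np.array(residuals))


def select_solution(solutions: IKSolutionSet, previous,
                    threshold: float = SOLUTION_THRESHOLD):
    """Closest solution to ``previous`` by max circular torsion deviation.

    Returns None when every solution deviates by more than ``threshold`` in
    some torsion (the continuity rejection that avoids jumps between
    successive conformations).
    """
    if len(solutions) == 0:
        return None
    previous = np.asarray(previous, dtype=float)
    dev = np.max(np.abs(wrap_angle(solutions.torsions - previous)), axis=1)
    best = int(np.argmin(dev))
    if dev[best] > threshold:
        return None
    return solutions.torsions[best]


# ---------------------------------------------------------------------------
# Chain reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    conformation: ProteinConformation | None
    success: bool
    status: str
    state: CoarseState | None = None          # realized frames (with perturbations)
    torsions: np.ndarray | None = None        # (k-1, 6) accepted IK solutions
    n_perturbations: int = 0


class ChainKinematics:
    """Precomputed per-tripeptide geometry, atom indexing and torsion seeds.

    Built once per planning problem (geometry is frozen along the whole
    exploration) and shared by every reconstruction call.
    """

    def __init__(self, reference: ProteinConformation,
                 steric_model: StericModel | None = None):
        self.reference = reference
        self.geometry = ChainGeometry.from_conformation(reference)
        self.triples, self.n_term, self.c_term = decompose_tripeptides(reference)
        self.k = len(self.triples)
        self.tripeptides = [tripeptide_geometry(self.geometry, t[0])
                            for t in self.triples[:-1]]
        self.params = _stack_params(self.tripeptides) if self.tripeptides else {}
        self.steric_model = steric_model or StericModel()
        self.radii = atom_radii(reference, self.steric_model)
        self.exclusions = backbone_exclusions(reference)

        # atom indices written by each IK segment: residues r..r+2, where the
        # first residue's N/CA/C come from the base frame itself
        self._segment_atoms = []
        for i, (r, r1, r2) in enumerate(self.triples[:-1]):
            idx = {}
            for res, tag in ((r, 1), (r1, 2), (r2, 3)):
                for nm in ("N", "CA", "C", "O", "CB"):
                    if reference.has_atom(res, nm):
                        idx[(tag, nm)] = reference.atom_index(res, nm)
            self._segment_atoms.append(idx)

        n_term_res = set(self.n_term)
        self._n_term_idx = [j for j in range(reference.n_atoms)
                            if reference.residue_index[j] in n_term_res]
        c_res = set(self.triples[-1]) | set(self.c_term)
        self._c_term_idx = [j for j in range(reference.n_atoms)
                            if reference.residue_index[j] in c_res]

        # atom index -> owning particle frame (terminal fragments ride on the
        # first/last frame)
        res_to_frame = np.zeros(reference.n_residues, dtype=int)
        for fi, triple in enumerate(self.triples):
            for res in triple:
                res_to_frame[res] = fi
        for res in self.n_term:
            res_to_frame[res] = 0
        for res in self.c_term:
            res_to_frame[res] = self.k - 1
        self._atom_frame = res_to_frame[reference.residue_index]

        # CB placement parameters per tripeptide position
        g = self.geometry
        self._cb_params = [
            [(g.has_cb[res], g.b_cacb[res], g.a_ncacb[res], g.d_cb[res])
             for res in triple]
            for triple in self.triples[:-1]
        ]

    def frame_of_atom(self, atom_index: int) -> int:
        """Index of the particle frame that positions this atom."""
        return int(self._atom_frame[atom_index])

    def seed_torsions(self) -> np.ndarray:
        """Torsion 6-vectors of the reference conformation, per IK segment."""
        g = self.geometry
        out = np.empty((self.k - 1, 6))
        for i, (r, _, _) in enumerate(self.triples[:-1]):
            out[i] = [g.psi[r], g.phi[r + 1], g.psi[r + 1],
                      g.phi[r + 2], g.psi[r + 2], g.phi[r + 3]]
        return out

    # -- assembly ----------------------------------------------------------
    def _segment_coords(self, i: int, torsions, base_R, base_o):
        """Atom index -> position map for IK segment i."""
        atoms, _ = forward_kinematics(self.tripeptides[i], torsions,
                                      base_R, base_o)
        out = {}
        seg = self._segment_atoms[i]
        for tag in (1, 2, 3):
            for nm in ("N", "CA", "C", "O"):
                key = (tag, nm)
                if key in seg:
                    out[seg[key]] = atoms[f"{nm}{tag}"]
            if (tag, "CB") in seg:
                has_cb, b, ang, dih = self._cb_params[i][tag - 1]
                cb = geometry.place_atom(atoms[f"C{tag}"], atoms[f"N{tag}"],
                                         atoms[f"CA{tag}"], b, ang, dih)
                out[seg[(tag, "CB")]] = cb
        return out


def reconstruct_chain(state: CoarseState, previous: ProteinConformation,
                      kin: ChainKinematics | None = None,
                      seed_torsions: np.ndarray | None = None,
                      perturb_magnitude=(0.1, 0.02), max_trials: int = 10,
                      check_collisions: bool = True,
                      solution_threshold: float = SOLUTION_THRESHOLD,
                      snap_tolerance=(0.2, 0.1),
                      steric_scale: float | None = None,
                      clash_alternatives: bool = True,
                      rng: np.random.Generator | None = None
                      ) -> ReconstructionResult:
    """Rebuild the all-atom backbone from particle frames.

    Tripeptides are processed N to C. For each, the closure onto the next
    particle is solved (seeded polish first, enumeration as fallback, closest
    solution selected); on IK failure or a steric clash the downstream
    particle's pose is slightly perturbed and the solve retried, up to
    ``max_trials`` times. Terminal fragments ride rigidly on the first/last
    frame. Failure is a reported outcome, not an exception.

    Sampled particle poses are generically a little off the reachable
    manifold of the 6R closure (mode displacements move origins while
    orientations are carried over), so an unconverged least-squares closure
    whose realized end frame lies within ``snap_tolerance`` (Angstrom, rad) of
    the target is accepted and the downstream particle snapped to the
    realized pose — a deterministic, bounded version of the
    perturb-the-downstream-particle retry policy. The returned state always
    holds the realized frames, against which every closure satisfies the
    exact tolerances.
    """
    rng = rng or np.random.default_rng()
    kin = kin or ChainKinematics(previous)
    k = kin.k
    frames_R = state.rotations.copy()
    frames_o = state.origins.copy()
    coords = np.array(previous.coords)
    seeds = (np.array(seed_torsions, dtype=float) if seed_torsions is not None
             else kin.seed_torsions())
    checker = (IncrementalClashChecker(
                   kin.radii, steric_scale or kin.steric_model.scale,
                   kin.exclusions)
               if check_collisions else None)
    n_perturb = 0
    accepted = np.empty((max(k - 1, 0), 6))

    # N-terminal fragment: rigid on frame 0 (internally clash-free by
    # construction, committed without checking)
    if kin._n_term_idx:
        local = state.n_term_local
        if local is None:
            R0, o0 = frame_of_reference(previous, kin.triples[0][0])
            local = geometry.to_local(R0, o0, previous.coords[kin._n_term_idx])
        coords[kin._n_term_idx] = local @ frames_R[0].T + frames_o[0]
        if checker:
            checker.commit(kin._n_term_idx, coords)

    if k >= 2:
        # fast path: polish all segments at once from the seed torsions
        tor, conv, _ = polish_ik(seeds, frames_R[:-1], frames_o[:-1],
                                 frames_R[1:], frames_o[1:], kin.params)
        solved_exact = conv.copy()
        dirty = np.zeros(k - 1, dtype=bool)

        c_local = state.c_term_local
        if c_local is None:
            Rl, ol = frame_of_reference(previous, kin.triples[-1][0])
            c_local = geometry.to_local(Rl, ol, previous.coords[kin._c_term_idx])

        for i in range(k - 1):
            trials = 0
            alternatives: list | None = None
            while True:
                if dirty[i]:
                    t_i, c_i, _ = polish_ik(
                        seeds[i:i + 1], frames_R[i:i + 1], frames_o[i:i + 1],
                        frames_R[i + 1:i + 2], frames_o[i + 1:i + 2],
                        {kk: v[i:i + 1] for kk, v in kin.params.items()})
                    tor[i] = t_i[0]
                    solved_exact[i] = bool(c_i[0])
                    dirty[i] = False
                ok = solved_exact[i]
                if ok:
                    accepted[i] = tor[i]
                else:
                    # snap: accept the closest reachable downstream pose
                    _, (rR, ro) = forward_kinematics(
                        kin.tripeptides[i], tor[i], frames_R[i], frames_o[i])
                    pos_dev = float(np.linalg.norm(ro - frames_o[i + 1]))
                    ori_dev = geometry.rotation_error(rR, frames_R[i + 1])
                    if (pos_dev <= snap_tolerance[0]
                            and ori_dev <= snap_tolerance[1]):
                        accepted[i] = tor[i]
                        frames_R[i + 1] = rR
                        frames_o[i + 1] = ro
                        solved_exact[i] = True
                        if i + 1 < k - 1:
                            dirty[i + 1] = True
                        ok = True
                    else:
                        sols = solve_ik(kin.tripeptides[i], frames_R[i],
                                        frames_o[i], frames_R[i + 1],
                                        frames_o[i + 1])
                        chosen = select_solution(sols, seeds[i],
                                                 threshold=solution_threshold)
                        if chosen is not None:
                            accepted[i] = chosen
                            tor[i] = chosen
                            solved_exact[i] = True
                            ok = True
                clash = None
                if ok:
                    seg = kin._segment_coords(i, accepted[i], frames_R[i],
                                              frames_o[i])
                    idx = list(seg.keys())
                    for jj, pos in seg.items():
                        coords[jj] = pos
                    is_last = i == k - 2
                    if is_last:
                        coords[kin._c_term_idx] = (c_local @ frames_R[-1].T
                                                   + frames_o[-1])
                        idx = idx + [j for j in kin._c_term_idx if j not in seg]
                    if checker:
                        clash = checker.check(idx, coords)
                    if clash is None:
                        if checker:
                            checker.commit(idx, coords)
                        break
                    # clash: try other IK branches before perturbing the frame
                    if alternatives is None and not clash_alternatives:
                        alternatives = []
                    if alternatives is None:
                        sols = solve_ik(kin.tripeptides[i], frames_R[i],
                                        frames_o[i], frames_R[i + 1],
                                        frames_o[i + 1])
                        if len(sols):
                            dev = np.max(np.abs(wrap_angle(
                                sols.torsions - seeds[i])), axis=1)
                            order = np.argsort(dev)
                            alternatives = [
                                sols.torsions[j] for j in order
                                if dev[j] <= solution_threshold
                                and np.max(np.abs(wrap_angle(
                                    sols.torsions[j] - accepted[i])))
                                > DEDUP_TOLERANCE
                            ]
                        else:
                            alternatives = []
                    if alternatives:
                        accepted[i] = alternatives.pop(0)
                        tor[i] = accepted[i]
                        solved_exact[i] = True
                        continue
                trials += 1
                if trials > max_trials:
                    return ReconstructionResult(
                        None, False,
                        f"tripeptide {i}: no collision-free IK solution after "
                        f"{max_trials} perturbations", None, None, n_perturb)
                # perturb the downstream particle pose and retry
                frames_o[i + 1] = frames_o[i + 1] + geometry.random_in_ball(
                    rng, perturb_magnitude[0])
                frames_R[i + 1] = geometry.random_rotation_small(
                    rng, perturb_magnitude[1]) @ frames_R[i + 1]
                dirty[i] = True
                if i + 1 < k - 1:
                    dirty[i + 1] = True
                alternatives = None
                n_perturb += 1
    else:
        # single tripeptide: whole chain rides rigidly on frame 0
        c_local = state.c_term_local
        if c_local is None:
            Rl, ol = frame_of_reference(previous, kin.triples[-1][0])
            c_local = geometry.to_local(Rl, ol, previous.coords[kin._c_term_idx])
        coords[kin._c_term_idx] = c_local @ frames_R[-1].T + frames_o[-1]

    conf = previous.with_coords(coords)
    realized = CoarseState(frames_o, frames_R, state.n_term_local,
                           state.c_term_local)
    return ReconstructionResult(conf, True, "ok", realized,
                                accepted if k >= 2 else None, n_perturb)


def frame_of_reference(conf: ProteinConformation, residue: int):
    """Particle frame of a residue (origin at N, triad from N->CA, N->C)."""
    return frame_of_residue(conf, residue)
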