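"""Anisotropic elastic network model and normal mode analysis.

Particles (tripeptide frame origins, or C-alpha atoms for the one-per-residue
comparison model) are joined by harmonic springs when closer than a cutoff
``d_cut``. The potential is ``sum C/2 (d_ij - d0_ij)^2`` over connected
pairs; its Hessian at equilibrium has the familiar ANM block structure

    H_ij = -(C / d0_ij^2) * (r_j - r_i)(r_j - r_i)^T      (i != j, spring)
    H_ii = -sum_{j != i} H_ij

Diagonalization yields 3n eigenpairs; the six near-zero eigenvalues are
rigid-body motions. Low-frequency modes predict directions of collective,
large-amplitude motions; their agreement with an observed conformational
change is quantified by the overlap (normalized projection).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

DEFAULT_CUTOFF_TRIPEPTIDE = 16.0   # Angstrom
DEFAULT_CUTOFF_CALPHA = 8.0        # Angstrom
RIGID_EIGENVALUE_RATIO = 1e-8


@dataclass
class ElasticNetwork:
    positions: np.ndarray            # (n, 3) equilibrium particle positions
    cutoff: float
    elastic_constant: float
    springs: np.ndarray              # (m, 2) int pairs, i < j
    rest_lengths: np.ndarray         # (m,)

    @property
    def n_particles(self) -> int:
        return len(self.positions)


@dataclass
class NormalModeSet:
    """Eigenpairs of the ENM Hessian, sorted by ascending eigenvalue."""

    eigenvalues: np.ndarray     # (3n,)
    eigenvectors: np.ndarray    # (3n, 3n), columns unit-norm
    rigid_mask: np.ndarray      # (3n,) bool, True for rigid-body modes
    scaled_modes: np.ndarray    # (3n, n_flex) columns a_j of the sampler

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def flexible_indices(self) -> np.ndarray:
        return np.nonzero(~self.rigid_mask)[0]


@dataclass
class OverlapResult:
    overlaps: np.ndarray        # (3n,) |cosine| per mode; nan for rigid modes
    best_mode_index: int        # index into the full mode set
    best_overlap: float


def build_network(positions: np.ndarray, d_cut: float,
                  elastic_constant: float = 1.0) -> ElasticNetwork:
    """Connect every particle pair closer than ``d_cut`` by a spring."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least 2 particles")
    if d_cut <= 0:
        raise ValueError("cutoff must be positive")
    dists = squareform(pdist(positions))
    iu = np.triu_indices(n, k=1)
    within = dists[iu] < d_cut
    springs = np.stack([iu[0][within], iu[1][within]], axis=1)
    rest = dists[iu][within]
    if np.any(rest <= 1e-9):
        i, j = springs[np.argmin(rest)]
        raise ValueError(f"coincident particles {i} and {j}")
    return ElasticNetwork(positions, float(d_cut), float(elastic_constant),
                          springs, rest)


def potential_energy(net: ElasticNetwork, positions: np.ndarray) -> float:
    """Harmonic network energy of a displaced particle configuration."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape != net.positions.shape:
        raise ValueError("positions shape mismatch")
    if len(net.springs) == 0:
        return 0.0
    d = np.linalg.norm(positions[net.springs[:, 0]] - positions[net.springs[:, 1]],
                       axis=1)
    return float(0.5 * net.elastic_constant * np.sum((d - net.rest_lengths) ** 2))


def assemble_hessian(net: ElasticNetwork) -> np.ndarray:
    """Dense 3n x 3n ANM Hessian with zero block-row sums."""
    n = net.n_particles
    H = np.zeros((3 * n, 3 * n))
    pos = net.positions
    for (i, j), d0 in zip(net.springs, net.rest_lengths):
        rij = pos[j] - pos[i]
        block = -(net.elastic_constant / d0 ** 2) * np.outer(rij, rij)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def compute_modes(H: np.ndarray, amplitude: str = "inverse_eigenvalue",
                  rigid_ratio: float = RIGID_EIGENVALUE_RATIO) -> NormalModeSet:
    """Diagonalize the Hessian and flag rigid-body modes.

    ``amplitude`` controls the scaled sampling modes a_j: low-frequency modes
    get larger norm, either as v_j / lambda_j (default) or v_j / sqrt(lambda_j).
    Rigid modes are excluded from the scaled set.
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = eigh(H)
    if len(evals) < 7:
        rigid = np.abs(evals) < 1e-10
    else:
        ref = max(evals[6], 1e-12)
        rigid = np.abs(evals) < rigid_ratio * ref
    n_rigid = int(rigid.sum())
    if n_rigid != 6:
        import warnings
        warnings.warn(
            f"expected 6 rigid-body modes, found {n_rigid} "
            "(disconnected or degenerate network?)", stacklevel=2)
    flex = ~rigid
    lam = evals[flex]
    if amplitude == "inverse_eigenvalue":
        scale = 1.0 / lam
    elif amplitude == "inverse_sqrt_eigenvalue":
        scale = 1.0 / np.sqrt(lam)
    else:
        raise ValueError(f"unknown amplitude rule: {amplitude}")
    scaled = evecs[:, flex] * scale
    return NormalModeSet(evals, evecs, rigid, scaled)


def overlap(modes: NormalModeSet, q_open: np.ndarray,
            q_closed: np.ndarray, superpose: bool = True) -> OverlapResult:
    """Overlap I_j of each mode with the open->closed displacement.

    I_j is the absolute cosine between the 3n-dimensional displacement
    Delta q = q_open - q_closed and mode j; 1 means the mode points exactly
    along the observed conformational change. The best value over non-rigid
    modes is reported (ties broken by lowest mode index).

    With ``superpose=True`` (default) the closed particle set is first rigidly
    superposed onto the open one, so Delta q carries no net translation or
    rotation — the modes themselves are orthogonal to the rigid-body subspace,
    and leaving a rigid component in Delta q would depress every overlap.
    """
    q_open = np.asarray(q_open, dtype=float)
    q_closed = np.asarray(q_closed, dtype=float)
    if superpose:
        from .geometry import superpose as _superpose
        _, _, q_closed = _superpose(q_closed, q_open)
    dq = (q_open - q_closed).ravel()
    norm = np.linalg.norm(dq)
    if norm < 1e-12:
        raise ValueError("zero displacement between conformations")
    if dq.size != modes.eigenvectors.shape[0]:
        raise ValueError("displacement size does not match mode dimension")
    cos = np.abs(modes.eigenvectors.T @ dq) / (
        np.linalg.norm(modes.eigenvectors, axis=0) * norm)
    overlaps = np.where(modes.rigid_mask, np.nan, cos)
    flex = modes.flexible_indices
    best_rel = int(np.argmax(cos[flex]))
    best = int(flex[best_rel])
    return OverlapResult(overlaps, best, float(cos[best]))


def best_overlap(positions_open: np.ndarray, positions_closed: np.ndarray,
                 d_cut: float, elastic_constant: float = 1.0,
                 amplitude: str = "inverse_eigenvalue") -> OverlapResult:
    """Modes of the open form vs the open->closed particle displacement."""
    net = build_network(positions_open, d_cut, elastic_constant)
    modes = compute_modes(assemble_hessian(net), amplitude=amplitude)
    return overlap(modes, positions_open, positions_closed)


def cutoff_scan(positions_open: np.ndarray, positions_closed: np.ndarray,
                cutoffs) -> list[dict]:
    """Best overlap per cutoff distance (the cutoff-calibration protocol).

    Returns one row per cutoff: ``{"cutoff", "best_overlap",
    "best_mode_index"}``.
    """
    rows = []
    for d_cut in cutoffs:
        res = best_overlap(positions_open, positions_closed, float(d_cut))
        rows.append({
            "cutoff": float(d_cut),
            "best_overlap": res.best_overlap,
            "best_mode_index": res.best_mode_index,
        })
    return rows
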