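"""Hard-sphere steric validity of backbone (+CB) conformations.

Atoms clash when their distance falls below ``scale * (r_i + r_j)`` with van
der Waals radii per element. Directly bonded (1-2) and angle (1-3) pairs are
excluded; 1-4 pairs are checked. Neighbor search uses a uniform cell grid
whose result is identical to the brute-force pair scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .structure import ProteinConformation

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52}
DEFAULT_SCALE = 0.70


@dataclass
class StericModel:
    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    scale: float = DEFAULT_SCALE

    def __post_init__(self):
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be positive")

    def radius_of(self, atom_name: str) -> float:
        return self.radii[atom_name.strip()[0]]


def atom_radii(conf: ProteinConformation, model: StericModel) -> np.ndarray:
    return np.array([model.radius_of(n) for n in conf.atom_names])


def backbone_exclusions(conf: ProteinConformation) -> set[frozenset]:
    """1-2 (bonded) and 1-3 (angle) atom-index pairs of the backbone+CB graph."""
    bonds = []
    for i in range(conf.n_residues):
        n = conf.atom_index(i, "N")
        ca = conf.atom_index(i, "CA")
        c = conf.atom_index(i, "C")
        bonds += [(n, ca), (ca, c)]
        if conf.has_atom(i, "O"):
            bonds.append((c, conf.atom_index(i, "O")))
        if conf.has_atom(i, "CB"):
            bonds.append((ca, conf.atom_index(i, "CB")))
        if i + 1 < conf.n_residues:
            bonds.append((c, conf.atom_index(i + 1, "N")))
    neighbors: dict[int, set[int]] = {}
    for a, b in bonds:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    excl = {frozenset(b) for b in bonds}
    for mid, nbrs in neighbors.items():
        nbrs = sorted(nbrs)
        for ii in range(len(nbrs)):
            for jj in range(ii + 1, len(nbrs)):
                excl.add(frozenset((nbrs[ii], nbrs[jj])))
    return excl


class SpatialGrid:
    """Uniform cell grid over points; cell size >= the largest clash diameter."""

    def __init__(self, cell_size: float):
        self.cell = float(cell_size)
        self._cells: dict[tuple, list[int]] = {}
        self.points: list[np.ndarray] = []

    def _key(self, p) -> tuple:
        return tuple(np.floor(np.asarray(p) / self.cell).astype(int))

    def insert(self, index: int, p: np.ndarray) -> None:
        self._cells.setdefault(self._key(p), []).append(index)
        while len(self.points) <= index:
            self.points.append(None)
        self.points[index] = np.asarray(p, dtype=float)

    def neighbors(self, p: np.ndarray):
        """Indices of stored points in the 27 cells around ``p``."""
        kx, ky, kz = self._key(p)
        out = []
        for dx, dy, dz in product((-1, 0, 1), repeat=3):
            out += self._cells.get((kx + dx, ky + dy, kz + dz), [])
        return out


def _clash_scan(coords, radii, scale, exclusions, grid: SpatialGrid,
                query_indices):
    """First clashing pair among query atoms vs grid contents, or None."""
    for i in query_indices:
        p = coords[i]
        for j in grid.neighbors(p):
            if j == i or frozenset((i, j)) in exclusions:
                continue
            limit = scale * (radii[i] + radii[j])
            if np.dot(p - grid.points[j], p - grid.points[j]) < limit * limit:
                return (min(i, j), max(i, j))
    return None


def has_clash(conf: ProteinConformation, model: StericModel | None = None,
              exclusions: set | None = None):
    """Check a conformation for steric clashes.

    Returns ``(flag, pair)`` where ``pair`` is the first offending atom-index
    pair (or None). Grid-based; exact, matching the O(n^2) scan.
    """
    model = model or StericModel()
    radii = atom_radii(conf, model)
    if exclusions is None:
        exclusions = backbone_exclusions(conf)
    cell = 2.0 * model.scale * max(model.radii.values())
    grid = SpatialGrid(cell)
    coords = conf.coords
    for i in range(conf.n_atoms):
        grid.insert(i, coords[i])
    pair = _clash_scan(coords, radii, model.scale, exclusions, grid,
                       range(conf.n_atoms))
    return (pair is not None), pair


def has_clash_brute(conf: ProteinConformation, model: StericModel | None = None,
                    exclusions: set | None = None):
    """Brute-force O(n^2) reference scan (oracle for the grid)."""
    model = model or StericModel()
    radii = atom_radii(conf, model)
    if exclusions is None:
        exclusions = backbone_exclusions(conf)
    coords = conf.coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    limit = model.scale * (radii[:, None] + radii[None, :])
    hit = d < limit
    np.fill_diagonal(hit, False)
    for i, j in sorted(np.argwhere(hit).tolist()):
        if i < j and frozenset((int(i), int(j))) not in exclusions:
            return True, (int(i), int(j))
    return False, None


class IncrementalClashChecker:
    """Clash checking against a growing set of placed atoms.

    Used during chain reconstruction: atoms are committed tripeptide by
    tripeptide and each new batch is validated against everything placed so
    far (and within itself).
    """

    def __init__(self, radii: np.ndarray, scale: float, exclusions: set):
        self.radii = np.asarray(radii, dtype=float)
        self.scale = float(scale)
        self.exclusions = exclusions
        cell = 2.0 * self.scale * float(self.radii.max())
        self.grid = SpatialGrid(cell)
        self.committed: list[int] = []

    def check(self, indices, coords_full: np.ndarray):
        """First clash of atoms ``indices`` vs committed atoms + each other."""
        # check vs committed
        for i in indices:
            p = coords_full[i]
            for j in self.grid.neighbors(p):
                if frozenset((i, j)) in self.exclusions:
                    continue
                limit = self.scale * (self.radii[i] + self.radii[j])
                if np.dot(p - self.grid.points[j], p - self.grid.points[j]) < limit * limit:
                    return (min(i, j), max(i, j))
        # check within the new batch
        idx = list(indices)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if frozenset((i, j)) in self.exclusions:
                    continue
                d = coords_full[i] - coords_full[j]
                limit = self.scale * (self.radii[i] + self.radii[j])
                if np.dot(d, d) < limit * limit:
                    return (min(i, j), max(i, j))
        return None

    def commit(self, indices, coords_full: np.ndarray) -> None:
        for i in indices:
            self.grid.insert(i, coords_full[i])
            self.committed.append(i)
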