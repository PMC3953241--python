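"""Protein backbone containers, PDB I/O, tripeptide decomposition and
particle-frame computation.

The in-memory model keeps only the atoms the method needs: backbone N, CA, C,
O plus CB. A chain is decomposed into consecutive tripeptides; an oriented
reference frame ("particle") is attached to the N atom of each tripeptide's
first residue. The ordered set of particle frames is the coarse-grained state
used by the elastic network and the planner.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from . import geometry

BACKBONE_NAMES = ("N", "CA", "C", "O", "CB")

#: maximum C(i)-N(i+1) peptide bond length accepted before a chain break is
#: declared (Angstrom); covers distorted experimental structures.
PEPTIDE_BOND_TOLERANCE = 1.8


class ChainBreakError(ValueError):
    """Raised when consecutive residues are not peptide-bonded."""


class MissingAtomError(ValueError):
    """Raised when a residue lacks a required backbone atom."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray


@dataclass
class ProteinConformation:
    """All-atom (backbone + CB) conformation of a single chain.

    Atoms are stored column-wise in numpy arrays; ``residue_index`` is the
    0-based sequential internal numbering, ``auth_res_ids`` keeps the author
    numbering of the source file for output.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    residue_index: np.ndarray       # (n_atoms,) int
    coords: np.ndarray              # (n_atoms, 3) float
    residue_names: np.ndarray       # (n_res,) str
    chain_id: str = "A"
    source_id: str = "synthetic"
    auth_res_ids: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.auth_res_ids is None:
            self.auth_res_ids = np.arange(1, self.n_residues + 1)
        self._index = {
            (int(r), str(n)): i
            for i, (r, n) in enumerate(zip(self.residue_index, self.atom_names))
        }
        self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue: int, name: str) -> int:
        try:
            return self._index[(residue, name)]
        except KeyError:
            raise MissingAtomError(
                f"residue {residue} ({self.residue_names[residue]}) has no atom {name}"
            ) from None

    def atom_position(self, residue: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue, name)]

    def has_atom(self, residue: int, name: str) -> bool:
        return (residue, name) in self._index

    def backbone(self, name: str) -> np.ndarray:
        """(n_res, 3) coordinates of one backbone atom type for every residue."""
        idx = [self.atom_index(r, name) for r in range(self.n_residues)]
        return self.coords[idx]

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(i + 1, str(n), int(r), str(self.residue_names[int(r)]),
                       self.chain_id, self.coords[i])
            for i, (n, r) in enumerate(zip(self.atom_names, self.residue_index))
        ]

    def with_coords(self, coords: np.ndarray) -> "ProteinConformation":
        return replace(self, coords=np.array(coords, dtype=float))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ProteinConformation":
        """Rigidly transformed copy (x -> R x + t)."""
        return self.with_coords(self.coords @ np.asarray(R).T + np.asarray(t))

    # -- validation --------------------------------------------------------
    def _validate(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for r in range(self.n_residues):
            for name in ("N", "CA", "C"):
                if not self.has_atom(r, name):
                    raise MissingAtomError(
                        f"residue {r} ({self.residue_names[r]}) is missing "
                        f"backbone atom {name}"
                    )
        if self.n_residues > 1:
            c = self.backbone("C")[:-1]
            n = self.backbone("N")[1:]
            bonds = np.linalg.norm(c - n, axis=1)
            bad = np.nonzero(bonds > PEPTIDE_BOND_TOLERANCE)[0]
            if bad.size:
                raise ChainBreakError(
                    f"chain break between residues {bad[0]} and {bad[0] + 1}: "
                    f"C-N distance {bonds[bad[0]]:.2f} A"
                )


@dataclass
class ParticleFrame:
    """Oriented coarse particle: origin + right-handed orthonormal triad."""

    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)


@dataclass
class CoarseState:
    """Ordered particle frames, one per tripeptide.

    ``n_term_local`` / ``c_term_local`` hold the coordinates of the terminal
    fragments (leftover residues plus, at the C side, the final tripeptide)
    expressed in the first/last frame, so chain ends can be rebuilt rigidly.
    """

    origins: np.ndarray        # (k, 3)
    rotations: np.ndarray      # (k, 3, 3)
    n_term_local: np.ndarray | None = None   # (m_n, 3)
    c_term_local: np.ndarray | None = None   # (m_c, 3)

    @property
    def n_frames(self) -> int:
        return len(self.origins)

    @property
    def frames(self) -> list[ParticleFrame]:
        return [ParticleFrame(o, R) for o, R in zip(self.origins, self.rotations)]

    def with_origins(self, origins: np.ndarray) -> "CoarseState":
        return CoarseState(np.array(origins, dtype=float), self.rotations.copy(),
                           self.n_term_local, self.c_term_local)

    def copy(self) -> "CoarseState":
        return CoarseState(self.origins.copy(), self.rotations.copy(),
                           self.n_term_local, self.c_term_local)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _element_of(name: str) -> str:
    return name.strip()[0]


def load_pdb(path, chain: str | None = None, model: int = 1,
             on_gap: str = "error", source_id: str | None = None
             ) -> ProteinConformation:
    """Read one chain of a PDB file into a backbone+CB conformation.

    Parameters
    ----------
    chain:
        Chain identifier; default is the first polymer chain in the file.
    model:
        Model number for multi-model entries.
    on_gap:
        ``"error"`` raises on a chain break or a residue missing backbone
        atoms; ``"truncate"`` keeps the chain up to the first defect.
    """
    pdb_file = bpdb.PDBFile.read(str(path))
    array = pdb_file.get_structure(model=model, altloc="occupancy")
    array = array[bst.filter_amino_acids(array)]
    if array.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid residues found")
    if chain is None:
        chain = str(array.chain_id[0])
    array = array[array.chain_id == chain]
    if array.array_length() == 0:
        raise ValueError(f"{path}: chain {chain!r} is empty")
    array = array[np.isin(array.atom_name, BACKBONE_NAMES)]

    names, res_index, coords, res_names, auth_ids = [], [], [], [], []
    starts = bst.get_residue_starts(array, add_exclusive_stop=True)
    kept = 0
    prev_c = None
    for s, e in zip(starts[:-1], starts[1:]):
        sub_names = list(array.atom_name[s:e])
        sub_coords = array.coord[s:e]
        entry = {n: sub_coords[i] for i, n in enumerate(sub_names)}
        missing = [n for n in ("N", "CA", "C") if n not in entry]
        broken = (
            prev_c is not None
            and "N" in entry
            and np.linalg.norm(entry["N"] - prev_c) > PEPTIDE_BOND_TOLERANCE
        )
        if missing or broken:
            if on_gap == "truncate" and kept >= 1:
                break
            reason = (
                f"missing {missing}" if missing
                else "chain break (C-N distance exceeds tolerance)"
            )
            raise MissingAtomError(
                f"{path}: residue {array.res_id[s]} ({array.res_name[s]}): {reason}"
            ) if missing else ChainBreakError(
                f"{path}: residue {array.res_id[s]} ({array.res_name[s]}): {reason}"
            )
        for n in BACKBONE_NAMES:
            if n in entry:
                names.append(n)
                res_index.append(kept)
                coords.append(entry[n])
        res_names.append(str(array.res_name[s]))
        auth_ids.append(int(array.res_id[s]))
        prev_c = entry["C"]
        kept += 1

    return ProteinConformation(
        atom_names=np.array(names),
        residue_index=np.array(res_index),
        coords=np.array(coords, dtype=float),
        residue_names=np.array(res_names),
        chain_id=chain,
        source_id=source_id or str(path),
        auth_res_ids=np.array(auth_ids),
    )


def _to_atom_array(conf: ProteinConformation) -> bst.AtomArray:
    n = conf.n_atoms
    array = bst.AtomArray(n)
    array.coord = conf.coords.astype(np.float32)
    array.atom_name = conf.atom_names
    array.res_id = conf.auth_res_ids[conf.residue_index]
    array.res_name = conf.residue_names[conf.residue_index]
    array.chain_id = np.full(n, conf.chain_id)
    array.element = np.array([_element_of(a) for a in conf.atom_names])
    array.hetero = np.zeros(n, dtype=bool)
    return array


def write_pdb(conf: ProteinConformation, path) -> None:
    """Write a single conformation as a one-model PDB file."""
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(_to_atom_array(conf))
    pdb_file.write(str(path))


def write_path_pdb(conformations, path) -> None:
    """Write an ordered list of conformations as a multi-model PDB."""
    conformations = list(conformations)
    if not conformations:
        raise ValueError("empty path")
    base = _to_atom_array(conformations[0])
    stack = bst.stack(
        [base.copy() for _ in conformations]
    )
    stack.coord = np.stack([c.coords.astype(np.float32) for c in conformations])
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_path_pdb(path) -> list[ProteinConformation]:
    """Read a multi-model PDB written by :func:`write_path_pdb`."""
    pdb_file = bpdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    return [load_pdb(path, model=m + 1, source_id=f"{path}#{m + 1}")
            for m in range(n_models)]


# ---------------------------------------------------------------------------
# Tripeptide decomposition and particle frames
# ---------------------------------------------------------------------------

def decompose_tripeptides(conf: ProteinConformation):
    """Split the chain into consecutive tripeptides plus terminal leftovers.

    Returns ``(triples, n_term, c_term)`` where ``triples`` is a list of
    ``(i, i+1, i+2)`` residue-index tuples and the leftover ``n_res mod 3``
    residues are split floor(r/2) to the N terminus, the rest to the C
    terminus.
    """
    n_res = conf.n_residues
    if n_res < 5:
        raise ValueError(f"chain too short to decompose: {n_res} residues")
    r = n_res % 3
    n_left = r // 2
    k = (n_res - r) // 3
    triples = [(n_left + 3 * i, n_left + 3 * i + 1, n_left + 3 * i + 2)
               for i in range(k)]
    n_term = list(range(n_left))
    c_term = list(range(n_left + 3 * k, n_res))
    return triples, n_term, c_term


def frame_of_residue(conf: ProteinConformation, residue: int):
    """Particle frame of one residue: origin at N, triad from N->CA and N->C."""
    n = conf.atom_position(residue, "N")
    ca = conf.atom_position(residue, "CA")
    c = conf.atom_position(residue, "C")
    R, origin = geometry.frame_from_atoms(n, ca, c)
    return R, origin


def compute_particle_frames(conf: ProteinConformation) -> CoarseState:
    """Oriented particle per tripeptide; terminal fragments stored rigidly.

    The C-terminal fragment comprises the final tripeptide's non-frame atoms
    plus any leftover residues: the last tripeptide has no downstream frame to
    close against, so it travels rigidly with its own particle.
    """
    triples, n_term, c_term = decompose_tripeptides(conf)
    rotations = np.empty((len(triples), 3, 3))
    origins = np.empty((len(triples), 3))
    for i, (a, _, _) in enumerate(triples):
        R, o = frame_of_residue(conf, a)
        rotations[i] = R
        origins[i] = o

    n_term_atoms = [
        conf.coords[j] for j in range(conf.n_atoms)
        if conf.residue_index[j] in n_term
    ]
    n_term_local = (
        geometry.to_local(rotations[0], origins[0], np.array(n_term_atoms))
        if n_term_atoms else None
    )
    last_res = set(triples[-1]) | set(c_term)
    c_term_atoms = [
        conf.coords[j] for j in range(conf.n_atoms)
        if conf.residue_index[j] in last_res
    ]
    c_term_local = geometry.to_local(
        rotations[-1], origins[-1], np.array(c_term_atoms)
    )
    return CoarseState(origins, rotations, n_term_local, c_term_local)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def ca_rmsd(a: ProteinConformation, b: ProteinConformation,
            superpose: bool = True) -> float:
    """C-alpha RMSD between two conformations of the same chain.

    With ``superpose=True`` (default) an optimal least-squares rigid
    superposition is applied first.
    """
    if a.n_residues != b.n_residues:
        raise ValueError(
            f"residue count mismatch: {a.n_residues} vs {b.n_residues}"
        )
    ca_a = a.backbone("CA")
    ca_b = b.backbone("CA")
    if superpose:
        return geometry.superposed_rmsd(ca_a, ca_b)
    return geometry.rmsd(ca_a, ca_b)
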