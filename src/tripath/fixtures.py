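"""Synthetic polypeptide generator.

Produces ideal-geometry poly-alanine backbones (standard bond lengths and
angles, trans peptide bonds) with per-segment secondary structure, and pairs
of conformations related by a rigid hinge rotation of the C-terminal arm.
These stand in for experimental open/closed conformation pairs so that every
stage of the method is testable without any structure download.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .collision import StericModel, has_clash
from .internal import ChainGeometry, build_chain
from .structure import ProteinConformation

#: canonical torsion pairs (phi, psi) per secondary-structure pattern, rad
PATTERN_TORSIONS = {
    "helix": (np.deg2rad(-57.0), np.deg2rad(-47.0)),
    "extended": (np.deg2rad(-139.0), np.deg2rad(135.0)),
    "ppii": (np.deg2rad(-75.0), np.deg2rad(145.0)),
}

#: two-residue turn that folds a helix back onto itself with a comfortable
#: steric margin (phi1, psi1, phi2, psi2), rad
HAIRPIN_TURN = tuple(np.deg2rad((44.8, 70.4, 174.3, -167.8)))

#: four-residue inter-domain linker of the two-domain fixture: packs the
#: second hairpin against the first so that cross-domain springs break the
#: bend/twist degeneracy and the softest mode is a well-separated hinge bend
#: (phi x4, psi x4), rad
TWO_DOMAIN_LINKER = tuple(np.deg2rad(
    (-38.7, -72.9, 80.8, -71.4, -45.1, 107.4, 57.2, 72.4)))


@dataclass
class FixtureSpec:
    """Recipe for a synthetic chain.

    ``segments`` is a list of ``(pattern, length)`` pairs; ``hinge`` is
    ``(pivot_residue, axis, angle_rad)`` for hinge pairs. Alanine is used
    throughout (real CB atoms exercise collision checking); ``glycine_every``
    sprinkles GLY residues to cover the no-CB path.
    """

    n_residues: int = 60
    segments: list = field(default_factory=lambda: [("helix", -1)])
    hinge: tuple = (30, np.deg2rad(30.0))
    overrides: tuple = ()       # ((residue, phi, psi), ...) applied last
    glycine_every: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("fixtures need at least 5 residues")
        pivot, angle = self.hinge
        if not (0 < pivot < self.n_residues - 1):
            raise ValueError("hinge pivot must be interior to the chain")
        if abs(angle) >= np.pi:
            raise ValueError("|hinge angle| must be < pi")

    def residue_names(self) -> np.ndarray:
        names = np.array(["ALA"] * self.n_residues)
        if self.glycine_every > 0:
            names[::self.glycine_every] = "GLY"
        return names

    def torsions(self):
        phi = np.empty(self.n_residues)
        psi = np.empty(self.n_residues)
        pos = 0
        for pattern, length in self.segments:
            if length < 0:
                length = self.n_residues - pos
            p, s = PATTERN_TORSIONS[pattern]
            phi[pos:pos + length] = p
            psi[pos:pos + length] = s
            pos += length
        if pos < self.n_residues:
            p, s = PATTERN_TORSIONS[self.segments[-1][0]]
            phi[pos:] = p
            psi[pos:] = s
        for res, p, s in self.overrides:
            phi[res] = p
            psi[res] = s
        return phi, psi


def make_chain(spec: FixtureSpec) -> ProteinConformation:
    """Ideal-geometry backbone with the requested torsion pattern.

    Deterministic for a given spec; raises if the pattern self-intersects.
    """
    names = spec.residue_names()
    geom = ChainGeometry.ideal(names)
    phi, psi = spec.torsions()
    conf = build_chain(geom, phi, psi, source_id="synthetic")
    clash, pair = has_clash(conf, StericModel())
    if clash:
        raise ValueError(f"fixture spec self-intersects: atom pair {pair}")
    return conf


def make_hinge_pair(spec: FixtureSpec):
    """(open, closed) pair related by a rigid hinge rotation.

    The closed form rotates the whole C-terminal arm (every residue past the
    pivot, plus the pivot's carbonyl O) about the pivot's CA->C bond — i.e.
    the hinge is a change of the pivot's psi torsion, so the closed form keeps
    exact backbone geometry. Both forms are clash-free; the C-alpha RMSD
    between them is controlled by the hinge angle.
    """
    open_conf = make_chain(spec)
    pivot, angle = spec.hinge
    ca = open_conf.atom_position(pivot, "CA")
    c = open_conf.atom_position(pivot, "C")
    axis = (c - ca) / np.linalg.norm(c - ca)
    R = Rotation.from_rotvec(axis * angle).as_matrix()

    coords = np.array(open_conf.coords)
    moving = open_conf.residue_index > pivot
    moving[open_conf.atom_index(pivot, "O")] = True
    coords[moving] = (coords[moving] - ca) @ R.T + ca
    closed = open_conf.with_coords(coords)
    clash, pair = has_clash(closed, StericModel())
    if clash:
        raise ValueError(f"closed form self-intersects: atom pair {pair}")
    return open_conf, closed


def two_domain_spec(n_residues: int = 60, hinge_angle: float = np.deg2rad(30.0),
                    seed: int = 0) -> FixtureSpec:
    """Two helix-hairpin domains joined by a packed four-residue linker.

    Each domain is a helix hairpin (a compact, genuinely three-dimensional
    blob — a lone helix would leave the particle network quasi-collinear and
    produce spurious soft modes). The linker packs the domains against each
    other so that cross-domain springs break the bend/twist degeneracy: the
    softest mode is the hinge bend about the linker. The hinge pivot is the
    last linker residue, so the hinge rotates domain 2 exactly.
    """
    if not (52 <= n_residues <= 66):
        raise ValueError(
            "the two-domain fixture layout is designed for 52-66 residues "
            "(the hairpin and linker torsions are fixed; far outside this "
            "window the arms self-intersect)")
    d1_h2 = 11 + (n_residues - 60) // 2       # second helix of domain 1
    d2_h2 = n_residues - 45 - (n_residues - 60) // 2
    segments = [("helix", 13), ("helix", 2), ("helix", d1_h2),
                ("helix", 4),
                ("helix", 13), ("helix", 2), ("helix", d2_h2)]
    t1 = 13
    linker = 13 + 2 + d1_h2
    t2 = linker + 4 + 13
    p1, s1, p2, s2 = HAIRPIN_TURN
    lp = TWO_DOMAIN_LINKER
    overrides = (
        (t1, p1, s1), (t1 + 1, p2, s2),
        (linker, lp[0], lp[4]), (linker + 1, lp[1], lp[5]),
        (linker + 2, lp[2], lp[6]), (linker + 3, lp[3], lp[7]),
        (t2, p1, s1), (t2 + 1, p2, s2),
    )
    return FixtureSpec(n_residues=n_residues, segments=segments,
                       hinge=(linker + 3, hinge_angle), overrides=overrides,
                       seed=seed)
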