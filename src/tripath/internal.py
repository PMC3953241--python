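"""Internal-coordinate description of a protein backbone.

A :class:`ChainGeometry` freezes everything the multi-scale model treats as
rigid — bond lengths, bond angles, peptide-bond torsions (omega), carbonyl-O
and CB placement parameters — and records the free phi/psi torsions of a
reference conformation. Freezing the *input* values (rather than idealized
ones) makes the coarse-grain/reconstruct round trip exact.

The module also provides the sequential internal-to-Cartesian chain build
used by the synthetic-structure generator and the torsion-space relaxation
hook.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .structure import ProteinConformation

# Ideal backbone geometry (Engh-Huber-like values), Angstrom / radians.
IDEAL = {
    "b_nca": 1.458,
    "b_cac": 1.525,
    "b_cn": 1.329,
    "b_co": 1.231,
    "b_cacb": 1.521,
    "a_ncac": np.deg2rad(111.2),
    "a_cacn": np.deg2rad(116.2),
    "a_cnca": np.deg2rad(121.7),
    "a_caco": np.deg2rad(120.5),
    "a_ncacb": np.deg2rad(110.4),
    "d_o": np.pi,                  # dihedral N(i+1)-CA-C-O
    "d_cb": np.deg2rad(-122.6),    # dihedral C-N-CA-CB (L-amino acid)
    "omega": np.pi,                # trans peptide bond
}


@dataclass
class ChainGeometry:
    """Frozen internal coordinates of an n-residue backbone (+CB, +O)."""

    res_names: np.ndarray   # (n,) str
    b_nca: np.ndarray       # (n,) N(i)-CA(i)
    b_cac: np.ndarray       # (n,) CA(i)-C(i)
    b_cn: np.ndarray        # (n,) C(i)-N(i+1); last entry nan
    a_ncac: np.ndarray      # (n,) angle N-CA-C
    a_cacn: np.ndarray      # (n,) angle CA(i)-C(i)-N(i+1); last nan
    a_cnca: np.ndarray      # (n,) angle C(i)-N(i+1)-CA(i+1); last nan
    omega: np.ndarray       # (n,) dihedral CA(i)-C(i)-N(i+1)-CA(i+1); last nan
    b_co: np.ndarray        # (n,)
    a_caco: np.ndarray      # (n,)
    d_o: np.ndarray         # (n,) dihedral ref-CA-C-O; ref = N(i+1) (N(i) for last)
    has_cb: np.ndarray      # (n,) bool
    b_cacb: np.ndarray      # (n,)
    a_ncacb: np.ndarray     # (n,)
    d_cb: np.ndarray        # (n,) dihedral C-N-CA-CB
    phi: np.ndarray         # (n,) dihedral C(i-1)-N-CA-C; first entry nan
    psi: np.ndarray         # (n,) dihedral N-CA-C-N(i+1); last entry nan

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def base_local_ca_c(self, i: int):
        """CA and C positions of residue i in its own particle frame.

        The frame's x axis points N->CA and C lies in the xy half-plane with
        positive y, so both positions follow from the frozen bond geometry.
        """
        b1 = self.b_nca[i]
        b2 = self.b_cac[i]
        ang = self.a_ncac[i]
        l2 = b1 * b1 + b2 * b2 - 2.0 * b1 * b2 * np.cos(ang)
        x = (l2 - b2 * b2 + b1 * b1) / (2.0 * b1)
        y = np.sqrt(max(l2 - x * x, 0.0))
        ca = np.array([b1, 0.0, 0.0])
        c = np.array([x, y, 0.0])
        return ca, c

    @classmethod
    def from_conformation(cls, conf: ProteinConformation) -> "ChainGeometry":
        n = conf.n_residues
        N = conf.backbone("N")
        CA = conf.backbone("CA")
        C = conf.backbone("C")
        nan = np.full(n, np.nan)

        b_nca = np.linalg.norm(CA - N, axis=1)
        b_cac = np.linalg.norm(C - CA, axis=1)
        b_cn = nan.copy()
        b_cn[:-1] = np.linalg.norm(N[1:] - C[:-1], axis=1)
        a_ncac = geometry.bond_angle(N, CA, C)
        a_cacn = nan.copy()
        a_cacn[:-1] = geometry.bond_angle(CA[:-1], C[:-1], N[1:])
        a_cnca = nan.copy()
        a_cnca[:-1] = geometry.bond_angle(C[:-1], N[1:], CA[1:])
        omega = nan.copy()
        omega[:-1] = geometry.dihedral_angle(CA[:-1], C[:-1], N[1:], CA[1:])
        phi = nan.copy()
        phi[1:] = geometry.dihedral_angle(C[:-1], N[1:], CA[1:], C[1:])
        psi = nan.copy()
        psi[:-1] = geometry.dihedral_angle(N[:-1], CA[:-1], C[:-1], N[1:])

        b_co = np.full(n, IDEAL["b_co"])
        a_caco = np.full(n, IDEAL["a_caco"])
        d_o = np.full(n, IDEAL["d_o"])
        for i in range(n):
            if not conf.has_atom(i, "O"):
                continue
            o = conf.atom_position(i, "O")
            b_co[i] = np.linalg.norm(o - C[i])
            a_caco[i] = geometry.bond_angle(CA[i], C[i], o)
            ref = N[i + 1] if i < n - 1 else N[i]
            d_o[i] = geometry.dihedral_angle(ref, CA[i], C[i], o)

        has_cb = np.array([conf.has_atom(i, "CB") for i in range(n)])
        b_cacb = np.full(n, IDEAL["b_cacb"])
        a_ncacb = np.full(n, IDEAL["a_ncacb"])
        d_cb = np.full(n, IDEAL["d_cb"])
        for i in np.nonzero(has_cb)[0]:
            cb = conf.atom_position(i, "CB")
            b_cacb[i] = np.linalg.norm(cb - CA[i])
            a_ncacb[i] = geometry.bond_angle(N[i], CA[i], cb)
            d_cb[i] = geometry.dihedral_angle(C[i], N[i], CA[i], cb)

        return cls(conf.residue_names.copy(), b_nca, b_cac, b_cn, a_ncac,
                   a_cacn, a_cnca, omega, b_co, a_caco, d_o, has_cb, b_cacb,
                   a_ncacb, d_cb, phi, psi)

    @classmethod
    def ideal(cls, res_names) -> "ChainGeometry":
        """Ideal-geometry chain (trans peptide bonds, standard bonds/angles)."""
        res_names = np.asarray(res_names)
        n = len(res_names)
        full = lambda key: np.full(n, IDEAL[key])  # noqa: E731
        last_nan = lambda arr: np.concatenate([arr[:-1], [np.nan]])  # noqa: E731
        has_cb = res_names != "GLY"
        return cls(
            res_names,
            full("b_nca"), full("b_cac"), last_nan(full("b_cn")),
            full("a_ncac"), last_nan(full("a_cacn")), last_nan(full("a_cnca")),
            last_nan(full("omega")),
            full("b_co"), full("a_caco"), full("d_o"),
            has_cb, full("b_cacb"), full("a_ncacb"), full("d_cb"),
            np.full(n, np.nan), np.full(n, np.nan),
        )


def build_chain(geom: ChainGeometry, phi: np.ndarray, psi: np.ndarray,
                base_rotation: np.ndarray | None = None,
                base_origin: np.ndarray | None = None,
                res_names=None, chain_id: str = "A",
                source_id: str = "synthetic") -> ProteinConformation:
    """Sequential internal-to-Cartesian build of a full backbone.

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined at chain ends). The
    first residue is placed in the given base frame (identity frame at the
    origin by default) following the particle-frame convention.
    """
    n = geom.n_residues
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    R = np.eye(3) if base_rotation is None else np.asarray(base_rotation)
    o = np.zeros(3) if base_origin is None else np.asarray(base_origin)

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    O = np.empty((n, 3))

    ca0, c0 = geom.base_local_ca_c(0)
    N[0] = o
    CA[0] = o + R @ ca0
    C[0] = o + R @ c0
    for i in range(n - 1):
        N[i + 1] = geometry.place_atom(N[i], CA[i], C[i],
                                       geom.b_cn[i], geom.a_cacn[i], psi[i])
        O[i] = geometry.place_atom(N[i + 1], CA[i], C[i],
                                   geom.b_co[i], geom.a_caco[i], geom.d_o[i])
        CA[i + 1] = geometry.place_atom(CA[i], C[i], N[i + 1],
                                        geom.b_nca[i + 1], geom.a_cnca[i],
                                        geom.omega[i])
        C[i + 1] = geometry.place_atom(C[i], N[i + 1], CA[i + 1],
                                       geom.b_cac[i + 1], geom.a_ncac[i + 1],
                                       phi[i + 1])
    O[n - 1] = geometry.place_atom(N[n - 1], CA[n - 1], C[n - 1],
                                   geom.b_co[n - 1], geom.a_caco[n - 1],
                                   geom.d_o[n - 1])

    names, res_idx, coords = [], [], []
    res_names = geom.res_names if res_names is None else np.asarray(res_names)
    for i in range(n):
        for nm, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            names.append(nm)
            res_idx.append(i)
            coords.append(pos)
        if geom.has_cb[i]:
            cb = geometry.place_atom(C[i], N[i], CA[i], geom.b_cacb[i],
                                     geom.a_ncacb[i], geom.d_cb[i])
            names.append("CB")
            res_idx.append(i)
            coords.append(cb)

    return ProteinConformation(
        atom_names=np.array(names),
        residue_index=np.array(res_idx),
        coords=np.array(coords),
        residue_names=res_names,
        chain_id=chain_id,
        source_id=source_id,
    )
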