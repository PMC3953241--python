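"""Elastic network construction, Hessian, normal modes and overlaps."""
import numpy as np
import pytest

from tripath.enm import (assemble_hessian, best_overlap, build_network,
                         compute_modes, cutoff_scan, overlap, potential_energy)
from tripath.structure import compute_particle_frames


@pytest.fixture(scope="module")
def hinge_particles(hinge_pair):
    o, c = hinge_pair
    return (compute_particle_frames(o).origins,
            compute_particle_frames(c).origins)


def test_two_particles_within_and_beyond_cutoff():
    pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
    assert len(build_network(pos, 16.0).springs) == 1
    pos = np.array([[0.0, 0, 0], [20.0, 0, 0]])
    assert len(build_network(pos, 16.0).springs) == 0


def test_coincident_particles_raise():
    pos = np.zeros((2, 3))
    with pytest.raises(ValueError):
        build_network(pos, 16.0)


def test_spring_enumeration_matches_brute_force(hinge_particles):
    pos, _ = hinge_particles
    net = build_network(pos, 16.0)
    expected = {(i, j) for i in range(len(pos)) for j in range(i + 1, len(pos))
                if np.linalg.norm(pos[i] - pos[j]) < 16.0}
    assert {tuple(s) for s in net.springs} == expected


def test_potential_energy_zero_at_equilibrium_and_hand_value():
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    net = build_network(pos, 16.0, elastic_constant=2.0)
    assert potential_energy(net, pos) == 0.0
    stretched = np.array([[0.0, 0, 0], [2.5, 0, 0]])
    # C/2 * delta^2 = 2/2 * 0.25
    assert potential_energy(net, stretched) == pytest.approx(0.25, abs=1e-12)


def test_potential_energy_rigid_motion_invariant(hinge_particles):
    from scipy.spatial.transform import Rotation
    pos, _ = hinge_particles
    net = build_network(pos, 16.0)
    displaced = pos + np.random.default_rng(0).normal(size=pos.shape) * 0.3
    e0 = potential_energy(net, displaced)
    R = Rotation.from_euler("xyz", [0.3, 0.6, -0.2]).as_matrix()
    e1 = potential_energy(net, displaced @ R.T + [5.0, -3.0, 2.0])
    assert e1 == pytest.approx(e0, rel=1e-10)


def test_hessian_symmetric_block_row_sums_and_psd(hinge_particles):
    pos, _ = hinge_particles
    net = build_network(pos, 16.0)
    H = assemble_hessian(net)
    n = len(pos)
    assert np.abs(H - H.T).max() < 1e-12
    for i in range(n):
        row_sum = sum(H[3 * i:3 * i + 3, 3 * j:3 * j + 3] for j in range(n))
        np.testing.assert_allclose(row_sum, 0.0, atol=1e-10)
    evals = np.linalg.eigvalsh(H)
    assert evals.min() > -1e-8


def test_hessian_matches_finite_difference_of_energy():
    """The analytic ANM Hessian equals the numeric second derivative of the
    spring energy at equilibrium (independent brute-force oracle)."""
    rng = np.random.default_rng(4)
    pos = rng.normal(size=(4, 3)) * 3.0
    net = build_network(pos, d_cut=8.0, elastic_constant=1.3)
    H = assemble_hessian(net)
    eps = 1e-5
    x0 = pos.ravel()
    H_fd = np.empty_like(H)
    e0 = potential_energy(net, x0.reshape(-1, 3))
    for a in range(12):
        for b in range(12):
            if a == b:
                xp = x0.copy(); xp[a] += eps
                xm = x0.copy(); xm[a] -= eps
                H_fd[a, b] = (
                    potential_energy(net, xp.reshape(-1, 3)) - 2 * e0
                    + potential_energy(net, xm.reshape(-1, 3))
                ) / (eps * eps)
                continue
            xpp = x0.copy(); xpp[a] += eps; xpp[b] += eps
            xpm = x0.copy(); xpm[a] += eps; xpm[b] -= eps
            xmp = x0.copy(); xmp[a] -= eps; xmp[b] += eps
            xmm = x0.copy(); xmm[a] -= eps; xmm[b] -= eps
            H_fd[a, b] = (
                potential_energy(net, xpp.reshape(-1, 3))
                - potential_energy(net, xpm.reshape(-1, 3))
                - potential_energy(net, xmp.reshape(-1, 3))
                + potential_energy(net, xmm.reshape(-1, 3))
            ) / (4 * eps * eps)
    np.testing.assert_allclose(H, H_fd, atol=1e-5)


def test_connected_network_has_exactly_six_rigid_modes(hinge_particles):
    pos, _ = hinge_particles
    modes = compute_modes(assemble_hessian(build_network(pos, 16.0)))
    assert int(modes.rigid_mask.sum()) == 6
    assert np.all(modes.rigid_mask[:6])
    # eigenvector columns orthonormal
    V = modes.eigenvectors
    np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)


def test_two_body_spring_closed_form():
    """Two unit-separated particles, C=1: one nonzero eigenvalue 2 along the
    inter-particle axis (closed-form two-body problem)."""
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    net = build_network(pos, 16.0)
    with pytest.warns(UserWarning):
        modes = compute_modes(assemble_hessian(net))
    nonzero = modes.eigenvalues[np.abs(modes.eigenvalues) > 1e-10]
    assert len(nonzero) == 1
    assert nonzero[0] == pytest.approx(2.0, abs=1e-12)
    v = modes.eigenvectors[:, -1].reshape(2, 3)
    # displacement along x, antisymmetric
    np.testing.assert_allclose(np.abs(v[:, 0]), [np.sqrt(0.5)] * 2, atol=1e-9)
    np.testing.assert_allclose(v[:, 1:], 0.0, atol=1e-9)


def test_overlap_parallel_orthogonal_and_scale_invariance(hinge_particles):
    pos, _ = hinge_particles
    modes = compute_modes(assemble_hessian(build_network(pos, 16.0)))
    v7 = modes.eigenvectors[:, 6].reshape(-1, 3)
    res = overlap(modes, pos + 0.37 * v7, pos, superpose=False)
    assert res.best_mode_index == 6
    assert res.overlaps[6] == pytest.approx(1.0, abs=1e-9)
    # orthogonal mode sees zero
    assert res.overlaps[7] == pytest.approx(0.0, abs=1e-9)
    # scaling the displacement changes nothing
    res2 = overlap(modes, pos + 5.2 * v7, pos, superpose=False)
    assert res2.overlaps[6] == pytest.approx(1.0, abs=1e-9)


def test_overlap_zero_displacement_raises(hinge_particles):
    pos, _ = hinge_particles
    modes = compute_modes(assemble_hessian(build_network(pos, 16.0)))
    with pytest.raises(ValueError):
        overlap(modes, pos, pos)


def test_hinge_fixture_lowest_mode_overlap(hinge_particles):
    """The hinge displacement projects strongly onto the softest mode —
    the canonical low-frequency-mode picture of domain motions."""
    pos_open, pos_closed = hinge_particles
    res = best_overlap(pos_open, pos_closed, 16.0)
    assert res.best_mode_index == 6
    assert res.best_overlap > 0.8


def test_cutoff_scan_single_value_matches_direct_call(hinge_particles):
    pos_open, pos_closed = hinge_particles
    rows = cutoff_scan(pos_open, pos_closed, [16.0])
    direct = best_overlap(pos_open, pos_closed, 16.0)
    assert rows[0]["best_overlap"] == pytest.approx(direct.best_overlap)
    assert rows[0]["best_mode_index"] == direct.best_mode_index


def test_cutoff_scan_range_is_finite_and_complete(hinge_particles):
    pos_open, pos_closed = hinge_particles
    cutoffs = np.arange(12.0, 35.0, 1.0)
    rows = cutoff_scan(pos_open, pos_closed, cutoffs)
    assert len(rows) == len(cutoffs)
    vals = np.array([r["best_overlap"] for r in rows])
    assert np.all(np.isfinite(vals))
    assert np.all((vals >= 0) & (vals <= 1))
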