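"""6R forward/inverse kinematics and chain reconstruction."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tripath.geometry import rotation_error
from tripath.kinematics import (ChainKinematics, IKSolutionSet,
                                forward_kinematics, reconstruct_chain,
                                select_solution, solve_ik, wrap_angle)
from tripath.structure import (ca_rmsd, compute_particle_frames,
                               frame_of_residue)


@pytest.fixture(scope="module")
def kin(transition_pair):
    return ChainKinematics(transition_pair[0])


def test_forward_kinematics_reproduces_source_atoms(kin, transition_pair):
    """Torsions read off an existing tripeptide rebuild its atoms exactly."""
    conf = transition_pair[0]
    seeds = kin.seed_torsions()
    for i in (0, 5, kin.k - 2):
        r = kin.triples[i][0]
        R, o = frame_of_residue(conf, r)
        atoms, (eR, eo) = forward_kinematics(kin.tripeptides[i], seeds[i], R, o)
        for tag, res in ((1, r), (2, r + 1), (3, r + 2)):
            for nm in ("N", "CA", "C", "O"):
                np.testing.assert_allclose(
                    atoms[f"{nm}{tag}"], conf.atom_position(res, nm),
                    atol=1e-6)
        R_next, o_next = frame_of_residue(conf, r + 3)
        assert np.linalg.norm(eo - o_next) < 1e-6
        assert rotation_error(eR, R_next) < 1e-6


def test_forward_kinematics_equivariant_under_base_rotation(kin,
                                                            transition_pair):
    conf = transition_pair[0]
    seeds = kin.seed_torsions()
    R0, o0 = frame_of_residue(conf, kin.triples[2][0])
    atoms0, (eR0, eo0) = forward_kinematics(kin.tripeptides[2], seeds[2],
                                            R0, o0)
    Q = Rotation.from_euler("xyz", [0.7, -0.3, 1.9]).as_matrix()
    t = np.array([4.0, -1.0, 2.0])
    atoms1, (eR1, eo1) = forward_kinematics(kin.tripeptides[2], seeds[2],
                                            Q @ R0, Q @ o0 + t)
    for nm, pos in atoms0.items():
        np.testing.assert_allclose(atoms1[nm], Q @ pos + t, atol=1e-9)
    np.testing.assert_allclose(eo1, Q @ eo0 + t, atol=1e-9)
    np.testing.assert_allclose(eR1, Q @ eR0, atol=1e-9)


def test_solve_ik_finds_existing_closure(kin, transition_pair):
    conf = transition_pair[0]
    seeds = kin.seed_torsions()
    i = 4
    R, o = frame_of_residue(conf, kin.triples[i][0])
    Rn, on = frame_of_residue(conf, kin.triples[i][0] + 3)
    sols = solve_ik(kin.tripeptides[i], R, o, Rn, on)
    assert len(sols) >= 1
    dev = np.min(np.max(np.abs(wrap_angle(sols.torsions - seeds[i])), axis=1))
    assert dev < 1e-6


def test_solve_ik_unreachable_returns_empty(kin, transition_pair):
    conf = transition_pair[0]
    R, o = frame_of_residue(conf, kin.triples[0][0])
    far = o + np.array([50.0, 0.0, 0.0])
    sols = solve_ik(kin.tripeptides[0], R, o, R, far)
    assert len(sols) == 0


def test_solve_ik_fuzz_recovers_generating_torsions(kin, transition_pair):
    """Random reachable targets: every returned solution passes the
    forward-kinematics oracle and the generating torsions are recovered."""
    conf = transition_pair[0]
    rng = np.random.default_rng(42)
    for _ in range(25):
        i = int(rng.integers(0, kin.k - 1))
        g = kin.tripeptides[i]
        R, o = frame_of_residue(conf, kin.triples[i][0])
        tor = rng.uniform(-np.pi, np.pi, 6)
        _, (eR, eo) = forward_kinematics(g, tor, R, o)
        sols = solve_ik(g, R, o, eR, eo)
        assert len(sols) >= 1
        assert len(sols) <= 16
        for s in sols.torsions:
            _, (aR, ao) = forward_kinematics(g, s, R, o)
            assert np.linalg.norm(ao - eo) <= 1e-4
            assert rotation_error(aR, eR) <= 1e-4
        dev = np.min(np.max(np.abs(wrap_angle(sols.torsions - tor)), axis=1))
        assert dev < 1e-3


def test_select_solution_rules():
    prev = np.zeros(6)
    sols = IKSolutionSet(np.array([prev]), np.zeros(1))
    np.testing.assert_allclose(select_solution(sols, prev, 0.5), prev)

    lone = IKSolutionSet(np.array([np.full(6, 1.0)]), np.zeros(1))
    assert select_solution(lone, prev, 0.5) is None

    two = IKSolutionSet(np.array([np.full(6, 0.4), np.full(6, 0.1)]),
                        np.zeros(2))
    np.testing.assert_allclose(select_solution(two, prev, 0.5),
                               np.full(6, 0.1))

    empty = IKSolutionSet(np.empty((0, 6)), np.empty(0))
    assert select_solution(empty, prev, 0.5) is None


def test_reconstruct_round_trip_is_exact(kin, transition_pair):
    conf = transition_pair[0]
    state = compute_particle_frames(conf)
    res = reconstruct_chain(state, conf, kin=kin,
                            rng=np.random.default_rng(0))
    assert res.success
    assert res.n_perturbations == 0
    assert np.abs(res.conformation.coords - conf.coords).max() < 1e-9


def test_reconstruct_rigid_translation(kin, transition_pair):
    conf = transition_pair[0]
    state = compute_particle_frames(conf)
    shift = np.array([2.0, -1.0, 3.0])
    moved = state.with_origins(state.origins + shift)
    res = reconstruct_chain(moved, conf, kin=kin,
                            rng=np.random.default_rng(0))
    assert res.success
    np.testing.assert_allclose(res.conformation.coords, conf.coords + shift,
                               atol=1e-6)


def test_reconstruct_deterministic_for_solvable_frames(kin, transition_pair):
    conf = transition_pair[0]
    state = compute_particle_frames(conf)
    a = reconstruct_chain(state, conf, kin=kin, perturb_magnitude=(0.0, 0.0),
                          rng=np.random.default_rng(1))
    b = reconstruct_chain(state, conf, kin=kin, perturb_magnitude=(0.0, 0.0),
                          rng=np.random.default_rng(2))
    assert a.success and b.success
    np.testing.assert_array_equal(a.conformation.coords, b.conformation.coords)


def test_reconstruct_closure_residuals_within_tolerance(kin, transition_pair):
    """Every accepted segment closes onto the realized downstream frame
    within the position/orientation tolerances."""
    from tripath.planner import update_orientations
    from tripath.structure import CoarseState

    conf, goal = transition_pair
    s0 = compute_particle_frames(conf)
    sg = compute_particle_frames(goal)
    target = s0.origins + 0.02 * (sg.origins - s0.origins)
    rotations = update_orientations(s0.origins, target, s0.rotations)
    interp = CoarseState(target, rotations, s0.n_term_local, s0.c_term_local)
    res = reconstruct_chain(interp, conf, kin=kin, check_collisions=False,
                            rng=np.random.default_rng(3))
    assert res.success
    realized = res.state
    for i in range(kin.k - 1):
        _, (eR, eo) = forward_kinematics(kin.tripeptides[i], res.torsions[i],
                                         realized.rotations[i],
                                         realized.origins[i])
        assert np.linalg.norm(eo - realized.origins[i + 1]) <= 1e-4
        assert rotation_error(eR, realized.rotations[i + 1]) <= 1e-6
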