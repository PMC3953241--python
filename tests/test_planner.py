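"""Mode-biased sampling, tree metric, expansion and the outer loop."""
import numpy as np
import pytest

from tripath.collision import has_clash
from tripath.enm import assemble_hessian, build_network, compute_modes
from tripath.fixtures import make_hinge_pair, two_domain_spec
from tripath.kinematics import ChainKinematics
from tripath.planner import (PlannerConfig, TreeNode, biased_distance,
                             build_rrt, calibrated_amplification,
                             compute_pathway, expand, minimize_hook,
                             nearest_node, particle_rmsd, sample_random,
                             steric_penalty, update_orientations)
from tripath.structure import ca_rmsd, compute_particle_frames


@pytest.fixture(scope="module")
def planner_setup(transition_pair):
    o, goal = transition_pair
    kin = ChainKinematics(o)
    state = compute_particle_frames(o)
    modes = compute_modes(assemble_hessian(build_network(state.origins, 16.0)))
    return o, goal, kin, state, modes


class _FixedWeights:
    """rng stand-in handing out a prescribed weight vector."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def uniform(self, lo, hi, size=None):
        return self.w


def test_sample_random_zero_amplification_is_root(planner_setup):
    _, _, _, state, modes = planner_setup
    rng = np.random.default_rng(0)
    out = sample_random(state, modes, 0.0, rng)
    np.testing.assert_array_equal(out.origins, state.origins)


def test_sample_random_single_mode_linearity(planner_setup):
    """With w_j = delta_j7 the displacement is exactly f * a_7."""
    _, _, _, state, modes = planner_setup
    w = np.zeros(modes.scaled_modes.shape[1])
    w[0] = 1.0
    out = sample_random(state, modes, 2.5, _FixedWeights(w))
    expected = state.origins + 2.5 * modes.scaled_modes[:, 0].reshape(-1, 3)
    np.testing.assert_allclose(out.origins, expected, atol=1e-12)


def test_sample_random_is_centered(planner_setup):
    """Monte-Carlo mean displacement vanishes (symmetric weights)."""
    _, _, _, state, modes = planner_setup
    rng = np.random.default_rng(123)
    n = 10_000
    acc = np.zeros(state.origins.shape)
    sq = np.zeros(state.origins.shape)
    for _ in range(n):
        d = sample_random(state, modes, 1.0, rng).origins - state.origins
        acc += d
        sq += d * d
    mean = acc / n
    sigma = np.sqrt(sq / n)
    assert np.all(np.abs(mean) < 3 * sigma / np.sqrt(n) + 1e-12)


def test_calibrated_amplification_sets_rms_scale(planner_setup):
    _, _, _, state, modes = planner_setup
    f = calibrated_amplification(modes, 5.0)
    rng = np.random.default_rng(5)
    rms = np.mean([
        particle_rmsd(sample_random(state, modes, f, rng), state)
        for _ in range(300)])
    assert rms == pytest.approx(5.0, rel=0.25)


def test_biased_distance_arithmetic(planner_setup):
    _, _, _, state, _ = planner_setup

    class Fake:
        def __init__(self, origins):
            self.origins = origins

    n = state.n_frames
    base = np.zeros((n, 3))
    # RMSD(q,q_rand)=2, RMSD(q,q_goal)=3, RMSD(q_init,q_goal)=6 -> 1.0
    q = Fake(base)
    q_rand = Fake(base + [2.0, 0, 0])
    q_goal = Fake(base + [3.0, 0, 0])
    q_init = Fake(base + [-3.0, 0, 0])
    assert biased_distance(q, q_rand, q_goal, q_init) == pytest.approx(1.0)
    assert biased_distance(q, q, q_goal, q_init) == 0.0


def test_nearest_node_minimizes_biased_distance(planner_setup):
    o, goal, kin, state, modes = planner_setup
    goal_state = compute_particle_frames(goal)
    rng = np.random.default_rng(9)
    nodes = []
    for _ in range(12):
        s = state.with_origins(state.origins + rng.normal(size=(state.n_frames, 3)))
        nodes.append(TreeNode(s, o, None, None, np.nan))
    q_rand = sample_random(state, modes, 3.0, rng)
    idx = nearest_node(nodes, q_rand, goal_state, state)
    dists = [biased_distance(n.coarse, q_rand, goal_state, state)
             for n in nodes]
    assert idx == int(np.argmin(dists))


def test_update_orientations_exact_for_rigid_motion(planner_setup):
    from scipy.spatial.transform import Rotation
    _, _, _, state, _ = planner_setup
    R = Rotation.from_euler("xyz", [0.2, -0.5, 0.8]).as_matrix()
    t = np.array([1.0, 2.0, -3.0])
    new_origins = state.origins @ R.T + t
    new_rot = update_orientations(state.origins, new_origins, state.rotations)
    for a, b in zip(new_rot, state.rotations):
        np.testing.assert_allclose(a, R @ b, atol=1e-9)


def test_expand_zero_step_returns_near_node(planner_setup):
    o, goal, kin, state, _ = planner_setup
    cfg = PlannerConfig(seed=0)
    root = TreeNode(state, o, None, kin.seed_torsions(), ca_rmsd(o, goal))
    node, reason = expand(root, state, cfg.step_size, kin, cfg,
                          np.random.default_rng(0))
    assert reason is None
    assert np.abs(node.allatom.coords - o.coords).max() < 1e-6


def test_expand_full_step_reaches_nearby_target(planner_setup):
    o, goal, kin, state, _ = planner_setup
    cfg = PlannerConfig(seed=0)
    target = state.with_origins(state.origins + 0.05)
    root = TreeNode(state, o, None, kin.seed_torsions(), ca_rmsd(o, goal))
    node, reason = expand(root, target, 1.0, kin, cfg,
                          np.random.default_rng(0))
    assert reason is None
    # origins reach the requested target up to the snap tolerance
    assert np.linalg.norm(node.coarse.origins - target.origins,
                          axis=1).max() <= cfg.ik_snap_position + 1e-9


def test_build_rrt_fixed_seed_is_reproducible(planner_setup):
    o, goal, kin, state, modes = planner_setup
    goal_state = compute_particle_frames(goal)
    cfg = PlannerConfig(seed=0, rrt_max_iters=30)
    root = TreeNode(state, o, None, kin.seed_torsions(), ca_rmsd(o, goal))
    runs = []
    for _ in range(2):
        nodes, stats = build_rrt(root, goal, goal_state, modes, kin, cfg,
                                 np.random.default_rng(7), 0.3, state)
        runs.append((len(nodes), stats.iterations,
                     np.concatenate([n.coarse.origins.ravel() for n in nodes])))
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]
    np.testing.assert_array_equal(runs[0][2], runs[1][2])


def test_minimize_hook_none_is_identity(planner_setup):
    o, _, kin, _, _ = planner_setup
    assert minimize_hook(o, kin, mode="none") is o


def test_minimize_hook_never_introduces_clashes(planner_setup):
    o, _, kin, _, _ = planner_setup
    for mode in ("relief", "penalty"):
        out = minimize_hook(o, kin, mode=mode, relief=1.3,
                            rng=np.random.default_rng(0))
        assert not has_clash(out, kin.steric_model, kin.exclusions)[0]


def test_minimize_hook_penalty_descends(planner_setup):
    """Penalty mode strictly reduces the near-contact penalty on a fixture
    with engaged soft contacts."""
    o, _, kin, _, _ = planner_setup
    relief = 1.3
    pen0 = steric_penalty(o, kin.steric_model, kin.exclusions, kin.radii,
                          relief=relief)
    assert pen0 > 0
    out = minimize_hook(o, kin, mode="penalty", relief=relief)
    pen1 = steric_penalty(out, kin.steric_model, kin.exclusions, kin.radii,
                          relief=relief)
    assert pen1 <= pen0


def test_compute_pathway_identical_endpoints(planner_setup):
    o, _, _, _, _ = planner_setup
    path = compute_pathway(o, o, PlannerConfig(seed=0))
    assert path.status == "converged"
    assert path.outer_iterations == 0
    assert len(path) == 1


def test_compute_pathway_residue_mismatch_raises(planner_setup, helix30):
    o, _, _, _, _ = planner_setup
    with pytest.raises(ValueError):
        compute_pathway(o, helix30, PlannerConfig(seed=0))


def test_compute_pathway_small_fixture_converges_and_validates():
    """End-to-end on a small hinge pair: converges, and every conformation
    on the path is clash-free with exact backbone geometry."""
    o, goal = make_hinge_pair(two_domain_spec(54, np.deg2rad(35.0)))
    cfg = PlannerConfig(d_target=0.8, seed=0, max_outer_iters=25)
    path = compute_pathway(o, goal, cfg)
    assert path.status == "converged"
    assert path.ca_rmsd_to_goal[-1] <= 0.8
    kin = ChainKinematics(o)
    from tripath.internal import ChainGeometry
    ref = ChainGeometry.from_conformation(o)
    for conf in path.conformations:
        assert not has_clash(conf, kin.steric_model, kin.exclusions)[0]
        g = ChainGeometry.from_conformation(conf)
        np.testing.assert_allclose(g.b_nca, ref.b_nca, atol=1e-6)
        np.testing.assert_allclose(g.b_cac, ref.b_cac, atol=1e-6)
        np.testing.assert_allclose(g.b_cn[:-1], ref.b_cn[:-1], atol=1e-6)
        from tripath.kinematics import wrap_angle
        np.testing.assert_allclose(
            wrap_angle(g.omega[:-1] - ref.omega[:-1]), 0.0, atol=1e-6)
    # per-step particle displacement bounded by the expansion scale
    disp = path.residue_displacements
    assert disp is not None and disp.shape[1] == o.n_residues
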