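"""Mode-biased RRT exploration and the iterative transition-path finder.

The planner alternates between two levels. The outer loop recomputes
coarse-grained normal modes at the current root conformation, runs a short
RRT exploration biased by those modes until the protein has progressed a set
C-alpha-RMSD toward the goal, extracts the tree node closest to the goal,
passes it through the relaxation hook and makes it the next root. The inner
RRT samples coarse states as random linear combinations of scaled modes,
finds the nearest tree node under a goal-biased distance, and expands it by a
small interpolation step; every accepted node is rebuilt at the all-atom
level by inverse kinematics and checked for steric clashes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .collision import StericModel
from .enm import NormalModeSet, assemble_hessian, build_network, compute_modes
from .kinematics import ChainKinematics, reconstruct_chain
from .structure import CoarseState, ProteinConformation, ca_rmsd, \
    compute_particle_frames


@dataclass
class PlannerConfig:
    """Tunable parameters of the transition-path search.

    Distances in Angstrom, angles in radians. The RRT progress goal is
    reduced from ``rrt_progress_goal`` to ``rrt_progress_goal_final`` once the
    remaining distance to the goal falls below ``progress_switch_fraction``
    of the initial distance (convergence slows near the goal and more
    frequent mode recomputation helps).
    """

    d_cut: float = 16.0                      # ENM cutoff
    elastic_constant: float = 1.0
    amplification: float = 5.0               # f of the mode sampler
    step_size: float = 0.1                   # k, fraction per expansion
    d_target: float = 1.5                    # outer-loop stop distance
    rrt_progress_goal: float = 0.3
    rrt_progress_goal_final: float = 0.15
    progress_switch_fraction: float = 0.25
    rrt_max_iters: int = 4000
    max_outer_iters: int = 200
    outer_stall_limit: int = 10
    ik_max_trials: int = 4
    ik_perturb_position: float = 0.1
    ik_perturb_orientation: float = 0.02
    ik_clash_alternatives: bool = False      # enumerate IK branches on clash
    ik_snap_position: float = 0.2
    ik_snap_orientation: float = 0.1
    solution_threshold: float = 0.5
    goal_bias: float = 0.1                   # fraction of samples at the goal
    amplitude: str = "inverse_eigenvalue"
    minimize_mode: str = "relief"            # "none" | "relief" | "penalty"
    minimize_relief: float = 1.05            # near-contact relief factor
    minimize_max_shift: float = 0.15         # cap on hook displacement, A
    steric_buffer: float = 1.0               # planning-time clash-limit factor
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.step_size <= 1.0):
            raise ValueError("step_size must be in (0, 1]")
        for name in ("d_cut", "amplification", "d_target", "rrt_progress_goal",
                     "rrt_progress_goal_final", "rrt_max_iters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TreeNode:
    coarse: CoarseState
    allatom: ProteinConformation
    parent: int | None
    torsions: np.ndarray | None          # per-tripeptide IK cache
    ca_rmsd_to_goal: float


@dataclass
class RRTStats:
    iterations: int = 0
    ik_failures: int = 0
    clash_rejections: int = 0
    n_nodes: int = 1
    stopped_by: str = ""


@dataclass
class TransitionPath:
    """Ordered conformations of one transition, with per-step metrics."""

    conformations: list                      # [q_init, q_1, ..., q_final]
    ca_rmsd_to_goal: list                    # per conformation
    residue_displacements: np.ndarray | None # (n_steps, n_res) per-step CA moves
    status: str = "converged"
    outer_iterations: int = 0
    seed: int | None = None
    rrt_stats: list = field(default_factory=list)

    def __len__(self):
        return len(self.conformations)


# ---------------------------------------------------------------------------
# Elementary planner operations
# ---------------------------------------------------------------------------

def calibrated_amplification(modes: NormalModeSet, target_rms: float) -> float:
    """Amplification factor f such that a typical mode mix has a set size.

    The scaled modes a_j = v_j / lambda_j have norms governed by the lowest
    eigenvalue, which varies by orders of magnitude between systems; a fixed
    f would make the sampled displacement either negligible or absurd. f is
    therefore chosen once per mode set so that the root-mean-square
    per-particle displacement of a random draw (weights uniform in [-1, 1],
    variance 1/3) equals ``target_rms`` Angstrom. The sampling law itself
    stays the plain linear combination with a single constant f.
    """
    n_particles = modes.scaled_modes.shape[0] // 3
    mean_sq = np.sum(modes.scaled_modes ** 2) / 3.0
    return float(target_rms / np.sqrt(mean_sq / n_particles))


def sample_random(root: CoarseState, modes: NormalModeSet,
                  amplification: float, rng: np.random.Generator
                  ) -> CoarseState:
    """Random coarse state: particle origins displaced by a random mode mix.

    Each non-rigid scaled mode a_j receives an independent weight
    w_j ~ U[-1, 1]; origins move by ``amplification * sum w_j a_j`` while
    orientations are carried over from the root. The sample need not be a
    feasible conformation — it only steers the tree.
    """
    w = rng.uniform(-1.0, 1.0, modes.scaled_modes.shape[1])
    disp = amplification * (modes.scaled_modes @ w)
    return root.with_origins(root.origins + disp.reshape(-1, 3))


def particle_rmsd(a, b) -> float:
    """Unsuperposed RMSD of particle origins (the planner's native metric).

    Modes and interpolation act in the fixed laboratory frame, so no
    superposition is applied here.
    """
    pa = np.asarray(getattr(a, "origins", a))
    pb = np.asarray(getattr(b, "origins", b))
    return geometry.rmsd(pa, pb)


def biased_distance(q: CoarseState, q_rand: CoarseState, q_goal: CoarseState,
                    q_init: CoarseState) -> float:
    """Goal-biased tree metric RMSD(q,q_rand)*RMSD(q,q_goal)/RMSD(q_init,q_goal).

    Nodes close to the goal look closer to every sample, pulling the
    exploration toward the target conformation.
    """
    return (particle_rmsd(q, q_rand) * particle_rmsd(q, q_goal)
            / particle_rmsd(q_init, q_goal))


def nearest_node(nodes: list[TreeNode], q_rand: CoarseState,
                 q_goal: CoarseState, q_init: CoarseState) -> int:
    """Exact brute-force nearest neighbor under the biased distance."""
    d_norm = particle_rmsd(q_init, q_goal)
    origins = np.stack([n.coarse.origins for n in nodes])
    d_rand = np.sqrt(np.mean(np.sum(
        (origins - q_rand.origins) ** 2, axis=-1), axis=-1))
    d_goal = np.sqrt(np.mean(np.sum(
        (origins - q_goal.origins) ** 2, axis=-1), axis=-1))
    return int(np.argmin(d_rand * d_goal / d_norm))


def update_orientations(old_origins: np.ndarray, new_origins: np.ndarray,
                        old_rotations: np.ndarray, window: int = 2
                        ) -> np.ndarray:
    """Rotate each particle frame by its neighbourhood's best-fit rotation.

    For every frame, the optimal (Kabsch) rotation mapping the old origins of
    the surrounding ``window`` frames onto the new ones is applied to the old
    orientation. A rigidly moving domain therefore carries its frames rigidly
    — the inter-frame relative poses are preserved and the previous torsions
    still close the 6R segments exactly — while frames inside a genuine hinge
    receive the local average rotation. Without this update every domain
    rotation would be absorbed as internal segment shear, degrading local
    backbone geometry step by step.
    """
    from scipy.spatial.transform import Rotation

    k = len(old_origins)
    new_rotations = np.empty_like(old_rotations)
    for f in range(k):
        lo = max(0, f - window)
        hi = min(k, f + window + 1)
        a = old_origins[lo:hi] - old_origins[f]
        b = new_origins[lo:hi] - new_origins[f]
        rot, _ = Rotation.align_vectors(b, a)
        new_rotations[f] = rot.as_matrix() @ old_rotations[f]
    return new_rotations


def expand(q_near: TreeNode, q_rand: CoarseState, step_size: float,
           kin: ChainKinematics, cfg: PlannerConfig,
           rng: np.random.Generator, steric_scale: float | None = None):
    """One tree expansion: interpolate origins toward the sample and rebuild.

    ``steric_scale`` optionally overrides the clash limit used during
    planning (a small buffer above the hard limit keeps the tree from hugging
    the steric boundary, where almost every further move would clash).
    Returns (node, failure_reason); ``failure_reason`` is None on success,
    "ik" or "clash" otherwise.
    """
    target = q_near.coarse.origins + step_size * (q_rand.origins
                                                  - q_near.coarse.origins)
    rotations = update_orientations(q_near.coarse.origins, target,
                                    q_near.coarse.rotations)
    state = CoarseState(target, rotations, q_near.coarse.n_term_local,
                        q_near.coarse.c_term_local)
    result = reconstruct_chain(
        state, q_near.allatom, kin=kin, seed_torsions=q_near.torsions,
        perturb_magnitude=(cfg.ik_perturb_position, cfg.ik_perturb_orientation),
        max_trials=cfg.ik_max_trials,
        solution_threshold=cfg.solution_threshold,
        snap_tolerance=(cfg.ik_snap_position, cfg.ik_snap_orientation),
        steric_scale=steric_scale,
        clash_alternatives=cfg.ik_clash_alternatives, rng=rng)
    if not result.success:
        reason = "clash" if "collision" in result.status else "ik"
        return None, reason
    node = TreeNode(result.state, result.conformation, None, result.torsions,
                    np.nan)
    return node, None


def build_rrt(root_node: TreeNode, q_goal_conf: ProteinConformation,
              q_goal_state: CoarseState, modes: NormalModeSet,
              kin: ChainKinematics, cfg: PlannerConfig,
              rng: np.random.Generator, progress_goal: float,
              q_init_state: CoarseState, steric_scale: float | None = None):
    """Mode-biased RRT from one root until the progress goal or iteration cap.

    Returns (nodes, stats). Every node holds a collision-free, closure-valid
    all-atom conformation.
    """
    root_rmsd = root_node.ca_rmsd_to_goal
    nodes = [root_node]
    stats = RRTStats()
    # near the goal, samples scale with the remaining motion: a draw much
    # larger than the leftover displacement would steer almost every step
    # off-target
    target_rms = min(cfg.amplification, max(1.0, 2.0 * root_rmsd))
    f_eff = calibrated_amplification(modes, target_rms)
    for it in range(cfg.rrt_max_iters):
        stats.iterations = it + 1
        if rng.uniform() < cfg.goal_bias:
            q_rand = q_goal_state
        else:
            q_rand = sample_random(root_node.coarse, modes, f_eff, rng)
        near_idx = nearest_node(nodes, q_rand, q_goal_state, q_init_state)
        node, reason = expand(nodes[near_idx], q_rand, cfg.step_size, kin,
                              cfg, rng, steric_scale=steric_scale)
        if node is None:
            if reason == "clash":
                stats.clash_rejections += 1
            else:
                stats.ik_failures += 1
            continue
        node.parent = near_idx
        node.ca_rmsd_to_goal = ca_rmsd(node.allatom, q_goal_conf)
        nodes.append(node)
        if node.ca_rmsd_to_goal <= root_rmsd - progress_goal:
            stats.stopped_by = "progress"
            break
    else:
        stats.stopped_by = "max_iters"
    stats.n_nodes = len(nodes)
    return nodes, stats


def _min_margin(conf: ProteinConformation, kin: ChainKinematics) -> float:
    """Smallest distance / clash-limit ratio over non-excluded atom pairs."""
    coords = conf.coords
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    lim = kin.steric_model.scale * (kin.radii[:, None] + kin.radii[None, :])
    ratio = d / lim
    np.fill_diagonal(ratio, np.inf)
    for i, j in kin.exclusions:
        ratio[i, j] = ratio[j, i] = np.inf
    return float(ratio.min())


def segment_torsions(conf: ProteinConformation, kin: ChainKinematics
                     ) -> np.ndarray:
    """Per-tripeptide torsion 6-vectors of an arbitrary conformation."""
    from .internal import ChainGeometry
    g = ChainGeometry.from_conformation(conf)
    out = np.empty((kin.k - 1, 6))
    for i, (r, _, _) in enumerate(kin.triples[:-1]):
        out[i] = [g.psi[r], g.phi[r + 1], g.psi[r + 1],
                  g.phi[r + 2], g.psi[r + 2], g.phi[r + 3]]
    return out


def closest_to_target(nodes: list[TreeNode], q_goal_state: CoarseState) -> int:
    """Tree node with minimum (plain) particle RMSD to the goal state."""
    d = [particle_rmsd(n.coarse, q_goal_state) for n in nodes]
    return int(np.argmin(d))


# ---------------------------------------------------------------------------
# Relaxation hook
# ---------------------------------------------------------------------------

def steric_penalty(conf: ProteinConformation, model: StericModel,
                   exclusions: set, radii: np.ndarray,
                   relief: float = 1.0) -> float:
    """Sum of squared pair overlaps below ``relief`` times the clash limit.

    ``relief = 1`` counts only true clashes; ``relief > 1`` also penalizes
    near-contacts, turning the penalty into a clash-relief objective.
    """
    coords = conf.coords
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    lim = relief * model.scale * (radii[:, None] + radii[None, :])
    over = np.maximum(lim - d, 0.0)
    np.fill_diagonal(over, 0.0)
    for i, j in exclusions:
        over[i, j] = over[j, i] = 0.0
    return float(np.sum(np.triu(over, 1) ** 2))


def _tight_pairs(conf: ProteinConformation, kin: ChainKinematics,
                 relief: float):
    """Non-excluded atom pairs closer than ``relief`` times the clash limit."""
    coords = conf.coords
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    lim = kin.steric_model.scale * (kin.radii[:, None] + kin.radii[None, :])
    iu = np.triu_indices(conf.n_atoms, k=1)
    close = d[iu] < relief * lim[iu]
    pairs = []
    for i, j in zip(iu[0][close], iu[1][close]):
        if frozenset((int(i), int(j))) not in kin.exclusions:
            pairs.append((int(i), int(j), float(d[i, j]),
                          float(relief * lim[i, j])))
    return pairs


def _restore_segments(conf: ProteinConformation, kin: ChainKinematics,
                      state: CoarseState, relief: float,
                      rng: np.random.Generator):
    """Pull drifted inter-frame poses back toward the reference conformation.

    The coarse frames pin only every third residue, and with the frames fixed
    the torsions in between have no continuous freedom: local-geometry drift
    (which squeezes backbone contacts such as helical O(i)-N(i+2) pairs)
    lives in the relative poses of consecutive particles. For each segment
    involved in a tight contact, the downstream particle is moved part-way
    toward the relative pose it has in the reference structure — rigid
    domains should keep their native internal poses — and the chain is
    rebuilt. Accepted only when the steric margin improves without a true
    clash; retried with smaller fractions when it backfires.
    """
    from scipy.spatial.transform import Rotation
    from .collision import has_clash

    pairs = _tight_pairs(conf, kin, relief)
    if not pairs:
        return conf
    segs = sorted({f for i, j, _, _ in pairs
                   for f in (kin.frame_of_atom(i), kin.frame_of_atom(j))
                   if f < kin.k - 1})
    if not segs:
        return conf
    ref_state = compute_particle_frames(kin.reference)
    current = conf
    margin = _min_margin(current, kin)
    seeds = segment_torsions(conf, kin)

    k = state.n_frames
    rel_cur, rel_ref = [], []
    for f in range(k - 1):
        rel_cur.append((state.rotations[f].T @ state.rotations[f + 1],
                        state.rotations[f].T @ (state.origins[f + 1]
                                                - state.origins[f])))
        rel_ref.append((ref_state.rotations[f].T @ ref_state.rotations[f + 1],
                        ref_state.rotations[f].T @ (ref_state.origins[f + 1]
                                                    - ref_state.origins[f])))

    for eta in (0.4, 0.2, 0.1):
        # rebuild the frame chain with the offending segments' relative poses
        # interpolated toward the reference; all other segments keep their
        # current relative pose, so the downstream structure rides along
        # coherently instead of being squeezed between inconsistent frames
        new_R = state.rotations.copy()
        new_o = state.origins.copy()
        for f in range(k - 1):
            R_c, t_c = rel_cur[f]
            if f in segs:
                R_r, t_r = rel_ref[f]
                dR = Rotation.from_matrix(R_c.T @ R_r).as_rotvec()
                R_t = R_c @ Rotation.from_rotvec(eta * dR).as_matrix()
                t_t = (1 - eta) * t_c + eta * t_r
            else:
                R_t, t_t = R_c, t_c
            new_R[f + 1] = new_R[f] @ R_t
            new_o[f + 1] = new_o[f] + new_R[f] @ t_t
        trial_state = CoarseState(new_o, new_R, state.n_term_local,
                                  state.c_term_local)
        res = reconstruct_chain(trial_state, current, kin=kin,
                                seed_torsions=seeds, check_collisions=False,
                                rng=rng)
        if not res.success:
            continue
        clash, _ = has_clash(res.conformation, kin.steric_model,
                             kin.exclusions)
        if clash:
            continue
        if geometry.rmsd(res.conformation.backbone("CA"),
                         current.backbone("CA")) > 1.0:
            continue
        new_margin = _min_margin(res.conformation, kin)
        if new_margin > margin + 1e-6:
            return res.conformation
    return current


def _relief_hook(conf: ProteinConformation, kin: ChainKinematics,
                 relief: float, rng: np.random.Generator,
                 max_rounds: int = 4) -> ProteinConformation:
    """Clash relief at an outer-iteration root.

    Two mechanisms, both bounded and accepted only when the global steric
    margin improves without introducing a true clash: (1) re-anchoring of
    drifted segment torsions toward the reference conformation (see
    :func:`_reanchor_segments`); (2) directed particle pushes — the frames
    owning a tight atom pair move apart along the pair axis (intra-segment
    contacts instead stretch the segment via its downstream frame), the chain
    is rebuilt, and the push is halved and retried when it backfires. The
    input conformation is returned when no improvement is possible.
    """
    from .collision import has_clash

    current = conf
    best_ratio = _min_margin(current, kin)
    for _ in range(max_rounds):
        pairs = _tight_pairs(current, kin, relief)
        if not pairs:
            break
        state = compute_particle_frames(current)
        # first choice: restore drifted local geometry toward the reference
        restored = _restore_segments(current, kin, state, relief, rng)
        new_ratio = _min_margin(restored, kin)
        if new_ratio > best_ratio + 1e-6:
            current = restored
            best_ratio = new_ratio
            continue
        # fall back to directed particle pushes along the tight-pair axes
        seeds = segment_torsions(current, kin)
        shift = np.zeros_like(state.origins)
        k = state.n_frames
        for i, j, d, lim in pairs:
            axis = current.coords[i] - current.coords[j]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            axis /= norm
            delta = min(0.5 * (lim - d) + 0.02, 0.1)
            fi = kin.frame_of_atom(i)
            fj = kin.frame_of_atom(j)
            if fi != fj:
                shift[fi] += delta * axis
                shift[fj] -= delta * axis
            elif fi < k - 1:
                # intra-segment contact: stretch the segment by moving its
                # downstream frame outward along the inter-frame axis
                stretch = state.origins[fi + 1] - state.origins[fi]
                stretch = stretch / max(np.linalg.norm(stretch), 1e-9)
                shift[fi + 1] += 2.0 * delta * stretch
        accepted = False
        if np.any(shift):
            scale_try = 1.0
            for _ in range(3):
                trial_state = state.with_origins(
                    state.origins + scale_try * shift)
                res = reconstruct_chain(trial_state, current, kin=kin,
                                        seed_torsions=seeds,
                                        check_collisions=False, rng=rng)
                if res.success:
                    clash, _ = has_clash(res.conformation, kin.steric_model,
                                         kin.exclusions)
                    if not clash:
                        new_ratio = _min_margin(res.conformation, kin)
                        if new_ratio > best_ratio + 1e-6:
                            current = res.conformation
                            best_ratio = new_ratio
                            accepted = True
                            break
                scale_try *= 0.5
        if not accepted:
            break
    return current


def minimize_hook(conf: ProteinConformation, kin: ChainKinematics,
                  mode: str = "none", relief: float = 1.05,
                  n_steps: int = 25, max_shift: float = 0.15,
                  rng: np.random.Generator | None = None
                  ) -> ProteinConformation:
    """Relaxation stand-in applied to each outer-iteration root.

    ``"none"`` returns the conformation unchanged. ``"penalty"`` runs a short
    torsion-space steepest descent on the steric near-contact penalty (pairs
    closer than ``relief`` times the clash limit): accepted conformations tend
    to hug the hard-sphere boundary, which makes most subsequent expansion
    steps clash; relieving the tightest contacts restores room to move, the
    geometric analogue of the short energy minimization between explorations.
    Moves act on free torsions only and are accepted only when the penalty
    decreases, so the hook never introduces clashes or bond-geometry
    violations (the input conformation is returned unchanged if no relief is
    possible). The total displacement is capped at ``max_shift`` C-alpha RMSD
    so relief can never cancel the progress made by the exploration.
    """
    if mode == "none":
        return conf
    if mode == "relief":
        return _relief_hook(conf, kin, relief, rng or np.random.default_rng())
    if mode != "penalty":
        raise ValueError(f"unknown minimize mode: {mode}")
    from .internal import ChainGeometry, build_chain

    model = kin.steric_model
    radii = kin.radii
    coords = conf.coords
    # near-contact pair list, tracked with a buffer so descent stays valid
    dmat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    lim = model.scale * (radii[:, None] + radii[None, :])
    iu = np.triu_indices(conf.n_atoms, k=1)
    close = dmat[iu] < (relief + 0.1) * lim[iu]
    pairs = [(int(i), int(j)) for i, j in zip(iu[0][close], iu[1][close])
             if frozenset((int(i), int(j))) not in kin.exclusions]
    if not pairs:
        return conf
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    plim = relief * model.scale * (radii[pi] + radii[pj])

    def penalty(c):
        d = np.linalg.norm(c.coords[pi] - c.coords[pj], axis=1)
        return float(np.sum(np.maximum(plim - d, 0.0) ** 2))

    geom = ChainGeometry.from_conformation(conf)
    R0, o0 = geometry.frame_from_atoms(
        conf.atom_position(0, "N"), conf.atom_position(0, "CA"),
        conf.atom_position(0, "C"))
    phi, psi = geom.phi.copy(), geom.psi.copy()
    pen = penalty(conf)
    if pen == 0.0:
        return conf

    # torsions near the offending pairs are the only effective variables
    res_set: set[int] = set()
    d0 = np.linalg.norm(coords[pi] - coords[pj], axis=1)
    for (i, j), dist, limit in zip(pairs, d0, plim):
        if dist < limit:
            for a in (i, j):
                r = int(conf.residue_index[a])
                res_set.update(range(max(0, r - 2),
                                     min(geom.n_residues, r + 3)))
    active = sorted(res_set)

    current = conf
    ca_ref = conf.backbone("CA")
    step = 0.01
    eps = 1e-4
    n = geom.n_residues
    for _ in range(n_steps):
        if pen == 0.0:
            break
        grad_phi = np.zeros(n)
        grad_psi = np.zeros(n)
        for i in active:
            if i > 0:
                phi[i] += eps
                grad_phi[i] = (penalty(build_chain(geom, phi, psi, R0, o0))
                               - pen) / eps
                phi[i] -= eps
            if i < n - 1:
                psi[i] += eps
                grad_psi[i] = (penalty(build_chain(geom, phi, psi, R0, o0))
                               - pen) / eps
                psi[i] -= eps
        norm = np.sqrt(np.sum(grad_phi ** 2) + np.sum(grad_psi ** 2))
        if norm < 1e-12:
            break
        improved = False
        s = step
        for _ in range(6):
            phi_t = phi - s * grad_phi / norm
            psi_t = psi - s * grad_psi / norm
            trial = build_chain(geom, phi_t, psi_t, R0, o0)
            pen_t = penalty(trial)
            shift = geometry.rmsd(trial.backbone("CA"), ca_ref)
            if pen_t < pen and shift <= max_shift:
                phi, psi, pen, current = phi_t, psi_t, pen_t, trial
                improved = True
                break
            s *= 0.5
        if not improved:
            break
    if current is not conf:
        from .collision import has_clash
        clash, _ = has_clash(current, model, kin.exclusions)
        if clash:
            return conf
    return current


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------

def compute_pathway(q_init: ProteinConformation, q_goal: ProteinConformation,
                    cfg: PlannerConfig | None = None,
                    progress_callback=None) -> TransitionPath:
    """Iterative NMA -> RRT -> extract -> relax transition-path search.

    Stops when the superposed C-alpha RMSD to the goal drops below
    ``cfg.d_target``, when no progress has been made for
    ``cfg.outer_stall_limit`` outer iterations (partial path, status
    "stalled"), or at ``cfg.max_outer_iters`` (status "max_iters").
    """
    cfg = cfg or PlannerConfig()
    if q_init.n_residues != q_goal.n_residues:
        raise ValueError("conformations differ in residue count")
    rng = np.random.default_rng(cfg.seed)
    kin = ChainKinematics(q_init, steric_model=StericModel())

    d0 = ca_rmsd(q_init, q_goal)
    if d0 <= cfg.d_target:
        return TransitionPath([q_init], [d0], None, "converged", 0, cfg.seed)

    path = [q_init]
    rmsds = [d0]
    displacements = []
    stats_log = []
    status = "converged"

    q_init_state = compute_particle_frames(q_init)
    q_goal_state = compute_particle_frames(q_goal)
    root_conf = q_init
    root_state = q_init_state
    root_torsions = kin.seed_torsions()

    # planning-time steric scale: a small buffer above the hard clash limit,
    # capped by what the endpoint structures themselves satisfy
    base_scale = kin.steric_model.scale
    endpoint_margin = min(_min_margin(q_init, kin), _min_margin(q_goal, kin))
    buffer = float(np.clip(0.98 * endpoint_margin, 1.0, cfg.steric_buffer))
    plan_scale = base_scale * buffer
    best_rmsd = d0
    stall = 0
    outer = 0

    while True:
        d_now = rmsds[-1]
        if d_now <= cfg.d_target:
            status = "converged"
            break
        if outer >= cfg.max_outer_iters:
            status = "max_iters"
            break
        if stall >= cfg.outer_stall_limit:
            status = "stalled"
            break
        outer += 1

        net = build_network(root_state.origins, cfg.d_cut,
                            cfg.elastic_constant)
        modes = compute_modes(assemble_hessian(net), amplitude=cfg.amplitude)
        progress_goal = (cfg.rrt_progress_goal
                         if d_now > cfg.progress_switch_fraction * d0
                         else cfg.rrt_progress_goal_final)
        root_node = TreeNode(root_state, root_conf, None, root_torsions, d_now)
        nodes, stats = build_rrt(root_node, q_goal, q_goal_state, modes, kin,
                                 cfg, rng, progress_goal, q_init_state,
                                 steric_scale=plan_scale)
        stats_log.append(stats)
        q_close = nodes[closest_to_target(nodes, q_goal_state)]

        relaxed = minimize_hook(q_close.allatom, kin, mode=cfg.minimize_mode,
                                relief=cfg.minimize_relief,
                                max_shift=cfg.minimize_max_shift, rng=rng)
        d_new = ca_rmsd(relaxed, q_goal)
        displacements.append(np.linalg.norm(
            relaxed.backbone("CA") - path[-1].backbone("CA"), axis=1))
        path.append(relaxed)
        rmsds.append(d_new)
        if progress_callback is not None:
            progress_callback(outer, d_new, stats)

        if d_new < best_rmsd - 1e-6:
            best_rmsd = d_new
            stall = 0
        else:
            stall += 1

        root_conf = relaxed
        if cfg.minimize_mode == "none" or relaxed is q_close.allatom:
            root_state = q_close.coarse
            root_torsions = q_close.torsions
        else:
            root_state = compute_particle_frames(relaxed)
            root_torsions = segment_torsions(relaxed, kin)

    return TransitionPath(path, rmsds,
                          np.array(displacements) if displacements else None,
                          status, outer, cfg.seed, stats_log)


def write_report(path: TransitionPath, out) -> None:
    """Long-format TSV: per-iteration RMSD plus per-residue displacements."""
    with open(out, "w") as fh:
        fh.write("record\touter_iteration\tresidue\tvalue\n")
        for it, r in enumerate(path.ca_rmsd_to_goal):
            fh.write(f"ca_rmsd_to_goal\t{it}\t\t{r:.4f}\n")
        if path.residue_displacements is not None:
            for it, row in enumerate(path.residue_displacements, start=1):
                for res, d in enumerate(row):
                    fh.write(f"displacement\t{it}\t{res}\t{d:.4f}\n")
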