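# Methods

`tripath` computes large-amplitude conformational transition paths between
two experimentally determined conformations of a protein. It combines three
components: normal mode analysis (NMA) of a coarse-grained elastic network
built on tripeptides, a Rapidly-exploring Random Tree (RRT) planner whose
sampling is biased by those modes, and an all-atom backbone reconstruction by
6R inverse kinematics (IK) with hard-sphere collision checking. This note
records the model, its assumptions, the numerical choices, and the design
decisions taken where the problem was genuinely open.

## Multi-scale model

**Tripeptide particles.** The chain is split into consecutive tripeptides
(floor rule: `n mod 3` leftover residues go `floor(r/2)` to the N terminus,
the rest to the C terminus; a 214-residue chain gives 71 tripeptides plus one
C-terminal leftover). Each tripeptide carries one oriented particle: origin
at the N atom of its first residue, orientation the Gram-Schmidt triad of the
N→CA and N→C directions of that residue. With fixed bond lengths, bond
angles and peptide torsions ω, the backbone between two consecutive
particles has exactly six free torsions

    (ψ_r, φ_{r+1}, ψ_{r+1}, φ_{r+2}, ψ_{r+2}, φ_{r+3})

for a tripeptide starting at residue r — a 6R revolute chain with at most 16
closure solutions. (Because the frame triad uses the residue's own carbonyl
C, the base frame already fixes φ_r; the closure's six unknowns are shifted
by one torsion relative to the naive (φ,ψ)×3 reading. The substance — a 6R
problem per tripeptide — is unchanged.) The final tripeptide has no
downstream particle to close against and rides rigidly on its own frame,
merged with the C-terminal leftover; the N-terminal leftover rides on the
first frame.

Bond lengths, angles, ω torsions, carbonyl-O and CB placement parameters are
frozen at the *input* values rather than idealized, which makes the
coarse-grain/reconstruct round trip exact to machine precision.

## Elastic network and modes

Particles closer than a cutoff `d_cut` (default 16 Å for the tripeptide
model, 8 Å for the one-particle-per-residue comparison model) are joined by
harmonic springs, E = Σ C/2 (d_ij − d⁰_ij)². The anisotropic-network Hessian
has off-diagonal blocks −(C/d⁰²)(r_j−r_i)(r_j−r_i)ᵀ and diagonal blocks equal
to minus the row sum; it is symmetric positive semidefinite with exactly six
zero eigenvalues for a connected network. The elastic constant C defaults
to 1: mode directions and overlaps are independent of C.

**Overlap.** The agreement between a mode and an observed conformational
change is the absolute cosine between the 3n-dimensional displacement Δq and
the mode vector. The closed conformation's particles are first rigidly
superposed onto the open ones: eigenvectors are orthogonal to the rigid-body
subspace, so a rigid component left in Δq depresses every overlap without
physical meaning.

**Mode amplitudes for sampling.** Sampling uses scaled modes a_j = v_j/λ_j
(1/√λ optional), so low-frequency modes dominate the random mix. Because
the magnitude of 1/λ_min varies by orders of magnitude between systems, the
single amplification factor f of the sampler is calibrated per mode set so
that a random draw (weights uniform in [−1,1]) has a per-particle RMS
displacement equal to the configured amplification (default 5 Å). The
sampling law itself remains the plain linear combination
q_rand = q_root + Σ f·w_j·a_j.

## Inverse kinematics

Closure between consecutive particles is solved two ways, both verified
against forward kinematics (closure tolerances: 1e-4 Å position, 1e-6 rad
orientation):

* **Enumeration** (`solve_ik`): the six torsions reduce analytically to
  three unknowns — the first and last torsion plus the rotation of the rigid
  middle peptide unit {CA2, C2, N3, CA3} about its CA–CA axis (the middle
  unit is rigid because its ω is frozen, fixing the CA2–CA3 distance). A
  batched multistart Levenberg–Marquardt over a 6×6×6 torsion grid finds the
  roots, which are deduplicated at 1e-3 rad and verified by forward
  kinematics. Unreachable targets return an empty set.
* **Seeded polish**: during planning, steps are small and the previous
  torsions are excellent seeds; a batched Gauss–Newton on the 9-dimensional
  closure residual (target N/CA/C positions of the next particle's residue)
  solves all segments of the chain simultaneously in a few iterations.

**Snap acceptance.** Sampled particle poses are generically slightly off the
6R-reachable manifold. When the least-squares closure lands within a snap
tolerance (0.2 Å / 0.1 rad) of the requested downstream pose, the solution is
accepted and the downstream particle moved to the realized pose — a
deterministic, bounded form of the perturb-the-downstream-particle retry.
The realized coarse state is returned, and every closure satisfies the exact
tolerance against it. Random perturbations (0.1 Å / 0.02 rad, up to 10
trials per tripeptide by default; the planner uses 4) remain the fallback for
IK failures and steric clashes; reconstruction failure is a reported outcome
that sends the planner back to sampling.

## Collision model

Backbone N, CA, C, O plus CB atoms are hard spheres with van der Waals radii
C 1.70, N 1.55, O 1.52 Å scaled by 0.70; a pair clashes below
scale·(r_i+r_j). Bonded (1-2) and angle (1-3) pairs are excluded; 1-4 pairs
are checked. Glycine has no CB and none is synthesized. Neighbor search
uses a uniform cell grid whose result is identical to the O(n²) scan
(property-tested).

## Planner

The outer loop recomputes modes at the current root, runs an RRT until some
node has progressed 0.3 Å Cα-RMSD toward the goal (0.15 Å once the remaining
distance falls below 25% of the initial one), extracts the node closest to
the goal (plain particle RMSD), relieves its steric near-contacts, and
iterates until the superposed Cα-RMSD to the goal drops below `d_target`
(default 1.5 Å; the fixture tests use 0.5 Å), with stall (10 outer
iterations without improvement) and iteration caps (4000 inner, 200 outer).
Tree distances use unsuperposed particle-origin RMSD — modes and
interpolation act in the fixed laboratory frame — biased by the factor
RMSD(q,q_goal)/RMSD(q_init,q_goal) that pulls exploration toward the target.
Nearest-neighbor search is exact brute force.

**Orientation update at expansion.** Particle origins are interpolated a
fraction k (default 0.1) from the nearest node toward the sample. Carrying
orientations over unchanged proved structurally wrong: when the dominant
motion rotates a domain, frozen orientations force the IK to absorb the
displacement as internal segment shear, local backbone geometry drifts
(helical O(i)–N(i+2) contacts tighten to the clash limit within a few outer
iterations) and the search stalls. Each particle's orientation is therefore
rotated by the best-fit (Kabsch) rotation of its ±2-frame origin
neighbourhood, so rigidly moving domains carry their frames rigidly and
deformation concentrates at true hinges. The IK perturb-and-retry correction
still applies on top.

**Goal bias and amplitude schedule.** 10% of samples use the goal's particle
origins directly (standard RRT goal biasing), and the sampling amplitude is
capped at twice the remaining Cα-RMSD: without both, the endgame below ~1 Å
is sample-starved (a typical mode draw is then much larger than the leftover
displacement).

**Relaxation hook.** The original scheme runs a short force-field energy
minimization on each extracted node; that is out of scope here and replaced
by a geometric stand-in with three modes. `none` is the identity.
`penalty` is a bounded torsion-space steepest descent on the steric
near-contact penalty. The default, `relief`, addresses the actual failure
mode of hard-sphere planning — accepted conformations hug the clash boundary
(margin → 1.0), after which most moves are rejected. It restores the
relative poses of contact-involved segments part-way toward the reference
conformation (rigid domains should keep their native internal poses; with
frames fixed the intermediate torsions have no continuous freedom, so drift
lives in the inter-frame poses) and, for remaining contacts, pushes the
offending particles apart along the pair axis. Every move is accepted only
if the global steric margin improves without a true clash, and the total
displacement is capped, so the hook can only widen the tightest contact and
can never undo the exploration's progress.

## Synthetic test system

The generator builds ideal-geometry poly-alanine backbones (N–CA 1.458,
CA–C 1.525, C–N 1.329 Å, standard angles, trans ω) with per-segment
secondary structure. The two-domain fixture joins two helix hairpins
(a lone helix would leave the particle network quasi-collinear and create
spurious soft modes) through a packed four-residue linker whose torsions were
chosen so that (a) both conformations keep a steric margin ≥ 1.15 over the
whole hinge sweep, (b) the network has exactly six rigid modes, and (c) the
softest mode is a well-separated hinge bend with overlap > 0.9 against the
open→closed displacement. The hinge itself is a rotation about the pivot
residue's CA→C bond (a pure ψ change), so the closed form keeps exact
backbone geometry. The layout's fixed torsions support 52–66 residues.

What the fixture does *not* emulate: side chains beyond CB, sequence
heterogeneity, experimental coordinate noise, multi-domain topologies with
several linkers, and the size range of real transition systems (hundreds of
residues). Passing tests demonstrate the machinery — mode prediction,
closure, collision handling, planning — at desk scale, not performance on
experimental structures.

## Problem sizes and determinism

Tests and the acceptance script run the 60-residue fixture (20 particles):
the full transition (≈3.7 Å to below 0.5 Å) takes seconds to a few minutes
depending on the seed; the IK fuzz uses 100 random closures and the collision
property 500 jittered chains. All randomness flows from a single seeded
generator; fixed-seed runs are reproducible bit-for-bit.

## Known limitations

* The enumeration solver is numerical (multistart on the reduced 3-variable
  system); completeness of the solution set is empirical, not certified —
  though the generating solution was recovered in every fuzz trial.
* The relief hook is a geometric surrogate for energy minimization; it
  maintains steric feasibility but has no notion of favorable contacts.
* Paths are first approximations in the sense of the underlying method:
  geometrically valid, energy-agnostic.
* Real open/closed PDB pairs are the intended inputs (`tripath transition
  --init open.pdb --goal closed.pdb`); the numerical experiments shipped
  with the package run on the synthetic system only.
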