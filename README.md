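# tripath

Large-amplitude conformational transitions — the hinge motions of adenylate
kinase, the domain closure of periplasmic binding proteins — are central to
protein function but hard to observe directly and expensive to simulate.
`tripath` computes geometrically valid transition paths between two known
conformations of a protein in minutes on a single CPU, for structural
biologists and method developers who need a first, qualitative picture of a
transition mechanism rather than a free-energy profile.

## Method

Three ideas are combined in a multi-scale scheme:

1. **Tripeptide elastic network.** The chain is decomposed into tripeptides;
   one oriented particle (reference frame) is attached to each. Particles
   closer than a cutoff d_cut (16 Å default) are joined by springs,
   E = Σ C/2 (d_ij − d⁰_ij)², and the anisotropic-network Hessian
   H_ij = −(C/d⁰²)(r_j−r_i)(r_j−r_i)ᵀ is diagonalized. Low-frequency modes
   predict the directions of collective motions at one third the cost of a
   Cα network. Agreement with an observed change Δq is measured by the
   overlap I_j = |a_j·Δq| / (‖a_j‖‖Δq‖).

2. **Mode-biased RRT.** A Rapidly-exploring Random Tree grows in the
   particle space. Samples are random linear combinations of the scaled
   modes, q_rand = q_root + Σ f·w_j·a_j with w_j ~ U[−1,1] and a_j = v_j/λ_j;
   the tree metric d(q, q_rand) = RMSD(q,q_rand)·RMSD(q,q_goal)/RMSD(q_init,q_goal)
   pulls exploration toward the goal. An outer loop recomputes modes at each
   new root until the Cα-RMSD to the goal drops below d_target.

3. **6R inverse kinematics.** With bond lengths, angles and ω frozen, the
   backbone between consecutive particles is a 6R chain (three φ/ψ pairs, up
   to 16 closure solutions). Every tree expansion rebuilds the all-atom
   backbone (N, CA, C, O, CB) by solving these closures and is accepted only
   if clash-free under a hard-sphere model — so every conformation on the
   emitted path has exact backbone geometry and no steric overlap.

See `docs/methods.md` for the model details, numerical choices and known
limitations.

## Worked example

The package ships a synthetic two-domain system (two helix hairpins joined
by a packed linker) whose open and closed forms are related by a hinge
rotation — a stand-in for an experimental open/closed pair that needs no
download:

```sh
tripath fixture --n-residues 60 --hinge-angle 30 --out open.pdb closed.pdb
# wrote open.pdb and closed.pdb (ca_rmsd 1.93 A)

tripath overlap --open open.pdb --closed closed.pdb --cutoff 16
# best overlap 0.983 at mode 6 (cutoff 16 A); table in overlap.tsv
```

Mode 6 is the first non-rigid mode (modes 0–5 are rigid-body motions): the
softest vibration of the open form points almost exactly (cosine 0.98) along
the true open→closed displacement, which is what makes mode-biased sampling
effective. Scanning cutoffs reproduces the calibration protocol:

```sh
tripath overlap --open open.pdb --closed closed.pdb --scan
# best cutoff 16 A (overlap 0.983); table in overlap.tsv
```

A full transition search between a 3.7 Å-apart pair:

```sh
tripath fixture --n-residues 60 --hinge-angle 60 --out open.pdb closed.pdb
tripath transition --init open.pdb --goal closed.pdb --seed 1 \
    --config run.toml --out path.pdb --report report.tsv
# outer 1: ca_rmsd_to_goal=3.159 A  tree=2 nodes ...
# ...
# status=converged  conformations=11  final ca_rmsd=0.486 A  seed=1
```

(`run.toml` here contains `d_target = 0.5`.) `path.pdb` is a multi-model PDB
with one model per outer iteration; `report.tsv` holds the per-iteration
RMSD-to-goal and the per-residue displacement matrix in long format, from
which the two darker bands of a moving-domain heat map can be plotted
directly.

For real proteins, pass two PDB files of the same chain
(`--chain A` selects a chain; residues must match over the compared range).

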