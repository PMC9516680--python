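# Methods

## Model

### Degrees of freedom

A loop is N contiguous flexible residues terminated by a rigid
C-terminal anchor residue (Ct). The variables are the backbone torsions
q = (φ₁, ψ₁, …, φ_N, ψ_N, φ_Ct), n = 2N + 1; with ω angles enabled,
n = 3N + 1. Every bond length, bond angle and non-DOF torsion is a
fixed internal coordinate: coordinates are rebuilt from the fixed
N-terminal side by composing exact bond rotations, so applying the
current angles is the identity and non-DOF internals are preserved to
machine precision. Side chains are carried rigidly (they move with the
backbone they are attached to) but contribute no DOFs.

### Elastic network

The potential is a network of Hookean springs between heavy atoms of
the loop and of every nearby residue (default: whole residues with at
least one atom within 10 Å of a mobile atom). Environment atoms are
fixed — their Cartesian derivatives vanish — but their springs into the
loop enter the Hessian, which grounds the modes in the surrounding
protein and implicitly penalizes clashes. The default spring rule is
k = k0/d0² for all pairs within 10 Å; a plain distance-cutoff rule with
constant k is available (`enm_rule = cutoff`). The input structure is
the energy minimum by construction, so the torsional Hessian is the
Gram matrix H_ab = Σ k (∂d/∂q_a)(∂d/∂q_b) and is PSD. The
kinetic-energy matrix is T_ab = Σᵢ mᵢ (∂rᵢ/∂q_a)·(∂rᵢ/∂q_b) with
per-element atomic masses. No Eckart conditions are applied: the
anchored loop has no global rigid-body freedom.

### Closure constraints

Six scalar constraints pin the anchor: g₁–g₃ are the Cartesian
coordinates of the Ct Cα; g₄–g₆ are (r_N − o)·v, (r_N − o)·w and
(r_C − o)·v, where o is the equilibrium Cα position, u = unit(Cα→N),
v = unit(u × (Cα→C)) is the **normal** of the N–Cα–C plane and
w = u × v lies in the plane. The orientation of v is load-bearing: to
first order the anchor C moves on a cone about u whose tangent is the
plane normal, so only the out-of-plane projection r_C·v responds to
φ_Ct; with an in-plane v the constraint Jacobian would be rank 5. The
complementary projections r_N·u, r_C·u and r_C·w are first-order
redundant given the fixed N–Cα and Cα–C lengths and the N–Cα–C angle
(appending their gradient rows leaves the rank at 6, which the tests
assert). The frame is constant within one linearization step and
recomputed after every structural update.

### Constrained eigenproblem

Stationarity of the quadratic form under the constraints gives the
extended ("bordered Hessian") pencil

    [[H, J_gᵀ], [J_g, 0]] (v, λ) = ω² [[T, 0], [0, 0]] (v, λ).

The extended kinetic matrix is singular, so of the n + C eigenpairs 2C
are infinite/spurious and n − C are the closure-preserving modes
(2N − 5 without ω). The production route projects onto an orthonormal
basis Z of null(J_g) and solves the dense symmetric-definite problem
ZᵀHZ y = ω² ZᵀTZ y; the QZ solution of the bordered pencil is kept as a
cross-check and agrees to ~1e-13 in the spectrum. Lagrange-multiplier
components are recovered from the stationarity rows as
λ = −(J J ᵀ)⁻¹ J (H − ω²T) v and stored but excluded from
dihedral-space operations. Mode columns are T-orthonormal in dihedral
space (nullspace route); the modes are orthogonal in the extended
space, not in the n-dimensional dihedral space, and no
re-orthogonalization is performed. If ZᵀTZ is numerically rank
deficient (short loops make T ill-conditioned through the nested moving
sets), 1e-10·trace/n is added to its diagonal.

## Finite motions

The modes satisfy closure only to first order, so every finite motion
is a sequence of capped steps — the largest single-dihedral change per
step is `max_step_deg` (1° by default, and never more) — with the whole
NMA (network, H, T, frame, J_g, modes) recomputed about each new
conformation and the new modes matched to the previous ones by greedy
assignment on the absolute dot products of their unit-normalized
dihedral parts (signs fixed so matched dots are positive).

A single capped step leaves a quadratic anchor residual (~3e-4 Å at
1°). Re-anchoring alone lets those residuals accumulate linearly in the
step size along a trajectory, so each refresh also adds the
minimum-norm restoring correction δq = J_g⁺ (g_target − g), where
g_target are the anchor constraint values at the trajectory start. This
feedback keeps the anchor deviation stationary at the size of one
step's quadratic error: measured ≲ 2e-3 Å over 4 Å excursions at 1°
steps, and quartering when the step is halved. It is a first-order
correction inside the same linearization — not a post-hoc chain-closing
repair.

### Morphing

The target structure is first superposed rigidly onto the source (all
common atoms by default; `flanks` uses the backbone of the anchor
residues ± 2 more on each side; `none` skips). Each iteration computes
the constrained modes, forms the target direction, combines the modes
by their overlap with it, caps the step and applies it. The direction
default is **Cartesian**: coefficients c_k = ⟨D v_k, Δr⟩ / ‖D v_k‖²
project the coordinate difference onto each mode's Cartesian image.
A dihedral-space variant (project the wrapped dihedral difference onto
the unit-normalized mode span) is available but can stall in local
minima of the dihedral distance that are not minima of the RMSD — on
self-recovery tests the Cartesian default converges in 20/20 trials,
the dihedral variant in 18/20. Convergence: the best backbone RMSD
(loop N/CA/C/O atoms) must improve by at least `rmsd_tol` (Å, default
0.05) per `patience` (50) iterations, else the run stops; the returned
trace is the monotone best-RMSD curve.

### Ensemble sampling

Each excursion draws one random mode combination: coefficients are
standard normal, weighted 1/ω per mode ("thermal", matching the
harmonic amplitudes; an equal-weight option exists). The loop is flexed
along the (matched, refreshed) combination in capped steps; a
conformation is stored whenever the backbone RMSD from the last stored
one exceeds `spacing` (0.1 Å default); the excursion ends at `max_rmsd`
and restarts from the exact start conformation (bounding drift), until
`n_samples` (default 10,000) conformations are stored. Deterministic
under a fixed seed. Note that free excursions decorrelate under
repeated mode matching and their RMSD from the start can plateau below
`max_rmsd`; directed single-mode excursions (`flex_along_mode`, also
used for the per-mode animations at 0.25 Å frame spacing) reach large
amplitudes monotonically.

## Essential-dynamics comparison

PCA uses the N/CA/C/O atoms of the loop residues, mass-unweighted. The
reference is the snapshot with the smallest RMSD to the coordinate
mean; the covariance of displacements about it is diagonalized. No
extra superposition is performed: loop ensembles share the fixed
environment, so all frames are already in one lab frame. The overlap is
γ = Σᵢ Σⱼ (uᵢ·wⱼ)² / max(m_A, m_B) with m per ensemble the smallest
eigenvector count explaining 90 % of the variance (configurable, or a
fixed m); an eigenvalue-weighted RWSIP variant is behind a flag. γ = 1
for complete bases; for independent random rank-m subspaces of
dimension 3K it concentrates near m/(3K). The Z-score null permutes the
atom order of every snapshot of ensemble B independently (one
permutation per snapshot, all three coordinates together), re-runs the
PCA and recomputes γ; 1000 null models by default, deterministic under
seed, with a degenerate-null flag if σ = 0. B-factors are
8π²/3 · Σ_k λ_k ‖u_k(atom)‖² averaged over the backbone atoms of each
residue; profiles are compared by Spearman rank correlation (average
ranks on ties).

## Synthetic fixtures

`build_synthetic_loop` builds an N-residue loop flanked by two rigid
anchor residues with ideal geometry (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, Cα–Cβ 1.530 Å; angles 111.2°/116.6°/121.9°;
ω = 180°) at caller-chosen φ/ψ; alanine side chains, glycine on request.
Optional scaffold shells place single-atom pseudo-residues at exact
outward distances from loop Cα atoms to exercise environment selection.
The construction is fully deterministic (the `seed` argument is
accepted for API stability only). What the fixture does **not**
emulate: real side chains beyond Cβ, deviations from ideal bond
geometry, non-planar ω, missing atoms, alternate conformations, or a
dense protein environment — so green fixture tests establish the
correctness of the formalism and its numerics, not prediction quality
on deposited structures. The deposited-structure morphing driver
(`scripts/morph_benchmark.py` with `data/benchmarks/manifest.yaml`)
covers the latter when the PDB files have been fetched.

## Numerical choices and edge cases

* Torsions: IUPAC sign, atan2 form; collinear triplets raise.
* Constraint-Jacobian rank is checked (σ₆ ≥ 1e-8 σ₁), degenerate
  anchors raise.
* QZ route: eigenvalues with |β| ≤ 1e-8(|α| + |β|) are treated as the
  2C infinite modes and discarded.
* Altloc resolution: highest occupancy; insertion codes rejected;
  ATOM records only; hydrogens and waters dropped; masses by element.
* Chain breaks: C–N distance > 2.0 Å inside the loop raises.
* Ct side-chain atoms beyond the backbone (O, Cβ, …) are environment
  (fixed); only the anchor N/Cα/C are mobile.

## Known limitations

* Closure is preserved to ~1e-3 Å over multi-Å trajectories, not
  exactly; ω, bond lengths and angles never change, which bounds how
  closely an arbitrary target conformation can be reproduced.
* No energetic scoring or clash filtering beyond what the ENM encodes.
* Single-chain loops only; no mmCIF, no insertion codes.
* The morphing descent is greedy; pathological targets can require
  many iterations or stall at the convergence tolerance.
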