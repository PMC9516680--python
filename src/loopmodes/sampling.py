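"""Iterative small-step exploration of the closed-loop manifold.

The constrained modes respect closure only to first order, so all
finite excursions are taken as sequences of small steps (at most
``max_step_deg`` per dihedral, 1 degree by default) with the NMA
recomputed about every intermediate conformation.  Modes of consecutive
steps are matched by their dot products so a direction can be followed
coherently across refreshes.  Two drivers are provided: morphing toward
a target conformation (modes combined by their overlap with the target
direction) and random closed-ensemble generation around an equilibrium
conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .closure import (
    ConstrainedModeSet,
    anchor_frame,
    compute_constrained_modes,
    constraint_values,
    jacobian_matrix,
)
from .errors import LoopModesError
from .kinematics import apply_dihedrals, backbone_rmsd, define_dofs, extract_dihedrals, kabsch, wrap_angle
from .structure import LoopModel, LoopSpec, Structure, select_loop

BACKBONE_FOR_RMSD = ("N", "CA", "C", "O")


@dataclass
class MorphOptions:
    """Knobs of the iterative morphing driver.

    ``max_step_deg`` caps the largest single-dihedral change per step
    (must not exceed 1 degree, the validity range of the linearization).
    ``rmsd_tol`` is the relative best-RMSD improvement under which the
    run is declared converged over ``patience`` consecutive iterations.
    """

    max_step_deg: float = 1.0
    rmsd_tol: float = 0.05
    max_iters: int = 2000
    patience: int = 50
    superpose_mode: str = "full"  # full | flanks | none
    # target direction: Cartesian difference vector projected through the
    # modes (default), or the wrapped dihedral difference.  The dihedral
    # variant can stall in local minima of the dihedral distance that are
    # not minima of the RMSD.
    direction_space: str = "cartesian"  # cartesian | dihedral
    enm_rule: dict | None = None
    solver: str = "nullspace"

    def __post_init__(self):
        if not (0.0 < self.max_step_deg <= 1.0):
            raise LoopModesError("max_step_deg must lie in (0, 1] degrees")
        if self.max_iters < 1:
            raise LoopModesError("max_iters must be >= 1")


@dataclass
class MorphResult:
    """Outcome of a morph run; ``rmsd_trace`` is the monotone best-RMSD."""

    rmsd_trace: list
    final_rmsd: float
    initial_rmsd: float
    n_iterations: int
    converged: bool
    coords: np.ndarray
    q: np.ndarray


@dataclass
class Ensemble:
    """Ordered collection of closed-loop conformations sharing one atom table."""

    structure: Structure
    mobile_idx: np.ndarray
    dihedrals: list = field(default_factory=list)
    mobile_coords: list = field(default_factory=list)
    rmsd_from_start: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mobile_coords)

    def add(self, q: np.ndarray, mobile_xyz: np.ndarray, rmsd: float) -> None:
        self.dihedrals.append(np.array(q))
        self.mobile_coords.append(np.array(mobile_xyz))
        self.rmsd_from_start.append(float(rmsd))

    def full_coords(self, k: int) -> np.ndarray:
        out = self.structure.coords.copy()
        out[self.mobile_idx] = self.mobile_coords[k]
        return out


def _loop_backbone_rows(loop: LoopModel):
    """Mobile-block row positions of the loop-residue backbone atoms."""
    s = loop.structure
    rows = []
    for r in range(loop.spec.first, loop.spec.last + 1):
        for nm in BACKBONE_FOR_RMSD:
            rows.append(loop.mobile_pos(s.index(loop.spec.chain, r, nm)))
    return np.array(rows, dtype=int)


def match_modes(
    previous: ConstrainedModeSet, current: ConstrainedModeSet
) -> ConstrainedModeSet:
    """Reorder/sign-fix ``current`` to follow ``previous`` across a refresh.

    Greedy assignment maximizing the absolute dot product of the
    (unit-normalized) dihedral parts; each matched mode's sign is flipped
    so the dot product with its predecessor is positive.
    """
    if previous.n_modes != current.n_modes:
        raise LoopModesError("mode sets must have equal counts to be matched")
    P = previous.eigenvectors / np.linalg.norm(previous.eigenvectors, axis=0)
    Q = current.eigenvectors / np.linalg.norm(current.eigenvectors, axis=0)
    M = P.T @ Q  # rows: previous, cols: current
    absM = np.abs(M.copy())
    m = absM.shape[0]
    perm = np.full(m, -1, dtype=int)
    signs = np.ones(m)
    for _ in range(m):
        i, j = np.unravel_index(np.argmax(absM), absM.shape)
        perm[i] = j
        signs[i] = 1.0 if M[i, j] >= 0 else -1.0
        absM[i, :] = -1.0
        absM[:, j] = -1.0
    return ConstrainedModeSet(
        current.eigenvalues[perm],
        current.eigenvectors[:, perm] * signs[None, :],
        current.lagrange[:, perm] * signs[None, :],
    )


def _anchor_restoration(loop, frame0, g_target, D, coords) -> np.ndarray:
    """Minimum-norm dihedral correction pulling the anchor back on target.

    Individual steps preserve closure only to second order; over a long
    trajectory those residuals would otherwise accumulate linearly in the
    step size.  Solving J_g dq = g_target - g(coords) in the least-norm
    sense each refresh keeps the anchor deviation stationary at the size
    of a single step's quadratic error (so it shrinks as step^2).  The
    correction is itself second-order small (~1e-5 rad per step).
    """
    resid = g_target - constraint_values(loop, frame0, coords)
    J = jacobian_matrix(loop, frame0, D)
    return np.linalg.lstsq(J, resid, rcond=None)[0]


def _capped_step(direction: np.ndarray, max_step_deg: float) -> np.ndarray:
    """Scale so the largest dihedral change is at most max_step_deg (cap)."""
    cap = np.deg2rad(max_step_deg)
    peak = np.abs(direction).max()
    if peak <= cap or peak == 0.0:
        return direction
    return direction * (cap / peak)


def _superpose_structure(
    target: Structure, source: Structure, spec: LoopSpec, mode: str
) -> Structure:
    """Rigidly fit a copy of ``target`` onto ``source``.

    ``mode="full"`` uses every atom common to both structures;
    ``"flanks"`` uses the backbone of the anchor residues plus two more on
    either side of the loop; ``"none"`` returns an unmoved copy.
    """
    target = target.copy()
    if mode == "none":
        return target
    if mode == "full":
        keys = [
            (target.chain[i], int(target.resseq[i]), target.atname[i])
            for i in range(target.natoms)
        ]
        pairs = [
            (i, source.index(*k)) for i, k in enumerate(keys)
            if source.has_atom(*k)
        ]
    elif mode == "flanks":
        flank_res = list(range(spec.first - 3, spec.first)) + list(
            range(spec.last + 1, spec.last + 4)
        )
        pairs = []
        for r in flank_res:
            for nm in BACKBONE_FOR_RMSD:
                if target.has_atom(spec.chain, r, nm) and source.has_atom(
                    spec.chain, r, nm
                ):
                    pairs.append(
                        (target.index(spec.chain, r, nm),
                         source.index(spec.chain, r, nm))
                    )
    else:
        raise LoopModesError(f"unknown superposition mode {mode!r}")
    if len(pairs) < 3:
        raise LoopModesError("not enough common atoms for superposition")
    ti = np.array([p[0] for p in pairs])
    si = np.array([p[1] for p in pairs])
    R, t = kabsch(target.coords[ti], source.coords[si])
    target.coords = target.coords @ R.T + t
    return target


def morph_to_target(
    loop: LoopModel, target_structure: Structure, opts: MorphOptions | None = None
) -> MorphResult:
    """Flex the loop toward a target conformation along constrained modes.

    Each iteration recomputes the constrained NMA at the current
    conformation, forms the target direction (the wrapped dihedral
    difference to the target, or its Cartesian projection), combines the
    modes according to their overlap with that direction, and takes one
    capped step.  The best conformation seen is tracked; the run stops on
    convergence of the best RMSD or after ``max_iters``.
    """
    opts = opts or MorphOptions()
    spec = loop.spec
    target_structure = _superpose_structure(
        target_structure, loop.structure, spec, opts.superpose_mode
    )
    target_loop = select_loop(target_structure, spec, env_cutoff=0.0)
    t_dofs = define_dofs(target_loop)
    q_target = extract_dihedrals(target_loop, dofs=t_dofs)

    dofs = define_dofs(loop)
    bb_rows = _loop_backbone_rows(loop)
    target_bb = target_structure.coords[target_loop.mobile_idx][bb_rows]
    target_mobile = target_structure.coords[target_loop.mobile_idx]

    coords = loop.structure.coords.copy()
    q = extract_dihedrals(loop, coords=coords, dofs=dofs)
    frame0 = anchor_frame(loop, coords=coords)
    g_target = constraint_values(loop, frame0, coords)

    def loop_rmsd(c):
        return backbone_rmsd(c[loop.mobile_idx][bb_rows], target_bb)

    rmsd = loop_rmsd(coords)
    initial_rmsd = rmsd
    best_rmsd, best_coords, best_q = rmsd, coords.copy(), q.copy()
    trace = [best_rmsd]
    converged = False
    window_anchor = best_rmsd
    since_check = 0
    it = 0
    while it < opts.max_iters:
        it += 1
        dq = wrap_angle(q_target - q)
        if np.abs(dq).max() < 1e-10 or best_rmsd < 1e-9:
            converged = True
            break
        ctx = compute_constrained_modes(
            loop, coords=coords, dofs=dofs, enm_rule=opts.enm_rule,
            solver=opts.solver,
        )
        V = ctx.modes.eigenvectors
        if opts.direction_space == "dihedral":
            # overlap weights on unit-normalized dihedral parts; with the
            # modes spanning null(J_g) this is (near) the orthogonal
            # projection of dq onto the closure-preserving tangent space
            V = V / np.linalg.norm(V, axis=0)
            coeff = V.T @ dq
        elif opts.direction_space == "cartesian":
            dr = (target_mobile - coords[loop.mobile_idx]).ravel()
            DV = ctx.D @ V
            coeff = (DV.T @ dr) / np.maximum(
                np.einsum("ij,ij->j", DV, DV), 1e-12
            )
        else:
            raise LoopModesError(
                f"unknown direction space {opts.direction_space!r}"
            )
        step = _capped_step(V @ coeff, opts.max_step_deg)
        step = step + _anchor_restoration(loop, frame0, g_target, ctx.D, coords)
        q = wrap_angle(q + step)
        coords = apply_dihedrals(loop, q, dofs=dofs, coords=coords)
        rmsd = loop_rmsd(coords)
        if rmsd < best_rmsd:
            best_rmsd, best_coords, best_q = rmsd, coords.copy(), q.copy()
        trace.append(best_rmsd)
        since_check += 1
        if since_check >= opts.patience:
            # absolute best-RMSD improvement (Angstrom) over the window
            if window_anchor - best_rmsd < opts.rmsd_tol:
                converged = True
                break
            window_anchor = best_rmsd
            since_check = 0
    return MorphResult(
        trace, best_rmsd, initial_rmsd, it, converged, best_coords, best_q
    )


def sample_ensemble(
    loop: LoopModel,
    n_samples: int = 10000,
    max_rmsd: float = 1.5,
    spacing: float = 0.1,
    seed: int = 0,
    max_step_deg: float = 1.0,
    coefficient_weighting: str = "thermal",  # thermal (1/omega) | equal
    enm_rule: dict | None = None,
    max_total_steps: int | None = None,
) -> Ensemble:
    """Generate an ensemble of closed-loop conformations around the start.

    Each excursion draws one random combination of modes defining a
    target direction (standard-normal coefficients, weighted by 1/omega
    for thermal low-frequency emphasis unless ``coefficient_weighting`` is
    "equal"), flexes the loop along it in capped steps with per-step NMA
    refresh and mode matching, records a conformation whenever the
    backbone RMSD from the last saved one exceeds ``spacing``, stops at
    ``max_rmsd`` from the start, and returns to the start.  Excursions
    repeat until ``n_samples`` conformations are stored.  Deterministic
    under a fixed ``seed``.
    """
    if max_rmsd < 0:
        raise LoopModesError("max_rmsd must be non-negative")
    rng = np.random.default_rng(seed)
    dofs = define_dofs(loop)
    bb_rows = _loop_backbone_rows(loop)
    start_coords = loop.structure.coords.copy()
    q0 = extract_dihedrals(loop, coords=start_coords, dofs=dofs)
    start_bb = start_coords[loop.mobile_idx][bb_rows]

    ens = Ensemble(
        loop.structure.copy(),
        loop.mobile_idx.copy(),
        metadata={
            "seed": int(seed),
            "max_rmsd": float(max_rmsd),
            "spacing": float(spacing),
            "max_step_deg": float(max_step_deg),
            "weighting": coefficient_weighting,
        },
    )
    ens.add(q0, start_coords[loop.mobile_idx], 0.0)
    if max_rmsd <= 1e-12 or n_samples <= 1:
        return ens

    ctx0 = compute_constrained_modes(loop, coords=start_coords, dofs=dofs,
                                     enm_rule=enm_rule)
    frame0 = anchor_frame(loop, coords=start_coords)
    g_target = constraint_values(loop, frame0, start_coords)
    total_steps = 0
    step_budget = max_total_steps if max_total_steps is not None else 10**9
    while len(ens) < n_samples and total_steps < step_budget:
        c = rng.standard_normal(ctx0.modes.n_modes)
        if coefficient_weighting == "thermal":
            omega = np.sqrt(np.maximum(ctx0.modes.eigenvalues, 1e-12))
            c = c / omega
        elif coefficient_weighting != "equal":
            raise LoopModesError(
                f"unknown coefficient weighting {coefficient_weighting!r}"
            )
        coords = start_coords.copy()
        q = q0.copy()
        ctx = ctx0
        prev_modes = ctx0.modes
        amps = c.copy()
        last_saved_bb = start_bb
        while len(ens) < n_samples and total_steps < step_budget:
            total_steps += 1
            direction = prev_modes.eigenvectors @ amps
            step = _capped_step(direction, max_step_deg)
            if np.abs(step).max() < 1e-12:
                break
            step = step + _anchor_restoration(
                loop, frame0, g_target, ctx.D, coords
            )
            q = wrap_angle(q + step)
            coords = apply_dihedrals(loop, q, dofs=dofs, coords=coords)
            bb = coords[loop.mobile_idx][bb_rows]
            r_start = backbone_rmsd(bb, start_bb)
            if backbone_rmsd(bb, last_saved_bb) > spacing:
                ens.add(q, coords[loop.mobile_idx], r_start)
                last_saved_bb = bb
            if r_start >= max_rmsd:
                break
            ctx = compute_constrained_modes(loop, coords=coords, dofs=dofs,
                                            enm_rule=enm_rule)
            prev_modes = match_modes(prev_modes, ctx.modes)
    return ens


def flex_along_mode(
    loop: LoopModel,
    mode_index: int,
    sign: int = 1,
    target_rmsd: float = 3.0,
    frame_spacing: float = 0.25,
    max_step_deg: float = 1.0,
    enm_rule: dict | None = None,
    max_steps: int = 5000,
):
    """Excursion along one constrained mode with per-step refresh.

    Returns (frames, rmsds): mobile coordinate snapshots every
    ``frame_spacing`` Angstrom of backbone RMSD along the pathway, up to
    ``target_rmsd``.  Used for per-mode animations.
    """
    dofs = define_dofs(loop)
    bb_rows = _loop_backbone_rows(loop)
    start_coords = loop.structure.coords.copy()
    q = extract_dihedrals(loop, coords=start_coords, dofs=dofs)
    start_bb = start_coords[loop.mobile_idx][bb_rows]
    ctx = compute_constrained_modes(loop, coords=start_coords, dofs=dofs,
                                    enm_rule=enm_rule)
    prev_modes = ctx.modes
    frame0 = anchor_frame(loop, coords=start_coords)
    g_target = constraint_values(loop, frame0, start_coords)
    coords = start_coords.copy()
    frames, rmsds = [], []
    next_save = frame_spacing
    for _ in range(max_steps):
        direction = float(sign) * prev_modes.eigenvectors[:, mode_index]
        step = _capped_step(direction, max_step_deg)
        step = step + _anchor_restoration(loop, frame0, g_target, ctx.D, coords)
        q = wrap_angle(q + step)
        coords = apply_dihedrals(loop, q, dofs=dofs, coords=coords)
        r = backbone_rmsd(coords[loop.mobile_idx][bb_rows], start_bb)
        if r >= next_save:
            frames.append(coords[loop.mobile_idx].copy())
            rmsds.append(r)
            next_save += frame_spacing
        if r >= target_rmsd:
            break
        ctx = compute_constrained_modes(loop, coords=coords, dofs=dofs,
                                        enm_rule=enm_rule)
        prev_modes = match_modes(prev_modes, ctx.modes)
    return frames, rmsds
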