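"""Loop-closure constraints and the constrained eigenproblem.

Closing the loop requires the N/CA/C atoms of the C-terminal anchor
residue to keep their position and orientation.  Because the N-CA and
CA-C bond lengths and the N-CA-C angle are fixed internal coordinates,
C = 6 scalar constraints suffice: the three Cartesian coordinates of the
anchor CA (g1-g3) and three projections of the anchor N and C atoms onto
a reference frame (u, v, w) built around CA at equilibrium (g4-g6):

    g4 = (r_N - o) . v,   g5 = (r_N - o) . w,   g6 = (r_C - o) . v

with o the equilibrium CA position, u along CA->N, v the unit normal of
the N-CA-C plane (v = u x (r_C - o), normalized) and w = u x v (in the
plane).  The remaining projections (r_N . u, r_C . u, r_C . w) are
first-order redundant given the fixed bond geometry: r_N . u is the
fixed N-CA bond length, r_C . u and r_C . w follow from the CA-C length
and N-CA-C angle.  The orientation of v matters: to first order the
anchor C moves on a cone about u whose tangent is the plane normal, so
only the out-of-plane projection r_C . v sees the phi(Ct) rotation (an
in-plane v would leave J_g rank deficient).

Constrained modes are the stationary points of the quadratic form under
these constraints, obtained either by projecting the eigenproblem onto
the null space of the constraint Jacobian J_g (default, numerically
robust) or by solving the extended "bordered Hessian" pencil

    [[H, J_g^T], [J_g, 0]] (v, lambda) = w^2 [[T, 0], [0, 0]] (v, lambda)

whose finite spectrum coincides with the null-space route; 2C spurious
infinite modes are discarded, leaving n - C closure-preserving modes
(2N - 5 for an N-residue loop without omega DOFs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .enm import build_elastic_network, internal_hessian, kinetic_matrix, _regularize
from .errors import ConstraintRankError, DegenerateGeometryError, SolverError
from .kinematics import apply_dihedrals, cartesian_derivatives, define_dofs, extract_dihedrals
from .structure import LoopModel

N_CONSTRAINTS = 6


@dataclass
class AnchorFrame:
    """Orthonormal triad (u, v, w) anchored on the equilibrium Ct CA."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray


@dataclass
class ConstraintSet:
    """The six closure constraints: values at equilibrium and Jacobian J_g (6 x n)."""

    jacobian: np.ndarray
    g0: np.ndarray  # equilibrium constraint values
    frame: AnchorFrame
    atom_idx: dict  # global indices of the anchor N/CA/C

    @property
    def n_constraints(self) -> int:
        return self.jacobian.shape[0]


@dataclass
class ConstrainedModeSet:
    """The n - C closure-preserving modes.

    ``eigenvectors`` columns are the dihedral-space parts (n entries);
    ``lagrange`` columns hold the C multiplier components of each extended
    eigenvector.  Modes are orthonormal in the solver's extended metric,
    not necessarily in dihedral space.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lagrange: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def anchor_frame(loop: LoopModel, coords: np.ndarray | None = None) -> AnchorFrame:
    """Build the (u, v, w) frame from the anchor N/CA/C at equilibrium."""
    s = loop.structure
    if coords is None:
        coords = s.coords
    ch, ct = loop.spec.chain, loop.spec.ct_resseq
    r_n = coords[s.index(ch, ct, "N")]
    r_ca = coords[s.index(ch, ct, "CA")]
    r_c = coords[s.index(ch, ct, "C")]
    u = r_n - r_ca
    u = u / np.linalg.norm(u)
    v = np.cross(u, r_c - r_ca)  # normal of the N-CA-C plane
    nv = np.linalg.norm(v)
    if nv < 1e-8:
        raise DegenerateGeometryError("anchor N, CA, C are collinear")
    v = v / nv
    w = np.cross(u, v)
    return AnchorFrame(r_ca.copy(), u, v, w)


def constraint_values(loop: LoopModel, frame: AnchorFrame, coords: np.ndarray) -> np.ndarray:
    """The six constraint functions g(coords), Angstrom units."""
    s = loop.structure
    ch, ct = loop.spec.chain, loop.spec.ct_resseq
    r_n = coords[s.index(ch, ct, "N")]
    r_ca = coords[s.index(ch, ct, "CA")]
    r_c = coords[s.index(ch, ct, "C")]
    return np.array(
        [
            r_ca[0], r_ca[1], r_ca[2],
            (r_n - frame.origin) @ frame.v,
            (r_n - frame.origin) @ frame.w,
            (r_c - frame.origin) @ frame.v,
        ]
    )


def jacobian_matrix(loop: LoopModel, frame: AnchorFrame, D: np.ndarray) -> np.ndarray:
    """J_g (6 x n) for a given frame, without the rank check."""
    s = loop.structure
    ch, ct = loop.spec.chain, loop.spec.ct_resseq
    rows = {
        nm: loop.mobile_pos(s.index(ch, ct, nm)) for nm in ("N", "CA", "C")
    }
    n = D.shape[1]
    D3 = D.reshape(-1, 3, n)
    J = np.zeros((N_CONSTRAINTS, n))
    J[0:3] = D3[rows["CA"]]
    J[3] = frame.v @ D3[rows["N"]]
    J[4] = frame.w @ D3[rows["N"]]
    J[5] = frame.v @ D3[rows["C"]]
    return J


def constraint_jacobian(
    loop: LoopModel, frame: AnchorFrame, D: np.ndarray,
    coords: np.ndarray | None = None,
) -> ConstraintSet:
    """Assemble J_g (6 x n) from the Cartesian derivative matrix.

    Rows 1-3 are the derivative rows of the anchor CA coordinates; rows
    4-6 project the derivative rows of the anchor N and C onto (v, w, v).
    Raises :class:`ConstraintRankError` if rank(J_g) < 6.
    """
    s = loop.structure
    if coords is None:
        coords = s.coords
    ch, ct = loop.spec.chain, loop.spec.ct_resseq
    idx = {nm: s.index(ch, ct, nm) for nm in ("N", "CA", "C")}
    J = jacobian_matrix(loop, frame, D)
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] <= 0.0 or sv[-1] < 1e-8 * sv[0]:
        raise ConstraintRankError(
            f"constraint Jacobian is rank deficient (singular values {sv})"
        )
    return ConstraintSet(J, constraint_values(loop, frame, coords), frame, idx)


def _solve_nullspace(H, T, J):
    Z = scipy.linalg.null_space(J)
    if Z.shape[1] != H.shape[0] - J.shape[0]:
        raise SolverError("unexpected null-space dimension")
    Hr = Z.T @ H @ Z
    Tr = _regularize(Z.T @ T @ Z)
    evals, Y = scipy.linalg.eigh(0.5 * (Hr + Hr.T), Tr)
    V = Z @ Y
    return evals, V


def solve_constrained(
    H: np.ndarray, T: np.ndarray, constraints: ConstraintSet | np.ndarray,
    solver: str = "nullspace",
) -> ConstrainedModeSet:
    """Solve the closure-constrained eigenproblem; returns n - C finite modes.

    ``solver="nullspace"`` (default) projects onto null(J_g) and solves a
    dense symmetric-definite problem; ``solver="bordered"`` solves the
    extended bordered pencil by QZ and filters out the 2C infinite modes.
    Both routes yield the same spectrum and mode subspace.  An empty
    constraint set reduces to the unconstrained problem.
    """
    J = constraints.jacobian if isinstance(constraints, ConstraintSet) else np.asarray(constraints)
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    n = H.shape[0]
    C = J.shape[0] if J.size else 0
    if C == 0:
        evals, V = scipy.linalg.eigh(H, _regularize(T))
        return ConstrainedModeSet(evals, V, np.zeros((0, n)))
    if solver == "nullspace":
        evals, V = _solve_nullspace(H, T, J)
    elif solver == "bordered":
        evals, V = _solve_bordered(H, T, J, n - C)
    else:
        raise SolverError(f"unknown solver {solver!r}")
    # lambda = -(J J^T)^{-1} J (H - w^2 T) v, from the stationarity rows
    JJt = J @ J.T
    resid = H @ V - T @ V * evals[None, :]
    lam = -np.linalg.solve(JJt, J @ resid)
    return ConstrainedModeSet(evals, V, lam)


def _solve_bordered(H, T, J, n_keep):
    """QZ on the singular bordered pencil; keeps the finite real eigenpairs."""
    n, C = H.shape[0], J.shape[0]
    HB = np.block([[H, J.T], [J, np.zeros((C, C))]])
    TB = np.block([[T, np.zeros((n, C))], [np.zeros((C, n + C))]])
    try:
        ab, VB = scipy.linalg.eig(HB, TB, right=True, homogeneous_eigvals=True)
        alpha, beta = ab[0].ravel(), ab[1].ravel()
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise SolverError("QZ factorization of the bordered pencil failed") from exc
    finite = np.abs(beta) > 1e-8 * (np.abs(alpha) + np.abs(beta))
    lam = np.full(alpha.shape, np.inf)
    lam[finite] = (alpha[finite] / beta[finite]).real
    order = np.argsort(lam)[:n_keep]
    evals = lam[order]
    if not np.all(np.isfinite(evals)):
        raise SolverError("bordered pencil yielded too few finite eigenvalues")
    V = VB[:n, order].real
    # normalize the dihedral parts in the T metric for comparability
    for k in range(V.shape[1]):
        nrm = np.sqrt(max(V[:, k] @ T @ V[:, k], 1e-300))
        V[:, k] /= nrm
    return evals, V


@dataclass
class ClosureError:
    """Anchor deviation after a finite step along a dihedral direction."""

    ca_error: float  # |delta r_CA|, Angstrom
    n_v_error: float
    n_w_error: float
    c_v_error: float

    @property
    def max_error(self) -> float:
        return max(self.ca_error, abs(self.n_v_error), abs(self.n_w_error),
                   abs(self.c_v_error))


def verify_closure(
    loop: LoopModel, q0: np.ndarray, direction: np.ndarray, amplitude: float,
    dofs=None,
) -> ClosureError:
    """Measure anchor deviation after applying q0 + amplitude * direction.

    The modes preserve closure only to first order, so these errors grow
    quadratically with amplitude; the sampling layer keeps steps small (at
    most 1 degree) and refreshes the modes after every move.
    """
    if dofs is None:
        dofs = define_dofs(loop)
    ref = apply_dihedrals(loop, np.asarray(q0, dtype=float), dofs=dofs)
    frame = anchor_frame(loop, coords=ref)
    g_ref = constraint_values(loop, frame, ref)
    moved = apply_dihedrals(
        loop, np.asarray(q0) + amplitude * np.asarray(direction), dofs=dofs
    )
    g = constraint_values(loop, frame, moved)
    s = loop.structure
    ch, ct = loop.spec.chain, loop.spec.ct_resseq
    ca = s.index(ch, ct, "CA")
    return ClosureError(
        ca_error=float(np.linalg.norm(moved[ca] - ref[ca])),
        n_v_error=float(g[3] - g_ref[3]),
        n_w_error=float(g[4] - g_ref[4]),
        c_v_error=float(g[5] - g_ref[5]),
    )


@dataclass
class NMAContext:
    """Everything the samplers need at one conformation."""

    dofs: list
    q: np.ndarray
    coords: np.ndarray
    D: np.ndarray
    H: np.ndarray
    T: np.ndarray
    frame: AnchorFrame
    constraints: ConstraintSet
    modes: ConstrainedModeSet


def compute_constrained_modes(
    loop: LoopModel,
    coords: np.ndarray | None = None,
    dofs=None,
    enm_rule: dict | None = None,
    solver: str = "nullspace",
) -> NMAContext:
    """Full constrained-NMA pipeline at one conformation.

    Rebuilds the elastic network about the current coordinates (the
    current structure is the ENM minimum after every accepted move),
    assembles H and T, the anchor frame and constraint Jacobian, and
    solves for the n - C closure-preserving modes.
    """
    if coords is None:
        coords = loop.structure.coords
    if dofs is None:
        dofs = define_dofs(loop)
    q = extract_dihedrals(loop, coords=coords, dofs=dofs)
    D = cartesian_derivatives(loop, coords=coords, dofs=dofs)
    net_idx = np.concatenate([loop.mobile_idx, loop.env_idx])
    net = build_elastic_network(coords[net_idx], rule=enm_rule)
    H = internal_hessian(net, D, loop.n_mobile)
    T = kinetic_matrix(loop.structure.mass[loop.mobile_idx], D)
    frame = anchor_frame(loop, coords=coords)
    cons = constraint_jacobian(loop, frame, D, coords=coords)
    modes = solve_constrained(H, T, cons, solver=solver)
    return NMAContext(dofs, q, np.asarray(coords, float), D, H, T, frame, cons, modes)
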