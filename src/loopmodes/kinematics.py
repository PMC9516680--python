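"""Torsional degrees of freedom and loop kinematics.

The only variables are backbone dihedral angles: phi/psi of each flexible
residue plus phi of the C-terminal anchor (optionally the omega angles as
well); every bond length, bond angle and non-DOF torsion is held fixed.
Rebuilding is done by composing exact bond rotations from the fixed
N-terminal side outward, so applying the current angles is the identity
and all non-DOF internal coordinates are preserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, LoopModesError
from .structure import LoopModel


def wrap_angle(x):
    """Wrap radians to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    out = -((-x + np.pi) % (2.0 * np.pi) - np.pi)
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (radians, IUPAC sign) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear atoms in torsion computation")
    b1u = b1 / np.linalg.norm(b1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1u)
    return float(np.arctan2(y, x))


@dataclass
class DihedralDOF:
    """One rotatable backbone bond.

    ``axis`` is the ordered (start, end) global atom index pair;
    ``torsion_atoms`` the four atoms defining the angle's value; ``moving``
    the global indices of the *mobile* atoms displaced by this rotation
    (everything downstream toward the C-terminal anchor), and
    ``moving_rows`` the same set as positions inside the mobile block.
    """

    index: int
    kind: str  # "phi" | "psi" | "omega"
    resseq: int
    axis: tuple
    torsion_atoms: tuple
    moving: np.ndarray
    moving_rows: np.ndarray


def define_dofs(loop: LoopModel) -> list[DihedralDOF]:
    """Enumerate the torsional DOFs of a loop in chain order.

    Order: phi_1, psi_1, [omega_1,] ..., phi_N, psi_N, [omega_N,] phi_Ct.
    Moving sets are computed from chain topology with the N-terminal side
    fixed, and are restricted to mobile atoms (the fixed environment never
    moves).
    """
    s = loop.structure
    spec = loop.spec
    ch = spec.chain
    mobile_set = set(loop.mobile_idx.tolist())
    pos_of = {int(g): i for i, g in enumerate(loop.mobile_idx)}

    def res_atoms_mobile(r):
        return [i for i in s.residue_atoms(ch, r).tolist() if i in mobile_set]

    def downstream(r_from):
        """All mobile atoms of residues >= r_from (Ct contributes N/CA/C)."""
        out = []
        for r in range(r_from, spec.last + 1):
            out.extend(res_atoms_mobile(r))
        if r_from <= spec.ct_resseq:
            out.extend(
                s.index(ch, spec.ct_resseq, nm)
                for nm in ("N", "CA", "C")
                if s.index(ch, spec.ct_resseq, nm) in mobile_set
            )
        return out

    dofs = []

    def add(kind, r, axis, tors, moving):
        moving = np.array(sorted(set(moving)), dtype=int)
        dofs.append(
            DihedralDOF(
                index=len(dofs),
                kind=kind,
                resseq=r,
                axis=axis,
                torsion_atoms=tors,
                moving=moving,
                moving_rows=np.array([pos_of[int(i)] for i in moving], dtype=int),
            )
        )

    for r in range(spec.first, spec.last + 1):
        n_r = s.index(ch, r, "N")
        ca_r = s.index(ch, r, "CA")
        c_r = s.index(ch, r, "C")
        c_prev = s.index(ch, r - 1, "C")
        n_next = s.index(ch, r + 1, "N")
        # phi: everything of this residue past CA, plus all residues downstream
        moving_phi = [
            i for i in res_atoms_mobile(r) if i not in (n_r, ca_r)
        ] + downstream(r + 1)
        add("phi", r, (n_r, ca_r), (c_prev, n_r, ca_r, c_r), moving_phi)
        # psi: the carbonyl O plus all residues downstream
        moving_psi = [s.index(ch, r, "O")] + downstream(r + 1)
        add("psi", r, (ca_r, c_r), (n_r, ca_r, c_r, n_next), moving_psi)
        if spec.include_omega:
            ca_next = s.index(ch, r + 1, "CA")
            moving_om = [i for i in downstream(r + 1) if i != n_next]
            add("omega", r, (c_r, n_next), (ca_r, c_r, n_next, ca_next), moving_om)
    # phi of the Ct anchor: only its own C atom is mobile past the N-CA bond
    ct = spec.ct_resseq
    n_ct = s.index(ch, ct, "N")
    ca_ct = s.index(ch, ct, "CA")
    c_ct = s.index(ch, ct, "C")
    add(
        "phi", ct, (n_ct, ca_ct),
        (s.index(ch, spec.last, "C"), n_ct, ca_ct, c_ct),
        [c_ct] if c_ct in mobile_set else [],
    )
    assert len(dofs) == spec.n_dof
    return dofs


def extract_dihedrals(
    loop: LoopModel, coords: np.ndarray | None = None,
    dofs: list[DihedralDOF] | None = None,
) -> np.ndarray:
    """Current DOF values (radians, wrapped to (-pi, pi])."""
    if coords is None:
        coords = loop.structure.coords
    if dofs is None:
        dofs = define_dofs(loop)
    return np.array(
        [dihedral(*(coords[i] for i in d.torsion_atoms)) for d in dofs]
    )


def _rotation_matrix(axis_unit, angle):
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis_unit
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def apply_dihedrals(
    loop: LoopModel, q: np.ndarray,
    dofs: list[DihedralDOF] | None = None,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Rebuild coordinates so the DOFs take the values ``q``.

    Returns a full coordinate array (copy); only mobile atoms change.
    Each DOF is set by one exact rotation of its downstream atoms about
    the current bond axis, which preserves every non-DOF internal
    coordinate bit-exactly.  ``extract(apply(q)) == q``.
    """
    if dofs is None:
        dofs = define_dofs(loop)
    q = np.asarray(q, dtype=float)
    if q.shape != (len(dofs),):
        raise LoopModesError("dihedral vector length mismatch")
    out = np.array(
        loop.structure.coords if coords is None else coords, dtype=float
    )
    for d in dofs:
        cur = dihedral(*(out[i] for i in d.torsion_atoms))
        delta = float(wrap_angle(q[d.index] - cur))
        if abs(delta) < 1e-15 or d.moving.size == 0:
            continue
        a0 = out[d.axis[0]]
        e = out[d.axis[1]] - a0
        e = e / np.linalg.norm(e)
        R = _rotation_matrix(e, delta)
        out[d.moving] = (out[d.moving] - a0) @ R.T + a0
    return out


def cartesian_derivatives(
    loop: LoopModel,
    coords: np.ndarray | None = None,
    dofs: list[DihedralDOF] | None = None,
) -> np.ndarray:
    """Analytic d r_i / d q_a for every mobile atom, shape (3M, n), A/rad.

    For an atom i in the moving set of DOF a the derivative is
    ``e_a x (r_i - r_a)`` with ``e_a`` the unit bond axis and ``r_a`` a
    point on the axis; upstream atoms and environment atoms have exactly
    zero columns.
    """
    if coords is None:
        coords = loop.structure.coords
    if dofs is None:
        dofs = define_dofs(loop)
    m = loop.n_mobile
    D = np.zeros((3 * m, len(dofs)))
    for d in dofs:
        if d.moving.size == 0:
            continue
        a0 = coords[d.axis[0]]
        e = coords[d.axis[1]] - a0
        e = e / np.linalg.norm(e)
        disp = np.cross(e, coords[d.moving] - a0)  # (k, 3)
        rows = (3 * d.moving_rows[:, None] + np.arange(3)[None, :]).ravel()
        D[rows, d.index] = disp.ravel()
    return D


# ---------------------------------------------------------------------------
# Superposition and RMSD


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation R and translation t mapping P onto Q (least squares)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = qc - R @ pc
    return R, t


def backbone_rmsd(A: np.ndarray, B: np.ndarray, superpose: bool = False) -> float:
    """RMSD between two same-shape coordinate sets, optionally Kabsch-fitted."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise LoopModesError("coordinate sets must share shape (K, 3)")
    if superpose:
        R, t = kabsch(A, B)
        A = A @ R.T + t
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
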