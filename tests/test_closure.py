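"""Closure constraints, the bordered/null-space eigenproblem and mode counts."""

import numpy as np
import pytest
import scipy.linalg

from loopmodes.closure import (
    anchor_frame,
    compute_constrained_modes,
    constraint_jacobian,
    constraint_values,
    jacobian_matrix,
    solve_constrained,
    verify_closure,
)
from loopmodes.enm import solve_unconstrained
from loopmodes.errors import ConstraintRankError
from loopmodes.kinematics import apply_dihedrals, cartesian_derivatives, define_dofs, extract_dihedrals

from conftest import make_loop, random_phi_psi


class TestAnchorFrame:
    def test_orthonormal_triad(self, loop8):
        _, loop = loop8
        f = anchor_frame(loop)
        assert abs(f.u @ f.v) < 1e-12
        assert np.linalg.norm(f.u) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(f.v) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(f.w, np.cross(f.u, f.v), atol=1e-15)

    def test_rotation_equivariance(self, loop8, rng):
        structure, loop = loop8
        f0 = anchor_frame(loop)
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        rotated = structure.coords @ R.T
        f1 = anchor_frame(loop, coords=rotated)
        np.testing.assert_allclose(f1.u, R @ f0.u, atol=1e-12)
        np.testing.assert_allclose(f1.v, R @ f0.v, atol=1e-12)
        np.testing.assert_allclose(f1.w, R @ f0.w, atol=1e-12)

    def test_anchor_c_in_u_w_plane(self, loop8):
        """v is the plane normal, so r_C . v vanishes at equilibrium."""
        structure, loop = loop8
        f = anchor_frame(loop)
        ct = loop.spec.ct_resseq
        r_c = structure.coords[structure.index("A", ct, "C")] - f.origin
        assert abs(r_c @ f.v) < 1e-12


class TestConstraintJacobian:
    def test_shape_for_11_residue_loop(self, loop11):
        _, loop = loop11
        D = cartesian_derivatives(loop)
        cons = constraint_jacobian(loop, anchor_frame(loop), D)
        assert cons.jacobian.shape == (6, 23)

    def test_finite_difference_agreement(self, rng):
        _, loop = make_loop(6, phi_psi=random_phi_psi(6, rng))
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        D = cartesian_derivatives(loop, dofs=dofs)
        frame = anchor_frame(loop)
        cons = constraint_jacobian(loop, frame, D)
        h = 1e-6
        for a in range(len(dofs)):
            qp, qm = q.copy(), q.copy()
            qp[a] += h
            qm[a] -= h
            gp = constraint_values(loop, frame, apply_dihedrals(loop, qp, dofs=dofs))
            gm = constraint_values(loop, frame, apply_dihedrals(loop, qm, dofs=dofs))
            np.testing.assert_allclose(
                (gp - gm) / (2 * h), cons.jacobian[:, a], atol=1e-6
            )

    def test_moving_set_contract_in_columns(self, loop8):
        """Rows touching atoms outside a DOF's moving set are zero."""
        structure, loop = loop8
        dofs = define_dofs(loop)
        D = cartesian_derivatives(loop, dofs=dofs)
        cons = constraint_jacobian(loop, anchor_frame(loop), D)
        ct = loop.spec.ct_resseq
        anchor_atoms = {structure.index("A", ct, nm) for nm in ("N", "CA", "C")}
        # phi(Ct) moves only the anchor C: rows built on N and CA are zero
        last = dofs[-1]
        assert set(last.moving) == {structure.index("A", ct, "C")}
        np.testing.assert_allclose(cons.jacobian[0:5, last.index], 0.0,
                                   atol=1e-15)
        assert abs(cons.jacobian[5, last.index]) > 1e-3
        for d in dofs:
            if not (set(d.moving) & anchor_atoms):
                np.testing.assert_allclose(cons.jacobian[:, d.index], 0.0)

    def test_redundant_projections_do_not_raise_rank(self, loop8):
        """Appending r_N.u, r_C.u, r_C.w rows leaves rank 6 (fixed geometry)."""
        structure, loop = loop8
        D = cartesian_derivatives(loop)
        frame = anchor_frame(loop)
        cons = constraint_jacobian(loop, frame, D)
        ct = loop.spec.ct_resseq
        D3 = D.reshape(-1, 3, D.shape[1])
        rows = {
            nm: loop.mobile_pos(structure.index("A", ct, nm))
            for nm in ("N", "C")
        }
        extra = np.vstack(
            [
                frame.u @ D3[rows["N"]],
                frame.u @ D3[rows["C"]],
                frame.w @ D3[rows["C"]],
            ]
        )
        stacked = np.vstack([cons.jacobian, extra])
        assert np.linalg.matrix_rank(stacked, tol=1e-6) == 6

    def test_degenerate_anchor_rejected(self, loop8):
        _, loop = loop8
        D = cartesian_derivatives(loop)
        frame = anchor_frame(loop)
        with pytest.raises(ConstraintRankError):
            constraint_jacobian(loop, frame, np.zeros_like(D))


class TestConstrainedSolve:
    def test_17_modes_for_11_residue_loop(self, loop11):
        _, loop = loop11
        ctx = compute_constrained_modes(loop)
        assert ctx.modes.n_modes == 17

    @pytest.mark.parametrize("n_res", [4, 7, 13])
    def test_mode_count_2n_minus_5(self, n_res):
        _, loop = make_loop(n_res)
        ctx = compute_constrained_modes(loop)
        assert ctx.modes.n_modes == 2 * n_res - 5

    def test_omega_dofs_give_3n_minus_5(self):
        _, loop = make_loop(6, include_omega=True)
        ctx = compute_constrained_modes(loop)
        assert ctx.modes.n_modes == 3 * 6 - 5

    def test_modes_lie_in_constraint_null_space(self, loop8):
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        resid = ctx.constraints.jacobian @ ctx.modes.eigenvectors
        assert np.abs(resid).max() <= 1e-8

    def test_empty_constraints_reduce_to_unconstrained(self, loop8):
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        free = solve_constrained(ctx.H, ctx.T, np.empty((0, ctx.H.shape[0])))
        ref = solve_unconstrained(ctx.H, ctx.T)
        np.testing.assert_allclose(free.eigenvalues, ref.eigenvalues,
                                   rtol=1e-10, atol=1e-12)

    def test_nullspace_oracle_agreement(self, loop8):
        """Spectrum/subspace match an independently coded projection solve."""
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        J = ctx.constraints.jacobian
        # independent oracle: scipy QR-based null basis + dense eig of the
        # explicitly inverted reduced problem
        Z = scipy.linalg.null_space(J)
        Hr, Tr = Z.T @ ctx.H @ Z, Z.T @ ctx.T @ Z
        evals = np.sort(scipy.linalg.eigvals(np.linalg.solve(Tr, Hr)).real)
        np.testing.assert_allclose(ctx.modes.eigenvalues, evals, rtol=1e-8,
                                   atol=1e-10)
        Q1, _ = np.linalg.qr(ctx.modes.eigenvectors)
        overlap = np.linalg.svd(Q1.T @ Z, compute_uv=False).min()
        assert overlap >= 1 - 1e-8

    def test_lagrange_multipliers_close_stationarity(self, loop8):
        """(H - w^2 T) v + J^T lambda = 0 for every returned mode."""
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        J = ctx.constraints.jacobian
        for k in range(ctx.modes.n_modes):
            v = ctx.modes.eigenvectors[:, k]
            r = (
                ctx.H @ v
                - ctx.modes.eigenvalues[k] * (ctx.T @ v)
                + J.T @ ctx.modes.lagrange[:, k]
            )
            assert np.linalg.norm(r) < 1e-7 * max(
                1.0, abs(ctx.modes.eigenvalues[k])
            )


class TestVerifyClosure:
    def test_zero_amplitude_zero_error(self, loop8):
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        err = verify_closure(loop, ctx.q, ctx.modes.eigenvectors[:, 0], 0.0)
        assert err.max_error == 0.0

    def test_second_order_scaling(self, loop8):
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        amps = np.deg2rad(np.array([0.1, 0.25, 0.5, 1.0, 2.0]))
        errs = [
            verify_closure(
                loop, ctx.q, ctx.modes.eigenvectors[:, 0], a
            ).max_error
            for a in amps
        ]
        slope = np.polyfit(np.log(amps), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_constrained_beat_unconstrained_at_one_degree(self, loop8):
        _, loop = loop8
        ctx = compute_constrained_modes(loop)
        free = solve_unconstrained(ctx.H, ctx.T)
        amp = np.deg2rad(1.0)

        def ca_err(direction):
            d = direction / np.linalg.norm(direction)
            return verify_closure(loop, ctx.q, d, amp).ca_error

        free_err = ca_err(free.eigenvectors[:, 0])
        worst_constrained = max(
            ca_err(ctx.modes.eigenvectors[:, k])
            for k in range(ctx.modes.n_modes)
        )
        assert free_err > worst_constrained
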