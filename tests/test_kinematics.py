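"""Torsional DOFs, reconstruction, analytic derivatives and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopmodes.errors import DegenerateGeometryError, LoopModesError
from loopmodes.kinematics import (
    apply_dihedrals,
    backbone_rmsd,
    cartesian_derivatives,
    define_dofs,
    dihedral,
    extract_dihedrals,
    wrap_angle,
)

from conftest import make_loop, random_phi_psi


def torsion_oracle(p0, p1, p2, p3):
    """Independent IUPAC torsion oracle (Biopython's vector algebra)."""
    from Bio.PDB.vectors import Vector, calc_dihedral

    return calc_dihedral(Vector(*p0), Vector(*p1), Vector(*p2), Vector(*p3))


class TestDofDefinition:
    @pytest.mark.parametrize("n_res,omega,expected", [(11, False, 23),
                                                      (11, True, 34),
                                                      (4, False, 9)])
    def test_dof_count(self, n_res, omega, expected):
        _, loop = make_loop(n_res, include_omega=omega, scaffold=())
        assert len(define_dofs(loop)) == expected

    def test_last_dof_is_ct_phi_with_minimal_moving_set(self):
        structure, loop = make_loop(6, scaffold=())
        dofs = define_dofs(loop)
        last = dofs[-1]
        assert last.kind == "phi" and last.resseq == loop.spec.ct_resseq
        c_ct = structure.index("A", loop.spec.ct_resseq, "C")
        assert last.moving.tolist() == [c_ct]

    def test_moving_sets_nested(self):
        _, loop = make_loop(6, include_omega=True, scaffold=())
        dofs = define_dofs(loop)
        for a, b in zip(dofs, dofs[1:]):
            assert set(b.moving) <= set(a.moving)
        for d in dofs:
            assert d.axis[0] not in d.moving and d.axis[1] not in d.moving


class TestTorsions:
    def test_cis_arrangement_is_zero(self):
        p = [np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
             np.array([1.0, 0.0, 0.0]), np.array([1.0, 1.0, 0.0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_rejected(self):
        p = [np.array([float(i), 0.0, 0.0]) for i in range(3)]
        with pytest.raises(DegenerateGeometryError):
            dihedral(p[0], p[1], p[2], np.array([3.0, 1.0, 0.0]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3.0
        try:
            ours = dihedral(*pts)
        except DegenerateGeometryError:
            return
        assert ours == pytest.approx(torsion_oracle(*pts), abs=1e-9)


class TestReconstruction:
    def test_identity(self, loop8):
        structure, loop = loop8
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        out = apply_dihedrals(loop, q, dofs=dofs)
        np.testing.assert_allclose(out, structure.coords, atol=1e-9)

    def test_apply_extract_inverse(self, loop8, rng):
        _, loop = loop8
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        q2 = wrap_angle(q + rng.uniform(-0.5, 0.5, size=q.size))
        coords = apply_dihedrals(loop, q2, dofs=dofs)
        back = extract_dihedrals(loop, coords=coords, dofs=dofs)
        np.testing.assert_allclose(wrap_angle(back - q2), 0.0, atol=1e-9)

    def test_axis_atoms_immobile(self, loop8):
        structure, loop = loop8
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        q2 = q.copy()
        q2[0] = wrap_angle(q2[0] + np.pi)  # phi of first flexible residue
        out = apply_dihedrals(loop, q2, dofs=dofs)
        n1 = structure.index("A", 2, "N")
        ca1 = structure.index("A", 2, "CA")
        np.testing.assert_allclose(out[n1], structure.coords[n1], atol=1e-12)
        np.testing.assert_allclose(out[ca1], structure.coords[ca1], atol=1e-12)

    def test_non_dof_internals_preserved(self, rng):
        """Bond lengths, angles and omega torsions survive a large rebuild."""
        structure, loop = make_loop(7, phi_psi=random_phi_psi(7, rng),
                                    scaffold=())
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        q2 = wrap_angle(q + rng.uniform(-1.5, 1.5, size=q.size))
        out = apply_dihedrals(loop, q2, dofs=dofs)

        def bonded(c, r, n1, r2, n2):
            return np.linalg.norm(
                c[structure.index("A", r2, n2)] - c[structure.index("A", r, n1)]
            )

        for r in range(2, 8):
            for (r1, a1, r2, a2) in [(r, "N", r, "CA"), (r, "CA", r, "C"),
                                     (r, "C", r + 1, "N")]:
                assert bonded(out, r1, a1, r2, a2) == pytest.approx(
                    bonded(structure.coords, r1, a1, r2, a2), abs=1e-9
                )
            om = dihedral(
                out[structure.index("A", r, "CA")],
                out[structure.index("A", r, "C")],
                out[structure.index("A", r + 1, "N")],
                out[structure.index("A", r + 1, "CA")],
            )
            assert abs(wrap_angle(om - np.pi)) < 1e-9 or abs(om) == pytest.approx(
                np.pi, abs=1e-9
            )


class TestDerivatives:
    def test_finite_difference_agreement(self, rng):
        _, loop = make_loop(6, phi_psi=random_phi_psi(6, rng))
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        D = cartesian_derivatives(loop, dofs=dofs)
        h = 1e-6
        for a in range(len(dofs)):
            qp, qm = q.copy(), q.copy()
            qp[a] += h
            qm[a] -= h
            fd = (
                apply_dihedrals(loop, qp, dofs=dofs)[loop.mobile_idx]
                - apply_dihedrals(loop, qm, dofs=dofs)[loop.mobile_idx]
            ) / (2 * h)
            np.testing.assert_allclose(fd.ravel(), D[:, a], atol=1e-6)

    def test_upstream_columns_exactly_zero(self, loop8):
        _, loop = loop8
        dofs = define_dofs(loop)
        D = cartesian_derivatives(loop, dofs=dofs)
        n = len(dofs)
        for d in dofs:
            outside = np.setdiff1d(np.arange(loop.n_mobile), d.moving_rows)
            rows = (3 * outside[:, None] + np.arange(3)).ravel()
            assert np.all(D[rows, d.index] == 0.0)

    def test_first_order_consistency_slope(self, loop8, rng):
        _, loop = loop8
        dofs = define_dofs(loop)
        q = extract_dihedrals(loop, dofs=dofs)
        D = cartesian_derivatives(loop, dofs=dofs)
        direction = rng.normal(size=q.size)
        direction /= np.linalg.norm(direction)
        base = loop.structure.coords[loop.mobile_idx].ravel()
        deltas = np.logspace(-4, -2, 6)
        errs = []
        for d in deltas:
            moved = apply_dihedrals(loop, q + d * direction, dofs=dofs)
            lin = base + D @ (d * direction)
            errs.append(
                np.linalg.norm(moved[loop.mobile_idx].ravel() - lin)
            )
        slope = np.polyfit(np.log(deltas), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)


class TestRMSD:
    def test_identity_and_translation(self, rng):
        A = rng.normal(size=(12, 3))
        assert backbone_rmsd(A, A) == 0.0
        B = A + np.array([1.0, 0.0, 0.0])
        assert backbone_rmsd(A, B, superpose=False) == pytest.approx(1.0)
        assert backbone_rmsd(A, B, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(LoopModesError):
            backbone_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_matches_quaternion_oracle(self, rng):
        """Kabsch result equals Horn's quaternion superposition."""
        for _ in range(5):
            A = rng.normal(size=(15, 3)) * 4
            R_true, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(R_true) < 0:
                R_true[:, 0] *= -1
            B = A @ R_true.T + rng.normal(size=3) + rng.normal(size=(15, 3)) * 0.3

            # quaternion-based oracle
            Ac = A - A.mean(0)
            Bc = B - B.mean(0)
            S = Ac.T @ Bc
            K = np.array(
                [
                    [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
                     S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
                    [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
                     S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
                    [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
                     -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
                    [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1],
                     -S[0, 0] - S[1, 1] + S[2, 2]],
                ]
            )
            lam = np.linalg.eigvalsh(K)[-1]
            e2 = max((Ac**2).sum() + (Bc**2).sum() - 2 * lam, 0.0)
            oracle = np.sqrt(e2 / A.shape[0])
            assert backbone_rmsd(A, B, superpose=True) == pytest.approx(
                oracle, abs=1e-9
            )
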