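"""Elastic network model and the torsion-space generalized eigenproblem.

The potential energy is a network of Hookean springs between heavy atoms
(loop + fixed environment), at its minimum in the input structure.  In
the torsional coordinates q the vibrational problem is

    H v = w^2 T v

with H the second-derivative (Hessian) matrix of the spring energy and T
the kinetic-energy (mass-metric) matrix, both n x n where n is the number
of dihedral DOFs.  Environment atoms carry springs into the loop but have
zero derivatives, which grounds the loop modes in the surrounding protein.
No Eckart conditions are applied: the anchored loop has no global
rigid-body freedom to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .errors import LoopModesError, SolverError

#: default spring rule: k = k0 / d0^2 for all pairs within 10 A
DEFAULT_ENM_RULE = {"rule": "power", "k0": 1.0, "power": 2.0, "cutoff": 10.0}


@dataclass
class ElasticNetwork:
    """Spring list over the network atoms (mobile block first, then environment).

    ``i``/``j`` index into the network atom ordering; ``k`` are force
    constants and ``d0`` the equilibrium distances.
    """

    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    d0: np.ndarray
    u: np.ndarray  # (n_springs, 3) unit vectors r_j - r_i at equilibrium

    @property
    def n_springs(self) -> int:
        return self.i.size


@dataclass
class ModeSet:
    """Eigenpairs of the (unconstrained) torsion-space eigenproblem.

    ``eigenvalues`` (w^2) ascend; eigenvector columns are T-orthonormal.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    metric: str = "T"

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def build_elastic_network(coords: np.ndarray, rule: dict | None = None) -> ElasticNetwork:
    """Connect atom pairs by springs according to ``rule``.

    ``rule["rule"]`` is ``"cutoff"`` (k = k0 for d0 <= cutoff) or
    ``"power"`` (k = k0 * d0**(-power) for d0 <= cutoff).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise LoopModesError("elastic network needs at least 2 atoms")
    rule = {**DEFAULT_ENM_RULE, **(rule or {})}
    cutoff = float(rule["cutoff"])
    if cutoff <= 0:
        empty = np.empty(0)
        return ElasticNetwork(
            np.empty(0, int), np.empty(0, int), empty, empty, np.empty((0, 3))
        )
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        empty = np.empty(0)
        return ElasticNetwork(
            np.empty(0, int), np.empty(0, int), empty, empty, np.empty((0, 3))
        )
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = coords[j] - coords[i]
    d0 = np.linalg.norm(dvec, axis=1)
    if rule["rule"] == "cutoff":
        k = np.full(d0.shape, float(rule["k0"]))
    elif rule["rule"] == "power":
        k = float(rule["k0"]) * d0 ** (-float(rule["power"]))
    else:
        raise LoopModesError(f"unknown ENM rule {rule['rule']!r}")
    return ElasticNetwork(i, j, k, d0, dvec / d0[:, None])


def spring_jacobian(net: ElasticNetwork, D: np.ndarray, n_mobile: int) -> np.ndarray:
    """d d_ij / d q_a for every spring, shape (n_springs, n).

    ``D`` is the (3M, n) mobile-atom derivative matrix; network atoms with
    index >= n_mobile are environment (zero derivatives).
    """
    n = D.shape[1]
    S = np.zeros((net.n_springs, n))
    D3 = D.reshape(n_mobile, 3, n)
    # d|r_j - r_i|/dq = u_ij . (dr_j/dq - dr_i/dq); environment terms are zero
    mi = net.i < n_mobile
    if np.any(mi):
        S[mi] -= np.einsum("sd,sdn->sn", net.u[mi], D3[net.i[mi]])
    mj = net.j < n_mobile
    if np.any(mj):
        S[mj] += np.einsum("sd,sdn->sn", net.u[mj], D3[net.j[mj]])
    return S


def internal_hessian(net: ElasticNetwork, D: np.ndarray, n_mobile: int) -> np.ndarray:
    """Torsion-space Hessian H_ab = sum_springs k (dd/dq_a)(dd/dq_b).

    The first-derivative (force) term vanishes because the input structure
    is the ENM minimum, so H is the Gram matrix of the spring-length
    derivatives and is symmetric PSD by construction.
    """
    S = spring_jacobian(net, D, n_mobile)
    H = (S * net.k[:, None]).T @ S
    return 0.5 * (H + H.T)


def kinetic_matrix(masses: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Mass-metric T_ab = sum_i m_i (dr_i/dq_a).(dr_i/dq_b)."""
    masses = np.asarray(masses, dtype=float)
    w = np.repeat(masses, 3)
    T = D.T @ (w[:, None] * D)
    return 0.5 * (T + T.T)


def _regularize(T: np.ndarray) -> np.ndarray:
    """Tiny diagonal shift if T is numerically rank deficient."""
    n = T.shape[0]
    scale = np.trace(T) / n
    if scale <= 0:
        raise SolverError("kinetic matrix has non-positive trace")
    evals = np.linalg.eigvalsh(T)
    if evals[0] < 1e-12 * scale:
        T = T + (1e-10 * scale) * np.eye(n)
    return T


def solve_unconstrained(H: np.ndarray, T: np.ndarray) -> ModeSet:
    """Solve H v = w^2 T v; ascending eigenvalues, T-orthonormal vectors."""
    H = np.asarray(H, dtype=float)
    T = _regularize(np.asarray(T, dtype=float))
    try:
        evals, vecs = scipy.linalg.eigh(H, T)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise SolverError(
            f"generalized eigensolver failed (cond(T)={np.linalg.cond(T):.2e})"
        ) from exc
    return ModeSet(evals, vecs)
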