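"""Essential-dynamics comparison of loop conformational ensembles.

Two ensembles of the same loop (e.g. an MD trajectory and an NMA
pseudo-trajectory) are compared through PCA of the Cartesian covariance
of their backbone atoms about the member closest to the ensemble
average.  The similarity of the dominant-motion subspaces is the
overlap

    gamma = (1 / max(m_A, m_B)) * sum_{i<=m_A} sum_{j<=m_B} (u_i . w_j)^2

over the smallest eigenvector counts m explaining 90% of each
ensemble's variance (gamma = 1 when complete bases are compared), and
is referred to a null distribution built by randomly permuting the atom
order independently in every snapshot of the second ensemble and
re-doing its PCA, yielding a Z-score.  Eigenvector-derived B-factor
profiles give a per-residue view of the same comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .errors import LoopModesError
from .sampling import BACKBONE_FOR_RMSD, Ensemble
from .structure import LoopSpec, Structure


@dataclass
class PCAResult:
    """Cartesian-covariance decomposition of one ensemble.

    Eigenvalues (A^2) descend; eigenvector columns (3K entries) are
    orthonormal.  ``reference`` is the snapshot closest to the coordinate
    mean, about which displacements were taken; ``m90`` is the smallest
    number of eigenvectors explaining >= 90% of the total variance.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    reference: np.ndarray
    reference_index: int
    n_atoms: int

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def m_for(self, variance_fraction: float = 0.9) -> int:
        """Smallest eigenvector count explaining the given variance fraction."""
        tot = self.total_variance
        if tot <= 0:
            return 0
        csum = np.cumsum(self.eigenvalues) / tot
        return int(np.searchsorted(csum, variance_fraction - 1e-12) + 1)

    @property
    def m90(self) -> int:
        return self.m_for(0.9)


@dataclass
class OverlapResult:
    """Subspace overlap of two ensembles with its permutation-null Z-score."""

    gamma: float
    m_a: int
    m_b: int
    zscore: float
    null_mean: float
    null_std: float
    n_null: int
    seed: int
    degenerate_null: bool = False  # sigma_null == 0


def backbone_coordinates(source, spec: LoopSpec) -> np.ndarray:
    """Snapshot array (S, K, 3) of the loop-residue backbone atoms (N, CA, C, O).

    ``source`` is an :class:`~loopmodes.sampling.Ensemble` or a list of
    :class:`~loopmodes.structure.Structure` (e.g. models of a multi-model
    PDB).
    """
    if isinstance(source, Ensemble):
        s = source.structure
        idx = [
            s.index(spec.chain, r, nm)
            for r in range(spec.first, spec.last + 1)
            for nm in BACKBONE_FOR_RMSD
        ]
        return np.stack([source.full_coords(k)[idx] for k in range(len(source))])
    models = list(source)
    if not models:
        raise LoopModesError("no snapshots")
    out = []
    for m in models:
        idx = [
            m.index(spec.chain, r, nm)
            for r in range(spec.first, spec.last + 1)
            for nm in BACKBONE_FOR_RMSD
        ]
        out.append(m.coords[idx])
    return np.stack(out)


def loop_residue_index(spec: LoopSpec) -> np.ndarray:
    """Residue label per backbone atom, aligned with :func:`backbone_coordinates`."""
    return np.repeat(
        np.arange(spec.first, spec.last + 1), len(BACKBONE_FOR_RMSD)
    )


def pca(snapshots: np.ndarray) -> PCAResult:
    """PCA of the Cartesian covariance about the closest-to-average snapshot.

    ``snapshots`` has shape (S, K, 3) with S >= 2 consistent frames.  The
    reference is the member minimizing the RMSD to the coordinate mean;
    the covariance of displacements about it is diagonalized
    (mass-unweighted).
    """
    X = np.asarray(snapshots, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2 or X.shape[2] != 3:
        raise LoopModesError("need an (S, K, 3) array with at least 2 snapshots")
    S, K, _ = X.shape
    mean = X.mean(axis=0)
    ref_idx = int(np.argmin(((X - mean) ** 2).sum(axis=(1, 2))))
    ref = X[ref_idx]
    disp = (X - ref).reshape(S, 3 * K)
    cov = disp.T @ disp / S
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    return PCAResult(evals, evecs, ref, ref_idx, K)


def subspace_overlap(
    a: PCAResult,
    b: PCAResult,
    variance_fraction: float = 0.9,
    m: int | None = None,
    method: str = "count",
) -> float:
    """Overlap gamma of the dominant subspaces of two decompositions.

    With ``method="count"`` (default): the normalized sum of squared
    inner products over the top m_A x m_B eigenvector pairs, m chosen per
    ensemble from ``variance_fraction`` (or fixed by ``m``); equals 1 when
    complete bases are compared.  ``method="rwsip"`` gives the
    eigenvalue-weighted root-weighted-square-inner-product variant.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise LoopModesError("ensembles decompose different atom selections")
    if method == "rwsip":
        la, lb = a.eigenvalues, b.eigenvalues
        M = a.eigenvectors.T @ b.eigenvectors
        num = float(la @ (M**2) @ lb)
        den = float(np.sum(la * lb))
        if den <= 0:
            raise LoopModesError("degenerate spectra for RWSIP")
        return float(np.sqrt(num / den))
    if method != "count":
        raise LoopModesError(f"unknown overlap method {method!r}")
    if m is not None:
        m_a = m_b = int(m)
    else:
        m_a = a.m_for(variance_fraction)
        m_b = b.m_for(variance_fraction)
    if m_a == 0 or m_b == 0:
        raise LoopModesError("zero-variance ensemble has no dominant subspace")
    U = a.eigenvectors[:, :m_a]
    W = b.eigenvectors[:, :m_b]
    return float(np.sum((U.T @ W) ** 2) / max(m_a, m_b))


def overlap_zscore(
    snapshots_a: np.ndarray,
    snapshots_b: np.ndarray,
    variance_fraction: float = 0.9,
    m: int | None = None,
    n_null: int = 1000,
    seed: int = 0,
    permute_both: bool = False,
) -> OverlapResult:
    """gamma between two ensembles and its Z-score against a permutation null.

    The null randomizes ensemble B: every snapshot's atom order is
    permuted independently (one permutation per snapshot, applied to all
    three coordinates of an atom), its PCA is redone and gamma
    recomputed; ``n_null`` such models give the null mean and standard
    deviation.  ``permute_both`` additionally randomizes ensemble A.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    A = pca(snapshots_a)
    B = pca(snapshots_b)
    m_a = int(m) if m is not None else A.m_for(variance_fraction)
    m_b = int(m) if m is not None else B.m_for(variance_fraction)
    gamma = subspace_overlap(A, B, variance_fraction, m=m)
    XB = np.asarray(snapshots_b, dtype=float)
    XA = np.asarray(snapshots_a, dtype=float)
    nulls = np.empty(n_null)
    for t in range(n_null):
        XBp = np.stack([x[rng.permutation(x.shape[0])] for x in XB])
        Ap = A
        if permute_both:
            XAp = np.stack([x[rng.permutation(x.shape[0])] for x in XA])
            Ap = pca(XAp)
        nulls[t] = subspace_overlap(Ap, pca(XBp), variance_fraction, m=m)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=0))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (gamma - mu) / sd
    return OverlapResult(gamma, m_a, m_b, z, mu, sd, n_null, int(seed), degenerate)


def bfactor_profile(p: PCAResult, residue_index: np.ndarray) -> tuple:
    """Per-residue B-factors from the eigenvector decomposition.

    The per-atom mean-square fluctuation sum_k lambda_k |u_k(atom)|^2 is
    scaled by 8 pi^2 / 3 and averaged over the backbone atoms of each
    residue.  Returns (residue labels, B values).
    """
    residue_index = np.asarray(residue_index)
    if residue_index.size != p.n_atoms:
        raise LoopModesError("residue index length must match the atom selection")
    U2 = (p.eigenvectors**2).reshape(p.n_atoms, 3, -1).sum(axis=1)
    msf = U2 @ p.eigenvalues  # (K,)
    b_atom = (8.0 * np.pi**2 / 3.0) * msf
    labels = []
    values = []
    for r in dict.fromkeys(residue_index.tolist()):
        labels.append(r)
        values.append(float(b_atom[residue_index == r].mean()))
    return np.array(labels), np.array(values)


def spearman_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise LoopModesError("profiles must share a length of at least 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise LoopModesError("zero-variance profile has no rank correlation")
    rho = spearmanr(a, b).statistic
    return float(rho)
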