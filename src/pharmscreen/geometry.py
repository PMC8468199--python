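"""Rigid-body superposition (Kabsch) shared by mapping and trajectory code."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper-rotation alignment of one point set onto another.

    ``rotation`` is orthonormal with determinant +1 (reflections are never
    allowed); ``degenerate`` flags near-collinear/planar-rank-deficient input
    where the rotation is not unique.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q.

    Finds the proper rotation R and translation t minimizing
    ``sum_i |R p_i + t - q_i|^2`` via SVD of the cross-covariance matrix,
    with the standard sign correction so that det(R) = +1.  Point sets with
    fewer than 3 points, or rank-deficient (collinear) configurations, are
    solved in the least-squares sense and flagged degenerate.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = P.shape[0]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    aligned = P @ R.T + t
    rmsd = float(np.sqrt(((aligned - Q) ** 2).sum() / n))
    # rank < 2 means the rotation about the degenerate axis is arbitrary
    degenerate = n < 3 or int(np.linalg.matrix_rank(P0, tol=1e-8)) < 2
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               degenerate=degenerate)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed proper rotation matrix (via QR of a Gaussian)."""
    M = rng.normal(size=(3, 3))
    Qm, Rm = np.linalg.qr(M)
    Qm *= np.sign(np.diag(Rm))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm
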