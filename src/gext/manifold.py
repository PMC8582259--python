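"""Grassmann-manifold primitives for idempotent density matrices.

A closed-shell single-determinant density is fully determined by the span of
its occupied orbitals.  After Löwdin orthonormalization, the occupied
coefficient matrix ``C`` (``N_b x N``, orthonormal columns) is a point on the
Stiefel manifold, and the projector ``D = C C^T`` (symmetric, idempotent,
trace ``N``) represents the corresponding point on the Grassmann manifold of
``N``-dimensional subspaces of ``R^{N_b}``.

This module provides the two maps that make linear extrapolation of densities
possible: the Grassmann logarithm, taking a nearby subspace to a tangent
vector at a reference frame ``C0`` (horizontal lift, ``C0^T Gamma = 0``), and
the Grassmann exponential, its local inverse.  Both reduce to one thin SVD.

With principal angles ``theta_k`` between ``span(C0)`` and ``span(C)``, the
maps are

    Log:  L = (I - C0 C0^T) C (C0^T C)^{-1},  L = U S V^T (thin SVD),
          Gamma = U arctan(S) V^T
    Exp:  Gamma = U S V^T,  C = C0 V cos(S) V^T + U sin(S) V^T

and are mutually inverse as long as every principal angle stays below pi/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as la

from .errors import (
    InjectivityDomainError,
    LinearDependenceError,
    RankDeficientFrameError,
    TangentSpaceError,
)

logger = logging.getLogger(__name__)

#: tolerance to which frames are expected to have orthonormal columns
FRAME_TOL = 1e-10
#: default residual threshold of the post-exponential orthonormality safeguard
GUARD_THRESHOLD = 1e-8
#: default eigenvalue floor below which an overlap matrix is declared singular
OVERLAP_EIG_FLOOR = 1e-10


def _as_matrix(frame) -> np.ndarray:
    """Accept either a bare ndarray or an OrthonormalFrame."""
    if isinstance(frame, OrthonormalFrame):
        return frame.C
    return np.asarray(frame, dtype=float)


@dataclass(frozen=True)
class OrthonormalFrame:
    """An ``N_b x N`` matrix with orthonormal columns (Stiefel element).

    The columns are occupied orbitals in the Löwdin-orthonormalized
    representation; the associated density projector is :meth:`projector`.
    """

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.array(self.C, dtype=float)
        if C.ndim != 2:
            raise ValueError("frame must be a 2-D matrix")
        if C.shape[1] > C.shape[0]:
            raise ValueError(f"n_occ {C.shape[1]} exceeds n_basis {C.shape[0]}")
        defect = np.linalg.norm(C.T @ C - np.eye(C.shape[1]))
        if defect > FRAME_TOL:
            raise ValueError(
                f"columns are not orthonormal: ||C^T C - I||_F = {defect:.3e}"
            )
        C.setflags(write=False)
        object.__setattr__(self, "C", C)

    @property
    def n_basis(self) -> int:
        return self.C.shape[0]

    @property
    def n_occ(self) -> int:
        return self.C.shape[1]

    def projector(self) -> np.ndarray:
        """The idempotent density projector ``D = C C^T`` (trace = n_occ)."""
        return self.C @ self.C.T


def overlap_roots(
    S: np.ndarray, threshold: float = OVERLAP_EIG_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric square root and inverse square root of an overlap matrix.

    Both roots are computed from one symmetric eigendecomposition, which keeps
    them exactly symmetric and guarantees ``S^{1/2} S^{-1/2} = I`` to round-off.

    Raises
    ------
    LinearDependenceError
        If the smallest eigenvalue of ``S`` is at or below ``threshold``,
        i.e. the basis is numerically linearly dependent.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"overlap matrix must be square, got {S.shape}")
    if np.max(np.abs(S - S.T)) > 1e-8 * max(1.0, np.max(np.abs(S))):
        raise ValueError("overlap matrix is not symmetric")
    w, V = la.eigh(0.5 * (S + S.T))
    if w[0] <= threshold:
        raise LinearDependenceError(
            f"overlap matrix is near-singular: smallest eigenvalue "
            f"{w[0]:.6e} <= threshold {threshold:.6e}"
        )
    sq = np.sqrt(w)
    S_half = (V * sq) @ V.T
    S_inv_half = (V / sq) @ V.T
    return S_half, S_inv_half


def lowdin_orthonormalize(
    C_ao: np.ndarray,
    S: np.ndarray,
    check_tol: float = 1e-6,
    S_half: np.ndarray | None = None,
) -> OrthonormalFrame:
    """Löwdin-orthonormalize S-orthonormal AO-basis orbitals: ``C~ = S^{1/2} C``.

    ``C_ao`` must satisfy ``C_ao^T S C_ao = I`` within ``check_tol`` (as the
    occupied block of a converged generalized eigenproblem does).  ``S_half``
    may be passed to reuse a precomputed square root.
    """
    C_ao = np.asarray(C_ao, dtype=float)
    S = np.asarray(S, dtype=float)
    if C_ao.ndim != 2 or C_ao.shape[0] != S.shape[0]:
        raise ValueError(
            f"dimension mismatch: C is {C_ao.shape}, S is {S.shape}"
        )
    gram = C_ao.T @ S @ C_ao
    defect = np.linalg.norm(gram - np.eye(C_ao.shape[1]))
    if defect > check_tol:
        raise ValueError(
            f"input orbitals are not S-orthonormal: ||C^T S C - I||_F = {defect:.3e}"
        )
    if S_half is None:
        S_half, _ = overlap_roots(S)
    C = S_half @ C_ao
    # clean up round-off so the frame invariant holds at 1e-10
    return OrthonormalFrame(orthonormality_guard(C, residual_threshold=FRAME_TOL))


def _deterministic_thin_svd(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with a fixed sign convention.

    Singular values come out descending (LAPACK); the sign of each pair of
    singular vectors is fixed by forcing the largest-magnitude entry of each
    left singular vector to be positive, so results are reproducible across
    platforms and LAPACK builds.
    """
    U, s, Vt = la.svd(A, full_matrices=False)
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, s, Vt


def grassmann_log(C0, C) -> np.ndarray:
    """Grassmann logarithm of ``span(C)`` at the reference frame ``C0``.

    Returns the horizontal-lift tangent vector ``Gamma`` (``N_b x N``,
    ``C0^T Gamma = 0``) whose exponential recovers the subspace of ``C``.
    Depends on ``C`` only through its column span (gauge independent).

    Raises
    ------
    InjectivityDomainError
        If ``C0^T C`` is singular, i.e. some principal angle reached pi/2 and
        the subspace left the injectivity domain of the logarithm; the caller
        should move to a new reference point.
    """
    C0 = _as_matrix(C0)
    C = _as_matrix(C)
    if C0.shape != C.shape:
        raise ValueError(f"frame shapes differ: {C0.shape} vs {C.shape}")
    M = C0.T @ C
    smin = np.min(la.svdvals(M)) if M.size else 0.0
    if smin < 1e-12:
        raise InjectivityDomainError(
            "C0^T C is singular (a principal angle reached pi/2): the point is "
            "out of the injectivity domain of the Grassmann logarithm; choose "
            "a new reference point"
        )
    L = (C - C0 @ M) @ la.inv(M)
    U, s, Vt = _deterministic_thin_svd(L)
    return (U * np.arctan(s)) @ Vt


def grassmann_exp(C0, Gamma: np.ndarray, check_tol: float = 1e-6) -> np.ndarray:
    """Grassmann exponential: map a tangent vector at ``C0`` back to a frame.

    ``Gamma`` must be horizontal at ``C0`` (``C0^T Gamma = 0`` within
    ``check_tol``).  The returned frame has orthonormal columns up to
    round-off; callers that need a strict guarantee should pass the result
    through :func:`orthonormality_guard`.
    """
    C0 = _as_matrix(C0)
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.shape != C0.shape:
        raise ValueError(f"tangent shape {Gamma.shape} != frame shape {C0.shape}")
    defect = np.max(np.abs(C0.T @ Gamma)) if Gamma.size else 0.0
    if defect > check_tol:
        raise TangentSpaceError(
            f"tangent vector is not horizontal at C0: max|C0^T Gamma| = {defect:.3e}"
        )
    U, s, Vt = _deterministic_thin_svd(Gamma)
    V = Vt.T
    return C0 @ (V * np.cos(s)) @ Vt + (U * np.sin(s)) @ Vt


def orthonormality_guard(
    C: np.ndarray, residual_threshold: float = GUARD_THRESHOLD
) -> np.ndarray:
    """Return ``C`` unchanged if its columns are orthonormal within threshold,
    otherwise the closest orthonormal frame (polar factor), with a warning.

    This is the safeguard applied after every exponential map: accumulated
    round-off in the SVD-based formulas can leave a small orthonormality
    residue, which would otherwise leak into the idempotency of ``C C^T``.

    Raises
    ------
    RankDeficientFrameError
        If ``C`` does not have full column rank (e.g. a zero column), in which
        case no nearby orthonormal frame spans an ``N``-dimensional subspace.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[1]
    residual = np.linalg.norm(C.T @ C - np.eye(n))
    if residual <= residual_threshold:
        return C
    U, s, Vt = la.svd(C, full_matrices=False)
    if s[-1] < 1e-10 * max(1.0, s[0]):
        raise RankDeficientFrameError(
            f"frame is rank deficient: smallest singular value {s[-1]:.3e}"
        )
    logger.warning(
        "orthonormality residual %.3e above threshold %.3e: re-orthonormalizing",
        residual,
        residual_threshold,
    )
    return U @ Vt


def projector_distance(A, B) -> float:
    """Frobenius distance between the density projectors of two frames.

    The natural gauge-free comparison of two subspaces: invariant under any
    orbital-mixing rotation of either frame.
    """
    A = _as_matrix(A)
    B = _as_matrix(B)
    return float(np.linalg.norm(A @ A.T - B @ B.T))
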