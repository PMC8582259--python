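"""The G-Ext core: tangent-space extrapolation of SCF density matrices.

Given converged densities at the previous ``N_t`` MD steps, the method

1. maps each converged occupied frame to a tangent vector ``Gamma_i`` at a
   fixed reference frame ``C0`` via the Grassmann logarithm,
2. fits the new geometry's Coulomb descriptor ``d`` as a linear combination
   of the stored descriptors by Tikhonov-regularized least squares,

       min_c ||P^T c - d||^2 + eps^2 ||c||^2,

3. forms ``Gamma* = sum_i c_i Gamma_i`` and maps it back through the
   Grassmann exponential, yielding a guess density that is idempotent with
   the correct trace *by construction*.

Because the reference point is fixed, each MD step costs exactly one
logarithm (for the newly converged density) and one exponential (for the
guess): two thin SVDs in total.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

from .descriptor import coulomb_matrix, descriptor_matrix
from .errors import ConvergenceError, InjectivityDomainError
from .geometry import Geometry
from .manifold import (
    OrthonormalFrame,
    grassmann_exp,
    grassmann_log,
    lowdin_orthonormalize,
    orthonormality_guard,
    overlap_roots,
)

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for the (rank-revealing) least-squares solve
LSTSQ_RCOND = 1e-12
#: minimum stored snapshots before extrapolation is attempted
DEFAULT_MIN_SNAPSHOTS = 3


@dataclass(frozen=True)
class CoefficientSolution:
    """Solution of the (regularized) descriptor fit."""

    c: np.ndarray
    residual: float
    epsilon: float


def solve_coefficients(
    P: np.ndarray, d: np.ndarray, epsilon: float = 0.0
) -> CoefficientSolution:
    """Fit descriptor ``d`` as a combination of the rows of ``P``.

    Solves ``min_c ||P^T c - d||^2 + eps^2 ||c||^2`` via the padded
    least-squares system ``[P^T; eps I] c ~ [d; 0]``.  With ``eps = 0`` and a
    rank-deficient/underdetermined system the minimum-norm solution is
    returned (SVD-based solver with relative cutoff ``LSTSQ_RCOND``).

    The reported ``residual`` is the *unpadded* misfit ``||P^T c - d||``.
    """
    P = np.asarray(P, dtype=float)
    d = np.asarray(d, dtype=float)
    if P.ndim != 2 or d.ndim != 1 or P.shape[1] != d.shape[0]:
        raise ValueError(f"incompatible shapes: P {P.shape}, d {d.shape}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite entries in descriptor system")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    n_t = P.shape[0]
    A = P.T
    b = d
    if epsilon > 0:
        A = np.vstack([A, epsilon * np.eye(n_t)])
        b = np.concatenate([d, np.zeros(n_t)])
    c, _, _, _ = la.lstsq(A, b, cond=LSTSQ_RCOND, lapack_driver="gelsd")
    residual = float(np.linalg.norm(P.T @ c - d))
    return CoefficientSolution(c=c, residual=residual, epsilon=float(epsilon))


@dataclass(frozen=True)
class GuessDensity:
    """An extrapolated guess density in both representations.

    ``D_ortho`` is exactly idempotent with trace = n_occ (built as ``C C^T``
    from a guarded orthonormal frame); ``D_ao`` is its back-transformation
    ``S^{-1/2} D_ortho S^{-1/2}`` with the *current* geometry's overlap.
    """

    D_ao: np.ndarray
    D_ortho: np.ndarray
    frame: OrthonormalFrame
    coefficients: CoefficientSolution


class SnapshotHistory:
    """Ring buffer of (descriptor, tangent vector) pairs at a fixed reference.

    The reference frame ``C0`` is chosen once (normally the first converged
    frame of the run); every stored snapshot is the Grassmann logarithm of a
    converged frame at that reference, paired with the geometry's descriptor.
    Oldest entries are evicted first once ``capacity`` is reached.
    """

    def __init__(self, capacity: int, reference: OrthonormalFrame):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self.reference = (
            reference
            if isinstance(reference, OrthonormalFrame)
            else OrthonormalFrame(reference)
        )
        self._entries: deque[tuple[np.ndarray, np.ndarray]] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def descriptors(self) -> list[np.ndarray]:
        return [d for d, _ in self._entries]

    @property
    def tangents(self) -> list[np.ndarray]:
        return [g for _, g in self._entries]

    def push(self, C_converged, d: np.ndarray) -> "SnapshotHistory":
        """Log the converged frame at the reference and append the snapshot.

        Exactly one logarithm (one SVD) is evaluated per call.
        """
        d = np.asarray(d, dtype=float)
        if self._entries and d.shape != self._entries[0][0].shape:
            raise ValueError("descriptor length differs from stored snapshots")
        gamma = grassmann_log(self.reference, C_converged)
        self._entries.append((d, gamma))
        return self

    def clear(self) -> None:
        self._entries.clear()


# spec-style free-function alias
def push_snapshot(h: SnapshotHistory, C_converged, d: np.ndarray) -> SnapshotHistory:
    return h.push(C_converged, d)


def extrapolate_guess(
    h: SnapshotHistory,
    d_new: np.ndarray,
    S_new: np.ndarray,
    epsilon: float,
    min_snapshots: int = DEFAULT_MIN_SNAPSHOTS,
    guard_threshold: float = 1e-8,
) -> GuessDensity | None:
    """Assemble the G-Ext guess density for a new geometry.

    Returns ``None`` (fallback sentinel) when fewer than ``min_snapshots``
    snapshots are stored or the exponential map fails; the caller should then
    fall back to its previous converged density.
    """
    if len(h) < min_snapshots:
        return None
    P = descriptor_matrix(h.descriptors)
    sol = solve_coefficients(P, np.asarray(d_new, dtype=float), epsilon)
    gamma_star = np.tensordot(sol.c, np.array(h.tangents), axes=1)
    try:
        C = grassmann_exp(h.reference, gamma_star)
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"Grassmann exponential failed ({exc}); falling back")
        return None
    C = orthonormality_guard(C, residual_threshold=guard_threshold)
    frame = OrthonormalFrame(C)
    D_ortho = frame.projector()
    _, S_inv_half = overlap_roots(np.asarray(S_new, dtype=float))
    D_ao = S_inv_half @ D_ortho @ S_inv_half
    return GuessDensity(D_ao=D_ao, D_ortho=D_ortho, frame=frame, coefficients=sol)


def mcweeny_step(D: np.ndarray) -> np.ndarray:
    """One McWeeny purification sweep ``D <- 3 D^2 - 2 D^3``."""
    D2 = D @ D
    return 3.0 * D2 - 2.0 * (D2 @ D)


def idempotency_defect(D: np.ndarray) -> float:
    """``||D^2 - D||_F``, zero iff D is an exact projector."""
    return float(np.linalg.norm(D @ D - D))


def mcweeny_purify(
    D: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> np.ndarray:
    """Drive a near-projector matrix to exact idempotency.

    Iterates ``D <- 3 D^2 - 2 D^3`` until ``||D^2 - D||_F <= tol``.  The
    scalar map sends eigenvalues in (-1/2, 1/2) to 0 and in (1/2, 3/2) to 1,
    so the trace of a near-projector input is preserved to tolerance.  A
    warning is emitted when eigenvalues start outside that basin.
    """
    D = np.asarray(D, dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-8 * max(1.0, np.max(np.abs(D))):
        raise ValueError("McWeeny purification expects a symmetric matrix")
    w = la.eigvalsh(D)
    if np.any(w < -0.5) or np.any(w > 1.5):
        warnings.warn(
            f"eigenvalues outside the McWeeny convergence basin "
            f"[-0.5, 1.5]: min {w[0]:.3f}, max {w[-1]:.3f}"
        )
    for _ in range(max_iter):
        if idempotency_defect(D) <= tol:
            return D
        D = mcweeny_step(D)
    residual = idempotency_defect(D)
    if residual <= tol:
        return D
    raise ConvergenceError(
        f"McWeeny purification did not converge in {max_iter} iterations: "
        f"final residual {residual:.3e}"
    )


@dataclass
class GExtConfig:
    """Tunable parameters of the G-Ext guess driver.

    ``epsilon_factor`` implements the recommended coupling of the Tikhonov
    parameter to the SCF tolerance, ``eps = 1e3 * r_scf``; an explicit
    ``epsilon`` overrides it.
    """

    n_t: int = 6
    epsilon: float | None = None
    epsilon_factor: float = 1e3
    min_snapshots: int = DEFAULT_MIN_SNAPSHOTS
    guard_threshold: float = 1e-8

    def effective_epsilon(self, r_scf: float) -> float:
        if self.epsilon is not None:
            return self.epsilon
        return self.epsilon_factor * r_scf


class GrassmannExtrapolator:
    """Stateful per-trajectory driver around :class:`SnapshotHistory`.

    Feed it each step's converged occupied AO coefficients via
    :meth:`update`; ask for a guess for the next geometry via :meth:`guess`.
    The reference frame is fixed at the first update; if a later logarithm
    leaves the injectivity domain the reference is reset to the offending
    frame and the history flushed (a pathology that smooth MD should never
    trigger, but the driver must survive it).
    """

    def __init__(self, config: GExtConfig | None = None):
        self.config = config or GExtConfig()
        self.history: SnapshotHistory | None = None
        self.last_solution: CoefficientSolution | None = None

    def update(
        self, g: Geometry, S: np.ndarray, C_occ_ao: np.ndarray, step: int | None = None
    ) -> None:
        """Store the converged occupied orbitals of one MD step."""
        frame = lowdin_orthonormalize(C_occ_ao, S)
        d = coulomb_matrix(g)
        if self.history is None:
            self.history = SnapshotHistory(self.config.n_t, frame)
        try:
            self.history.push(frame, d)
        except InjectivityDomainError:
            logger.warning(
                "reference point invalid at step %s: resetting reference and "
                "flushing history",
                step,
            )
            self.history = SnapshotHistory(self.config.n_t, frame)
            self.history.push(frame, d)

    def guess(self, g: Geometry, S: np.ndarray, r_scf: float) -> GuessDensity | None:
        """G-Ext guess for geometry ``g`` (``None`` until enough history)."""
        if self.history is None:
            return None
        guess = extrapolate_guess(
            self.history,
            coulomb_matrix(g),
            S,
            epsilon=self.config.effective_epsilon(r_scf),
            min_snapshots=self.config.min_snapshots,
            guard_threshold=self.config.guard_threshold,
        )
        if guess is not None:
            self.last_solution = guess.coefficients
        return guess
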