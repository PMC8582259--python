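"""Coulomb-matrix molecular descriptor.

The descriptor maps nuclear coordinates to a vector that is invariant under
rigid translations and rotations: the Coulomb matrix

    M_ij = Z_i Z_j / |R_i - R_j|   (i != j),      M_ii = 0.5 * Z_i^2.4,

flattened to its upper triangle (diagonal included, row-major) in the fixed
input atom order.  Atom order is deliberately *not* canonicalized: along one
MD trajectory atom identity is stable, so permutation invariance is not
needed, and keeping the raw order makes the descriptor a smooth function of
the coordinates.
"""

from __future__ import annotations

import numpy as np

from .geometry import Geometry

#: minimum allowed interatomic distance (bohr) before atoms count as coincident
MIN_DISTANCE = 1e-10


def coulomb_matrix_full(g: Geometry) -> np.ndarray:
    """The full symmetric M x M Coulomb matrix of a geometry (atomic units)."""
    Z = np.asarray(g.Z, dtype=float)
    r = g.distance_matrix()
    off = r + np.eye(g.n_atoms)  # placeholder diagonal, overwritten below
    if np.min(off) < MIN_DISTANCE:
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise ValueError(
            f"coincident atoms {i} and {j}: distance {r[i, j]:.3e} bohr"
        )
    M = np.outer(Z, Z) / off
    np.fill_diagonal(M, 0.5 * Z**2.4)
    return M


def coulomb_matrix(g: Geometry) -> np.ndarray:
    """Coulomb-matrix descriptor vector of length ``M (M + 1) / 2``.

    Upper triangle of :func:`coulomb_matrix_full`, diagonal included,
    row-major, fixed input atom order.
    """
    M = coulomb_matrix_full(g)
    iu = np.triu_indices(g.n_atoms)
    return M[iu]


def descriptor_length(n_atoms: int) -> int:
    return n_atoms * (n_atoms + 1) // 2


def descriptor_matrix(history_descriptors) -> np.ndarray:
    """Stack descriptors into the N_t x N_d matrix P (row i = i-th descriptor)."""
    ds = [np.asarray(d, dtype=float) for d in history_descriptors]
    if not ds:
        raise ValueError("need at least one descriptor")
    n_d = ds[0].shape
    if any(d.ndim != 1 for d in ds) or any(d.shape != n_d for d in ds):
        raise ValueError("descriptors have inhomogeneous lengths")
    return np.vstack(ds)
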