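"""Plain-text I/O: XYZ trajectories and whitespace/CSV matrix files.

XYZ files follow the usual convention (atom count, comment line, one
``symbol x y z`` record per atom, coordinates in angstrom); multi-frame files
are simply concatenated frames.  Matrices are stored full (no packed storage),
row-major, either whitespace- or comma-delimited.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np

from .geometry import BOHR_PER_ANGSTROM, SYMBOL_TO_Z, Z_TO_SYMBOL, Geometry


def read_xyz(path: str | os.PathLike) -> list[Geometry]:
    """Read a (possibly multi-frame) XYZ file; coordinates converted to bohr."""
    frames: list[Geometry] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from exc
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        Z, R = [], []
        for ln in body:
            parts = ln.split()
            sym = parts[0]
            Z.append(int(sym) if sym.isdigit() else SYMBOL_TO_Z[sym.capitalize()])
            R.append([float(x) for x in parts[1:4]])
        frames.append(Geometry.from_angstrom(Z, np.array(R)))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_xyz(
    path: str | os.PathLike,
    frames: Iterable[Geometry] | Geometry,
    comments: Sequence[str] | None = None,
) -> None:
    """Write one or more geometries to an XYZ file (angstrom)."""
    if isinstance(frames, Geometry):
        frames = [frames]
    frames = list(frames)
    with open(path, "w") as fh:
        for k, g in enumerate(frames):
            comment = comments[k] if comments is not None else f"frame {k}"
            fh.write(f"{g.n_atoms}\n{comment}\n")
            R = g.R / BOHR_PER_ANGSTROM
            for z, row in zip(g.Z, R):
                sym = Z_TO_SYMBOL.get(z, str(z))
                fh.write(f"{sym} {row[0]:.12f} {row[1]:.12f} {row[2]:.12f}\n")


def load_matrix(path: str | os.PathLike) -> np.ndarray:
    """Load a full matrix from whitespace- or comma-delimited text."""
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return mat


def save_matrix(path: str | os.PathLike, mat: np.ndarray, csv: bool = False) -> None:
    np.savetxt(path, np.atleast_2d(mat), delimiter="," if csv else " ", fmt="%.17g")


def load_overlap(path: str | os.PathLike, sym_tol: float = 1e-8) -> np.ndarray:
    """Load an overlap matrix, validating symmetry."""
    S = load_matrix(path)
    if S.shape[0] != S.shape[1]:
        raise ValueError(f"{path}: overlap matrix must be square, got {S.shape}")
    if np.max(np.abs(S - S.T)) > sym_tol:
        raise ValueError(f"{path}: overlap matrix is not symmetric to {sym_tol}")
    return 0.5 * (S + S.T)
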