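"""Molecular geometries (atomic numbers + Cartesian coordinates, atomic units)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: bohr per angstrom
BOHR_PER_ANGSTROM = 1.8897261254578281

#: element symbol -> atomic number, for the elements the synthetic clusters use
SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: standard atomic masses (amu)
ATOMIC_MASS = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    15: 30.974, 16: 32.06, 17: 35.45,
}


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: atomic numbers ``Z`` and coordinates ``R`` in bohr.

    The coordinate array is copied and made read-only so geometries can be
    shared freely between the descriptor, the engine and trajectory records.
    """

    Z: tuple[int, ...]
    R: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        R = np.array(self.R, dtype=float)
        if R.ndim != 2 or R.shape[1] != 3:
            raise ValueError(f"R must be (M, 3), got {R.shape}")
        if len(self.Z) != R.shape[0]:
            raise ValueError("len(Z) must match number of coordinate rows")
        if any(z <= 0 for z in self.Z):
            raise ValueError("atomic numbers must be positive")
        R.setflags(write=False)
        object.__setattr__(self, "Z", tuple(int(z) for z in self.Z))
        object.__setattr__(self, "R", R)

    @property
    def n_atoms(self) -> int:
        return len(self.Z)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise interatomic distances in bohr (M x M, zero diagonal)."""
        diff = self.R[:, None, :] - self.R[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))

    def masses(self) -> np.ndarray:
        """Standard atomic masses (amu) for each atom."""
        return np.array([ATOMIC_MASS[z] for z in self.Z])

    def with_coordinates(self, R: np.ndarray) -> "Geometry":
        return Geometry(self.Z, R)

    def translated(self, shift) -> "Geometry":
        return Geometry(self.Z, self.R + np.asarray(shift, dtype=float))

    def rotated(self, rotation: np.ndarray) -> "Geometry":
        """Rigidly rotate all coordinates by a 3x3 rotation matrix."""
        return Geometry(self.Z, self.R @ np.asarray(rotation, dtype=float).T)

    @classmethod
    def from_angstrom(cls, Z, R_angstrom) -> "Geometry":
        return cls(tuple(Z), np.asarray(R_angstrom, dtype=float) * BOHR_PER_ANGSTROM)
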