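"""Self-contained geometry-dependent SCF model plus NVE molecular dynamics.

The electronic model is a second-order self-consistent tight-binding
Hamiltonian in a minimal basis (one function per atom):

* overlap          ``S_ij  = exp(-gamma r_ij^2)`` (Gaussian kernel, SPD),
* core Hamiltonian ``H0_ii = onsite(Z_i)``, ``H0_ij = -t exp(-mu r_ij)``,
* charge self-consistency: with Mulliken populations ``p_i = [D S]_ii`` and
  fluctuations ``dn_i = p_i - Z_i^val``, the Fock matrix is
  ``F_ij = H0_ij + 1/2 U (dn_i + dn_j) S_ij`` (on-site Hubbard-like
  restoring term, the standard second-order tight-binding form),
* pairwise nuclear repulsion ``a exp(-b r_ij)``,
* total energy ``E = 1/2 Tr[D (H0 + F)] + E_rep``.

The density carries the closed-shell occupation: ``D = 2 C_occ C_occ^T``,
``Tr(D S) = n_electrons``.  The SCF loop is a plainly damped fixed-point
iteration so that the iteration count is a clean, monotone probe of
initial-guess quality; an Anderson accelerator exists behind a toggle but is
off by default.

Nuclear forces are central finite differences of the converged total energy
(exact for the implemented energy surface up to the SCF tolerance and the
O(h^2) stencil error), and dynamics is plain velocity Verlet in the NVE
ensemble.  All quantities are in hartree / bohr / fs / amu.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError
from .extrapolator import (
    GExtConfig,
    GrassmannExtrapolator,
    GuessDensity,
    idempotency_defect,
)
from .geometry import Geometry
from .io import write_xyz
from .manifold import overlap_roots

# ---------------------------------------------------------------------------
# unit conversions (all in one place)
# ---------------------------------------------------------------------------
HARTREE_J = 4.3597447222071e-18
BOHR_M = 5.29177210903e-11
AMU_KG = 1.66053906660e-27
FS_S = 1e-15
#: (bohr/fs^2) per (hartree/bohr/amu): acceleration conversion factor
ACC_CONV = HARTREE_J / (BOHR_M * AMU_KG) * FS_S**2 / BOHR_M
#: Boltzmann constant in hartree/K
KB_HARTREE = 3.166811563e-6
HARTREE_TO_KCALMOL = 627.5094740631


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the tight-binding model (hartree / bohr units).

    With one basis function per atom the model supports covalent bonding
    only, so the packaged clusters use univalent elements (H, Li, F, Na, Cl:
    one valence electron each) of distinct onsite energies -- every atom then
    takes part in a bond, clusters hold together, and the mixed onsites keep
    the frontier levels non-degenerate (a finite HOMO-LUMO gap keeps the
    charge response, and with it the fixed-point iteration, stable).  The
    hopping amplitude deliberately exceeds ``|onsite|`` so that the overlap
    pencil keeps its normal level ordering at short distances.  Defaults give
    bound, vibrating clusters with bond lengths around 2.5 bohr and a
    genuinely nonlinear SCF whose iteration count responds to guess quality.
    """

    onsite: dict = field(
        default_factory=lambda: {1: -0.50, 3: -0.40, 9: -0.65, 11: -0.38, 17: -0.55}
    )
    t: float = 1.30  # hopping amplitude, hartree
    mu: float = 0.80  # hopping decay, 1/bohr
    gamma: float = 0.50  # overlap decay, 1/bohr^2
    U: float = 0.20  # charge stiffness, hartree
    a: float = 6.00  # repulsion amplitude, hartree
    b: float = 1.80  # repulsion range, 1/bohr
    electrons_per_atom: dict = field(
        default_factory=lambda: {1: 1, 3: 1, 9: 1, 11: 1, 17: 1}
    )

    def __post_init__(self):
        for name in ("t", "mu", "gamma", "U", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    def valence(self, Z) -> np.ndarray:
        return np.array([self.electrons_per_atom[z] for z in Z], dtype=float)

    def n_electrons(self, Z) -> int:
        n = int(sum(self.electrons_per_atom[z] for z in Z))
        if n % 2:
            raise ValueError(f"total electron count {n} is odd (closed shell only)")
        return n


@dataclass(frozen=True)
class SCFResult:
    """Converged (or flagged) output of one SCF solve."""

    D_ao: np.ndarray
    C_occ: np.ndarray
    energy: float
    iterations: int
    orbital_energies: np.ndarray
    converged: bool
    charges: np.ndarray  # Mulliken net charges Z_val - p


# ---------------------------------------------------------------------------
# model matrices (batched over a leading geometry axis where useful)
# ---------------------------------------------------------------------------

def _distances(R: np.ndarray) -> np.ndarray:
    diff = R[..., :, None, :] - R[..., None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def build_overlap(g: Geometry, p: ModelParameters) -> np.ndarray:
    """Gaussian-decay overlap matrix (one basis function per atom, SPD)."""
    r = g.distance_matrix()
    return np.exp(-p.gamma * r * r)


def build_core(g: Geometry, p: ModelParameters) -> np.ndarray:
    """Core Hamiltonian: onsite energies and exponentially decaying hopping."""
    r = g.distance_matrix()
    H0 = -p.t * np.exp(-p.mu * r)
    np.fill_diagonal(H0, [p.onsite[z] for z in g.Z])
    return H0


def _repulsion(r: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Pairwise nuclear repulsion, batched: sum_{i<j} a exp(-b r_ij)."""
    e = p.a * np.exp(-p.b * r)
    iu = np.triu_indices(r.shape[-1], k=1)
    return np.sum(e[..., iu[0], iu[1]], axis=-1)


def _batch_matrices(Z, RB: np.ndarray, p: ModelParameters):
    """Overlap, core Hamiltonian and repulsion for a batch of geometries."""
    r = _distances(RB)
    S = np.exp(-p.gamma * r * r)
    H0 = -p.t * np.exp(-p.mu * r)
    idx = np.arange(len(Z))
    H0[..., idx, idx] = np.array([p.onsite[z] for z in Z])
    return S, H0, _repulsion(r, p)


def _roots_batch(S: np.ndarray):
    w, V = np.linalg.eigh(S)
    if np.min(w) <= 0:
        raise ValueError(
            f"overlap matrix indefinite (min eigenvalue {np.min(w):.3e}); "
            "check model parameters"
        )
    sq = np.sqrt(w)
    S_half = np.einsum("...ik,...k,...jk->...ij", V, sq, V)
    S_inv_half = np.einsum("...ik,...k,...jk->...ij", V, 1.0 / sq, V)
    return S_half, S_inv_half


def _density_from_fock(F, S_inv_half, n_occ, return_full: bool = False):
    """Aufbau density from a (batch of) Fock matrices.

    Diagonalizes in the orthonormal representation and doubly occupies the
    ``n_occ`` lowest levels (ties broken deterministically by the ascending
    eigenvalue order of LAPACK, i.e. lowest index first).
    """
    Ft = S_inv_half @ F @ S_inv_half
    w, V = np.linalg.eigh(Ft)
    C = S_inv_half @ V[..., :, :n_occ]
    D = 2.0 * (C @ np.swapaxes(C, -1, -2))
    if return_full:
        return D, C, w
    return D


def _fock(D, S, H0, zval, U):
    pop = np.einsum("...ij,...ji->...i", D, S)
    dn = pop - zval
    shift = 0.5 * U * (dn[..., :, None] + dn[..., None, :]) * S
    return H0 + shift, zval - pop


def _rms(A: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(A * A, axis=(-2, -1)))


def total_energy(D, H0, F, g: Geometry, p: ModelParameters) -> float:
    """Total energy ``1/2 Tr[D (H0 + F)] + sum_{i<j} a exp(-b r_ij)``."""
    r = g.distance_matrix()
    return float(0.5 * np.einsum("ij,ji->", D, H0 + F) + _repulsion(r, p))


def scf_solve(
    g: Geometry,
    p: ModelParameters,
    D_guess: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 0.4,
    accelerate: bool = False,
) -> SCFResult:
    """Solve the self-consistent tight-binding problem for one geometry.

    The loop is: build Fock from the current density, diagonalize, occupy by
    aufbau, measure the RMS element-wise change of the density, and stop when
    it drops to ``tol``; otherwise mix ``D <- D + damping * (D_new - D)``.
    ``iterations`` counts Fock builds, so restarting from a converged density
    costs exactly one iteration.  ``D_guess=None`` uses the core-Hamiltonian
    guess.  ``accelerate=True`` switches on Anderson mixing (off by default
    so that the iteration count remains a clean probe of guess quality).
    """
    Z = g.Z
    S, H0, e_rep = _batch_matrices(Z, g.R[None], p)
    S, H0, e_rep = S[0], H0[0], float(e_rep[0])
    _, S_inv_half = _roots_batch(S)
    zval = p.valence(Z)
    n_elec = p.n_electrons(Z)
    n_occ = n_elec // 2

    if D_guess is None:
        D = _density_from_fock(H0, S_inv_half, n_occ)
    else:
        D = np.array(D_guess, dtype=float)
        if D.shape != S.shape:
            raise ValueError(f"guess density shape {D.shape} != {S.shape}")
        tr = float(np.einsum("ij,ji->", D, S))
        if abs(tr - n_elec) > 0.5:
            raise ValueError(
                f"guess density has Tr(D S) = {tr:.3f}, expected {n_elec}"
            )

    hist_D: list[np.ndarray] = []
    hist_R: list[np.ndarray] = []
    converged = False
    iterations = max_iter
    for k in range(1, max_iter + 1):
        F, charges = _fock(D, S, H0, zval, p.U)
        D_new, C, w = _density_from_fock(F, S_inv_half, n_occ, return_full=True)
        if n_occ < len(Z) and w[n_occ] - w[n_occ - 1] < 1e-12:
            warnings.warn(
                "degenerate HOMO-LUMO gap at the occupation boundary; "
                "occupying lowest-index level"
            )
        if _rms(D_new - D) <= tol:
            D = D_new
            converged = True
            iterations = k
            break
        if accelerate:
            hist_D.append(D.ravel())
            hist_R.append((D_new - D).ravel())
            if len(hist_D) > 6:
                hist_D.pop(0)
                hist_R.pop(0)
            D = _anderson_mix(hist_D, hist_R, damping).reshape(D.shape)
        else:
            D = D + damping * (D_new - D)

    F, charges = _fock(D, S, H0, zval, p.U)
    energy = total_energy(D, H0, F, g, p)
    if not converged:
        warnings.warn(
            f"SCF did not converge in {max_iter} iterations (tol {tol:g})"
        )
    return SCFResult(
        D_ao=D,
        C_occ=C,
        energy=energy,
        iterations=iterations,
        orbital_energies=w,
        converged=converged,
        charges=charges,
    )


def _anderson_mix(hist_D: list, hist_R: list, beta: float) -> np.ndarray:
    """Anderson (type-II) mixing over the stored density/residual history.

    Finds weights theta (summing to 1) minimizing the combined residual
    ``||sum_k theta_k r_k||`` and returns ``sum_k theta_k (D_k + beta r_k)``.
    """
    m = len(hist_D)
    if m == 1:
        return hist_D[0] + beta * hist_R[0]
    Rmat = np.array(hist_R).T  # (n, m)
    A = Rmat[:, :-1] - Rmat[:, -1:]  # columns r_k - r_m
    alpha, *_ = np.linalg.lstsq(A, -Rmat[:, -1], rcond=None)
    theta = np.append(alpha, 1.0 - np.sum(alpha))
    Dmat = np.array(hist_D).T
    return (Dmat + beta * Rmat) @ theta


def _scf_batch(
    Z,
    RB: np.ndarray,
    p: ModelParameters,
    D0: np.ndarray,
    tol: float,
    max_iter: int = 400,
    damping: float = 0.4,
):
    """Damped fixed-point SCF for a batch of geometries, iterated in lockstep.

    Used by the finite-difference force evaluator where all displaced
    geometries (and hence their solves) are nearly identical; the stacked
    ``eigh`` amortizes the per-call cost.  Returns converged densities,
    energies and per-entry iteration counts.
    """
    S, H0, e_rep = _batch_matrices(Z, RB, p)
    _, S_inv_half = _roots_batch(S)
    zval = p.valence(Z)
    n_occ = p.n_electrons(Z) // 2
    B = RB.shape[0]
    D = np.array(D0, dtype=float)
    done = np.zeros(B, dtype=bool)
    its = np.full(B, max_iter, dtype=int)
    for k in range(1, max_iter + 1):
        act = ~done
        F, _ = _fock(D[act], S[act], H0[act], zval, p.U)
        D_new = _density_from_fock(F, S_inv_half[act], n_occ)
        res = _rms(D_new - D[act])
        conv = res <= tol
        idx = np.flatnonzero(act)
        D[idx[conv]] = D_new[conv]
        its[idx[conv]] = k
        D[idx[~conv]] = D[idx[~conv]] + damping * (D_new[~conv] - D[idx[~conv]])
        done[idx[conv]] = True
        if done.all():
            break
    if not done.all():
        raise ConvergenceError(
            f"batched SCF: {np.sum(~done)} of {B} entries unconverged "
            f"after {max_iter} iterations"
        )
    F, _ = _fock(D, S, H0, zval, p.U)
    E = 0.5 * np.einsum("bij,bji->b", D, H0 + F) + e_rep
    return D, E, its


def forces(
    g: Geometry,
    p: ModelParameters,
    tol: float = 1e-9,
    step: float = 1e-4,
    D_warm: np.ndarray | None = None,
) -> np.ndarray:
    """Nuclear forces ``F = -dE/dR`` by central finite differences (M x 3).

    Every displaced geometry is solved self-consistently to ``tol``
    (warm-started from a converged central density), so the force error is
    O(step^2) + O(tol / step).
    """
    F, _, _ = force_and_energy(g, p, tol=tol, step=step, D_warm=D_warm)
    return F


def force_and_energy(
    g: Geometry,
    p: ModelParameters,
    tol: float = 1e-9,
    step: float = 1e-4,
    D_warm: np.ndarray | None = None,
):
    """Forces plus converged central energy/density (one call per MD step)."""
    M = g.n_atoms
    center = scf_solve(g, p, D_guess=D_warm, tol=tol, max_iter=400)
    if not center.converged:
        raise ConvergenceError("central SCF did not converge in force evaluation")
    disp = np.tile(g.R[None], (2 * 3 * M, 1, 1))
    k = 0
    for i in range(M):
        for ax in range(3):
            disp[k, i, ax] += step
            disp[k + 1, i, ax] -= step
            k += 2
    D0 = np.tile(center.D_ao[None], (2 * 3 * M, 1, 1))
    _, E, _ = _scf_batch(g.Z, disp, p, D0, tol=tol)
    dE = (E[0::2] - E[1::2]) / (2.0 * step)
    return -dE.reshape(M, 3), center.energy, center


# ---------------------------------------------------------------------------
# molecular dynamics (NVE, velocity Verlet)
# ---------------------------------------------------------------------------


@dataclass
class MDState:
    """Instantaneous state of the nuclei."""

    geometry: Geometry
    velocities: np.ndarray  # (M, 3), bohr/fs
    masses: np.ndarray  # (M,), amu
    forces: np.ndarray  # (M, 3), hartree/bohr
    potential_energy: float  # hartree
    time: float = 0.0  # fs

    def kinetic_energy(self) -> float:
        """Nuclear kinetic energy in hartree."""
        v2 = np.sum(self.velocities**2, axis=1)
        return float(0.5 * np.sum(self.masses * v2) / ACC_CONV)

    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy()


def velocity_verlet_step(state: MDState, dt: float, force_fn) -> MDState:
    """One velocity Verlet step; ``force_fn(geometry) -> (forces, E_pot)``."""
    a_old = state.forces / state.masses[:, None] * ACC_CONV
    v_half = state.velocities + 0.5 * dt * a_old
    R_new = state.geometry.R + dt * v_half
    g_new = state.geometry.with_coordinates(R_new)
    F_new, E_new = force_fn(g_new)
    a_new = F_new / state.masses[:, None] * ACC_CONV
    v_new = v_half + 0.5 * dt * a_new
    return MDState(
        geometry=g_new,
        velocities=v_new,
        masses=state.masses,
        forces=F_new,
        potential_energy=E_new,
        time=state.time + dt,
    )


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded Maxwell-Boltzmann velocities (bohr/fs) with zero net momentum."""
    sigma = np.sqrt(KB_HARTREE * max(temperature, 0.0) * ACC_CONV / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= np.sum(v * masses[:, None], axis=0) / np.sum(masses)
    return v


# ---------------------------------------------------------------------------
# packaged cluster templates
# ---------------------------------------------------------------------------

def cluster_template(name: str) -> Geometry:
    """Packaged starting structures (coordinates in bohr, near equilibrium).

    ``tetra``: a bent F-H-Cl-H cluster (4 atoms, 4 electrons);
    ``chain6``: a 6-atom zigzag F-H-Cl-H-Li-H chain, the default benchmark
    system.  All elements are univalent in this model, so the clusters are
    covalently bound and the electron count is automatically even; mixed
    elements keep the orbital spectrum non-degenerate.  Coordinates are the
    relaxed minima of the default parameters (no point-group symmetry).
    """
    if name == "tetra":
        return Geometry(
            (9, 1, 17, 1),
            np.array(
                [
                    [0.000, 0.000, 0.000],
                    [1.900, 1.785, 0.239],
                    [3.253, 4.611, 0.810],
                    [4.896, 2.803, 0.151],
                ]
            ),
        )
    if name == "chain6":
        return Geometry(
            (9, 1, 17, 1, 3, 1),
            np.array(
                [
                    [0.000, 0.000, 0.000],
                    [1.672, 1.812, 1.068],
                    [2.848, 3.988, 2.491],
                    [5.015, 2.821, 1.320],
                    [7.376, 3.097, -0.557],
                    [7.583, 1.242, 1.149],
                ]
            ),
        )
    raise KeyError(f"unknown cluster template {name!r}")


# ---------------------------------------------------------------------------
# trajectory generation and guess-strategy probing
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """An NVE trajectory with per-step converged reference data."""

    Z: tuple
    dt: float
    seed: int
    params: ModelParameters
    geometries: list
    potential: np.ndarray
    kinetic: np.ndarray
    scf_iterations: np.ndarray  # iterations of the tight reference solves
    densities: list | None = None  # tight converged AO densities, if stored

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.geometries))

    @property
    def total(self) -> np.ndarray:
        return self.potential + self.kinetic

    @property
    def n_steps(self) -> int:
        return len(self.geometries) - 1

    def to_xyz(self, path) -> None:
        write_xyz(
            path,
            self.geometries,
            comments=[f"t = {t:.4f} fs" for t in self.times],
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_fs", "potential_ha", "kinetic_ha", "total_ha", "scf_iterations"])
            for i, t in enumerate(self.times):
                w.writerow(
                    [f"{t:.6f}", f"{self.potential[i]:.12f}", f"{self.kinetic[i]:.12f}",
                     f"{self.total[i]:.12f}", int(self.scf_iterations[i])]
                )


def generate_trajectory(
    template: str | Geometry = "chain6",
    n_steps: int = 200,
    dt: float = 0.5,
    seed: int = 0,
    temperature: float = 300.0,
    params: ModelParameters | None = None,
    force_tol: float = 1e-9,
    fd_step: float = 1e-4,
    store_densities: bool = True,
) -> Trajectory:
    """Run an NVE trajectory of the synthetic model (deterministic per seed).

    The propagation always uses tightly converged SCF solves (``force_tol``)
    inside the finite-difference force evaluation, so the trajectory itself
    is independent of any guess strategy under study; guess strategies are
    measured along the trajectory with :func:`probe_guess_strategy`.
    """
    p = params or ModelParameters()
    g0 = cluster_template(template) if isinstance(template, str) else template
    rng = np.random.default_rng(seed)
    masses = g0.masses()
    v0 = maxwell_boltzmann_velocities(masses, temperature, rng)

    F0, E0, center = force_and_energy(g0, p, tol=force_tol, step=fd_step)
    state = MDState(g0, v0, masses, F0, E0, time=0.0)

    geoms = [g0]
    pot = [E0]
    kin = [state.kinetic_energy()]
    its = [center.iterations]
    dens = [center.D_ao] if store_densities else None

    warm = {"D": center.D_ao}

    def force_fn(g: Geometry):
        F, E, c = force_and_energy(g, p, tol=force_tol, step=fd_step, D_warm=warm["D"])
        warm["D"] = c.D_ao
        force_fn.last = c
        return F, E

    for _ in range(n_steps):
        state = velocity_verlet_step(state, dt, force_fn)
        geoms.append(state.geometry)
        pot.append(state.potential_energy)
        kin.append(state.kinetic_energy())
        its.append(force_fn.last.iterations)
        if store_densities:
            dens.append(force_fn.last.D_ao)

    return Trajectory(
        Z=g0.Z,
        dt=dt,
        seed=seed,
        params=p,
        geometries=geoms,
        potential=np.array(pot),
        kinetic=np.array(kin),
        scf_iterations=np.array(its),
        densities=dens,
    )


# ---------------------------------------------------------------------------
# guess strategies
# ---------------------------------------------------------------------------


class CoreGuess:
    """Baseline: no information reuse; every SCF starts from the core guess."""

    name = "core"

    def guess(self, g: Geometry, S: np.ndarray):
        return None

    def update(self, g: Geometry, S: np.ndarray, result: SCFResult) -> None:
        pass


class PreviousDensityGuess:
    """Reuse the previous MD step's converged density unchanged."""

    name = "previous"

    def __init__(self):
        self._last: np.ndarray | None = None

    def guess(self, g: Geometry, S: np.ndarray):
        return self._last

    def update(self, g: Geometry, S: np.ndarray, result: SCFResult) -> None:
        self._last = result.D_ao


class GExtGuess:
    """Grassmann extrapolation of the previous ``n_t`` converged densities.

    Falls back to the previous converged density during warm-up (fewer than
    ``min_snapshots`` stored steps).  Records the idempotency defect and
    trace error of each produced orthonormal-representation guess so that
    the structural guarantee can be audited along a whole trajectory.
    """

    def __init__(self, n_t: int = 6, r_scf: float = 1e-7, config: GExtConfig | None = None):
        cfg = config or GExtConfig(n_t=n_t)
        cfg.n_t = n_t
        self.name = f"gext{n_t}"
        self.r_scf = r_scf
        self.extrapolator = GrassmannExtrapolator(cfg)
        self._fallback = PreviousDensityGuess()
        self.idempotency_defects: list[float] = []
        self.trace_errors: list[float] = []
        self.last_guess: GuessDensity | None = None

    def guess(self, g: Geometry, S: np.ndarray):
        gd = self.extrapolator.guess(g, S, self.r_scf)
        self.last_guess = gd
        if gd is None:
            return self._fallback.guess(g, S)
        n_occ = gd.frame.n_occ
        self.idempotency_defects.append(idempotency_defect(gd.D_ortho))
        self.trace_errors.append(abs(float(np.trace(gd.D_ortho)) - n_occ))
        # engine densities carry the closed-shell factor of 2
        return 2.0 * gd.D_ao

    def update(self, g: Geometry, S: np.ndarray, result: SCFResult) -> None:
        self.extrapolator.update(g, S, result.C_occ)
        self._fallback.update(g, S, result)


@dataclass
class ProbeResult:
    """Per-step guess-quality measurements along a fixed trajectory."""

    strategy: str
    r_scf: float
    iterations: np.ndarray
    guess_errors: np.ndarray  # ||D_guess - D_converged||_F (nan for core guess)
    energies: np.ndarray  # converged energies at r_scf, hartree
    total_energies: np.ndarray  # energies + trajectory kinetic term
    idempotency_defects: np.ndarray | None = None
    trace_errors: np.ndarray | None = None


def probe_guess_strategy(
    traj: Trajectory,
    strategy,
    r_scf: float,
    max_iter: int = 400,
) -> ProbeResult:
    """Measure SCF iteration counts for a guess strategy along a trajectory.

    At every frame the strategy proposes a guess, the SCF is converged to
    ``r_scf`` from it, and the converged result is handed back to the
    strategy (so history-based strategies see densities of exactly the
    accuracy the benchmark tolerance produces, as they would in a live run).
    """
    p = traj.params
    its, errs, ens, tots = [], [], [], []
    for i, g in enumerate(traj.geometries):
        S = build_overlap(g, p)
        D0 = strategy.guess(g, S)
        res = scf_solve(g, p, D_guess=D0, tol=r_scf, max_iter=max_iter)
        strategy.update(g, S, res)
        its.append(res.iterations)
        errs.append(
            float(np.linalg.norm(D0 - res.D_ao)) if D0 is not None else np.nan
        )
        ens.append(res.energy)
        tots.append(res.energy + traj.kinetic[i])
    return ProbeResult(
        strategy=strategy.name,
        r_scf=r_scf,
        iterations=np.array(its),
        guess_errors=np.array(errs),
        energies=np.array(ens),
        total_energies=np.array(tots),
        idempotency_defects=(
            np.array(strategy.idempotency_defects)
            if isinstance(strategy, GExtGuess)
            else None
        ),
        trace_errors=(
            np.array(strategy.trace_errors)
            if isinstance(strategy, GExtGuess)
            else None
        ),
    )


def make_strategy(name: str, r_scf: float, epsilon: float | None = None):
    """Build a guess strategy from its benchmark label.

    ``"core"``, ``"previous"`` or ``"gext<N>"`` (e.g. ``gext6``).
    """
    if name == "core":
        return CoreGuess()
    if name == "previous":
        return PreviousDensityGuess()
    if name.startswith("gext"):
        n_t = int(name[4:])
        cfg = GExtConfig(n_t=n_t, epsilon=epsilon)
        return GExtGuess(n_t=n_t, r_scf=r_scf, config=cfg)
    raise KeyError(f"unknown guess strategy {name!r}")
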