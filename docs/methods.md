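# Methods

## The extrapolation problem

In Born–Oppenheimer molecular dynamics the expensive step is the
self-consistent-field (SCF) solution at each new geometry. Converged
densities from previous steps are an obvious source for a starting guess,
but an idempotent density matrix (D² = D, tr D = N) lives on a curved
manifold: linear combinations of idempotent matrices are not idempotent, so
naive extrapolation produces an unphysical guess.

`gext` sidesteps the constraint geometrically. After Löwdin
orthonormalization (C̃ = S^{1/2} C) the occupied orbital frame is a point on
the Stiefel manifold and its projector D = C̃C̃ᵀ a point on the Grassmann
manifold Gr(N, N_b) of N-dimensional subspaces of ℝ^{N_b}. At a fixed
reference frame C₀ the Grassmann logarithm maps nearby subspaces to the
(flat) tangent space, where linear extrapolation is legitimate; the
Grassmann exponential maps the extrapolated tangent vector back, and the
result is *exactly* idempotent with the correct trace by construction, for
any extrapolation coefficients whatsoever.

## The maps

Both maps cost one thin SVD. With M = C₀ᵀC:

* Log: L = (I − C₀C₀ᵀ) C M⁻¹, thin SVD L = UΣVᵀ, Γ = U arctan(Σ) Vᵀ;
* Exp: thin SVD Γ = UΣVᵀ, C = C₀ V cos(Σ) Vᵀ + U sin(Σ) Vᵀ.

Σ holds the tangents of the principal angles between span(C₀) and span(C);
the maps are mutually inverse while every principal angle stays below π/2
(`InjectivityDomainError` otherwise). Both depend on C only through its
column span, so orbital-mixing rotations of the occupied block — the gauge
freedom of any SCF — are invisible to the method. SVD signs are fixed
(largest-magnitude entry of each left singular vector positive) so results
are bit-reproducible across LAPACK builds. After every exponential a guard
checks ‖CᵀC − I‖_F; above 1e-8 (default) the frame is replaced by its polar
factor, the closest orthonormal frame, with a warning. The reference C₀ is
fixed at the first converged frame of a run; should a later logarithm leave
the injectivity domain, the driver resets the reference to the offending
frame and flushes its history (smooth MD has never triggered this in our
runs; the path exists for robustness).

## Coefficients

The geometry enters through the Coulomb-matrix descriptor
d(R): M_ij = Z_iZ_j/r_ij off-diagonal, ½Z_i^2.4 on the diagonal, upper
triangle flattened row-major in fixed atom order (translation- and
rotation-invariant; deliberately *not* permutation-invariant — atom
identity is stable along one trajectory, and a fixed order keeps the
descriptor smooth). Units are bohr throughout; XYZ input in Å is converted
on read.

Given the stored descriptors P (N_t × N_d) and the new geometry's
descriptor d, the coefficients solve the Tikhonov-regularized least-squares
problem

    min_c ‖Pᵀc − d‖² + ε²‖c‖²,

implemented as the padded system [Pᵀ; εI] c ≈ [d; 0] via an SVD solver
(relative cutoff 1e-12), which for ε = 0 returns the minimum-norm solution
of a rank-deficient system. With ε = 0 and independent rows the fit is
interpolatory: querying a stored descriptor returns exactly that snapshot's
density. The default ε couples to the SCF tolerance as ε = 10³·r_scf, which
lets longer histories be used without coefficient blow-up; no constraint is
placed on Σc_i. The guess is then Exp(Σ c_i Γ_i), back-transformed to the AO
basis with the *current* geometry's S^{-1/2} (the only overlap meaningful to
the SCF that will consume the guess). Each MD step costs exactly one Log
(newly converged frame into the ring buffer of capacity N_t) and one Exp —
two SVDs of an N_b × N matrix.

McWeeny purification (D ← 3D² − 2D³, until ‖D² − D‖_F ≤ tol) is provided
for guesses produced by *other* schemes; G-Ext guesses never need it.

## The synthetic engine

The real target of the method is a KS-DFT (or HF) engine; to exercise and
measure the method at desk scale the package ships a self-contained
second-order tight-binding model with a genuinely nonlinear,
geometry-dependent SCF:

* one basis function per atom; overlap S_ij = exp(−γ r²_ij) (a Gaussian
  kernel, hence always positive definite);
* core Hamiltonian H⁰_ii = onsite(Z_i), H⁰_ij = −t·exp(−μ r_ij);
* Mulliken-charge self-consistency: with population fluctuations
  Δn_i = [DS]_ii − Z_i^val, F_ij = H⁰_ij + ½U(Δn_i + Δn_j)S_ij — the
  standard second-order (restoring-sign) charge coupling;
* pairwise repulsion a·exp(−b r); E = ½tr[D(H⁰+F)] + E_rep.

Defaults (hartree/bohr): t = 1.3, μ = 0.8, γ = 0.5, U = 0.2, a = 6.0,
b = 1.8; onsites −0.65 (F), −0.55 (Cl), −0.50 (H), −0.40 (Li), −0.38 (Na).
Two constraints shaped these numbers. First, t exceeds max|onsite| and γ/μ
is large enough that the generalized eigenvalue pencil keeps its normal
level ordering at short distances; otherwise the near-linear-dependence of
strongly overlapping basis functions opens a spurious, divergently
attractive channel. Second, the model supports covalent bonding only (the
charge coupling is on-site, so there is no ionic attraction): an atom with
a filled valence orbital is noble-gas-like and detaches from any cluster.
The packaged clusters therefore use univalent elements exclusively — every
atom takes part in a bond — which also makes the total electron count even
(closed shell) exactly when the atom count is. The shipped templates are a
bent 4-atom F–H–Cl–H cluster (`tetra`) and the default benchmark system, a
6-atom F–H–Cl–H–Li–H chain (`chain6`), both at the relaxed minima of the
default parameters. Mixing elements of different onsite energies keeps the
orbital spectrum non-degenerate; the measured HOMO–LUMO gaps (≈0.17–0.22
hartree) bound the charge response, and the fixed-point Jacobian radius
stays near 1.2, comfortably inside the stability region of plain linear
mixing at the default damping 0.4.

The SCF loop is deliberately a *plain damped fixed-point iteration*
(D ← D + α(D_new − D), convergence on the RMS element-wise density change,
iterations counted as Fock builds): its linear convergence makes the
iteration count an approximately logarithmic, monotone probe of
initial-guess error, which is the quantity the benchmark measures. An
Anderson accelerator exists behind a toggle (`accelerate=True`) but is off
everywhere iterations are compared.

Forces are central finite differences of the converged total energy
(step 1e-4 bohr), evaluated with a stacked batch of displaced SCF solves
warm-started from the central density. Finite differences amplify SCF error
by 1/step, so the propagation always converges the force solves tightly
(`force_tol = 1e-9` by default, 1e-10 in the conservation test) regardless
of the benchmark tolerance; dynamics is plain velocity Verlet in the NVE
ensemble with Maxwell–Boltzmann initial velocities (300 K default, zero net
momentum, seeded). A consequence worth stating plainly: the trajectory is
independent of the guess strategy under study, so `run_benchmark` generates
one trajectory per seed and probes every (strategy, tolerance) pair along
it — this realizes "identical initial conditions" exactly. The probe at
tolerance r_scf hands its *own* converged densities back to the strategy,
so history-based strategies see data of exactly the accuracy a live run at
that tolerance would produce — which is what makes the guess accuracy
tolerance-dependent, as for the real method.

What the engine does *not* emulate: real exchange–correlation, multi-shell
atoms and basis sets, inter-site Coulomb/polarization (hence no ionic or
hydrogen bonding), thermostats, and system sizes where diagonalization
dominates. Passing benchmarks here demonstrate the geometry of the method
(legality of every guess, interpolation, tolerance-coupling of the guess
quality), not quantitative iteration counts for any ab initio code.

## Evaluation protocol

Per-step SCF iteration counts are summarized by mean and *population*
standard deviation after discarding the first 8 steps (so every strategy is
past its history build-up). Energy stability of a trajectory is summarized
by two numbers computed on the total-energy series after discarding the
first 500 fs: the short-time fluctuation (STF) — the series is cut into
consecutive, non-overlapping, complete 50 fs windows, the RMS deviation
from each window's own mean is taken, and the window values averaged — and
the long-time drift (LTD), the ordinary-least-squares slope of energy
vs. time, reported per ps. "Fluctuation" is read as deviation from the
per-window mean, and the drift is fitted on the same post-discard series as
the STF; both are documented choices rather than uniquely forced ones. The
default benchmark is 2000 steps × 0.5 fs = 1 ps, run at r_scf ∈ {1e-5,
1e-7} for the core-Hamiltonian guess, the previous-density guess, and
G-Ext(N_t); problem sizes were chosen so a full multi-seed comparison runs
in minutes on one CPU.

## Numerical choices and degenerate inputs

* Overlap square roots by symmetric eigendecomposition, eigenvalue floor
  1e-10 (`LinearDependenceError` below it, naming the offending eigenvalue).
* Frame invariants enforced at 1e-10; tangent horizontality checked at 1e-6
  on entry to Exp.
* Aufbau ties (degenerate HOMO–LUMO at the occupation boundary) broken
  deterministically toward the lowest index, with a warning.
* Rank-deficient frames (e.g. a zero column) raise rather than being
  silently repaired: no nearby orthonormal frame spans the right subspace.
* Warm-up: until `min_snapshots` (default 3) snapshots exist the driver
  falls back to the previous converged density (core guess at step 0) —
  the cheapest consistent policy, and the first 8 steps are excluded from
  statistics anyway.

## Known limitations

The method is not time-reversible, so NVE energy drift at loose SCF
tolerances is expected for real engines; with this engine's tightly
converged finite-difference forces that effect is visible only through the
probe energies, not the trajectory itself. The fixed reference point is
only locally valid; the automatic reset is a safety net, not a studied
policy. Coulomb-matrix descriptors are not permutation-invariant and are
unsuitable when identical atoms can swap between steps.
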