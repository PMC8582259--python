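"""Synthetic tight-binding SCF model and NVE molecular dynamics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gext.engine import (
    ACC_CONV,
    CoreGuess,
    MDState,
    ModelParameters,
    PreviousDensityGuess,
    build_core,
    build_overlap,
    cluster_template,
    forces,
    generate_trajectory,
    make_strategy,
    probe_guess_strategy,
    scf_solve,
    total_energy,
    velocity_verlet_step,
)
from gext.geometry import Geometry


def atom2e():
    """A single closed-shell (2-electron) atom in a custom parameter set."""
    p = ModelParameters(
        onsite={2: -0.9}, electrons_per_atom={2: 2}
    )
    g = Geometry((2,), np.zeros((1, 3)))
    return g, p


def h2(r):
    return Geometry((1, 1), np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


class TestModelMatrices:
    def test_single_atom_overlap(self):
        g, p = atom2e()
        assert np.allclose(build_overlap(g, p), [[1.0]])

    def test_dimer_overlap_value(self):
        p = ModelParameters(gamma=1.0)
        S = build_overlap(h2(1.0), p)
        assert S[0, 0] == 1.0 and S[1, 1] == 1.0
        assert S[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_far_apart_overlap_is_identity(self):
        p = ModelParameters()
        S = build_overlap(h2(40.0), p)
        assert np.allclose(S, np.eye(2), atol=1e-12)

    def test_single_atom_core(self):
        g, p = atom2e()
        assert np.allclose(build_core(g, p), [[-0.9]])

    def test_dimer_levels_split_by_hopping(self):
        # with a negligible overlap tail the generalized eigenvalues reduce
        # to onsite +- |H0_12|
        p = ModelParameters(gamma=50.0)
        g = h2(1.5)
        H0 = build_core(g, p)
        S = build_overlap(g, p)
        w = np.linalg.eigvalsh(np.linalg.solve(S, H0))
        t12 = abs(H0[0, 1])
        assert np.allclose(w, [-0.5 - t12, -0.5 + t12], atol=1e-10)

    def test_infinite_separation_core_is_diagonal(self):
        p = ModelParameters()
        H0 = build_core(h2(60.0), p)
        assert abs(H0[0, 1]) < 1e-15


class TestSCF:
    def test_single_atom_converges_in_one_iteration(self):
        g, p = atom2e()
        res = scf_solve(g, p, tol=1e-10)
        assert res.converged and res.iterations == 1
        assert np.allclose(res.D_ao, [[2.0]], atol=1e-12)
        assert res.energy == pytest.approx(2 * -0.9, abs=1e-12)

    def test_symmetric_dimer_has_equal_charges(self):
        p = ModelParameters()
        res = scf_solve(h2(2.4), p, tol=1e-10)
        assert res.converged
        assert res.charges[0] == pytest.approx(res.charges[1], abs=1e-8)
        assert res.charges[0] == pytest.approx(0.0, abs=1e-8)

    def test_restart_from_converged_density_is_immediate(self):
        g = cluster_template("tetra")
        p = ModelParameters()
        first = scf_solve(g, p, tol=1e-9)
        again = scf_solve(g, p, D_guess=first.D_ao, tol=1e-9)
        assert again.converged and again.iterations <= 2

    def test_electron_count_and_trace(self):
        g = cluster_template("chain6")
        p = ModelParameters()
        res = scf_solve(g, p, tol=1e-9)
        S = build_overlap(g, p)
        assert np.trace(res.D_ao @ S) == pytest.approx(6.0, abs=1e-8)

    def test_bad_guess_trace_rejected(self):
        g = cluster_template("tetra")
        p = ModelParameters()
        with pytest.raises(ValueError, match="Tr"):
            scf_solve(g, p, D_guess=np.eye(4) * 5.0, tol=1e-8)

    def test_odd_electron_count_rejected(self):
        p = ModelParameters()
        g = Geometry((1, 1, 1), np.array([[0, 0, 0], [2.4, 0, 0], [0, 2.4, 0]]))
        with pytest.raises(ValueError, match="odd"):
            scf_solve(g, p)

    def test_unconverged_result_is_flagged(self):
        g = cluster_template("chain6")
        p = ModelParameters()
        with pytest.warns(UserWarning, match="did not converge"):
            res = scf_solve(g, p, tol=1e-12, max_iter=3)
        assert not res.converged

    def test_anderson_acceleration_reaches_same_fixed_point(self):
        g = cluster_template("chain6")
        p = ModelParameters()
        plain = scf_solve(g, p, tol=1e-10)
        accel = scf_solve(g, p, tol=1e-10, accelerate=True)
        assert accel.converged
        assert accel.iterations <= plain.iterations
        assert np.allclose(accel.D_ao, plain.D_ao, atol=1e-8)


class TestEnergyAndForces:
    def test_single_atom_energy_and_zero_force(self):
        g, p = atom2e()
        F = forces(g, p, tol=1e-10)
        assert np.allclose(F, 0.0, atol=1e-8)

    def test_energy_invariant_under_rigid_motions(self, rng):
        from scipy.spatial.transform import Rotation

        g = cluster_template("tetra")
        p = ModelParameters()
        e0 = scf_solve(g, p, tol=1e-11, max_iter=400).energy
        gt = g.translated([5.0, -2.0, 1.0])
        gr = g.rotated(Rotation.random(random_state=3).as_matrix())
        assert scf_solve(gt, p, tol=1e-11, max_iter=400).energy == pytest.approx(e0, abs=1e-10)
        assert scf_solve(gr, p, tol=1e-11, max_iter=400).energy == pytest.approx(e0, abs=1e-9)

    def test_dimer_curve_has_interior_minimum(self):
        p = ModelParameters()
        rs = np.linspace(1.6, 4.5, 30)
        E = np.array([scf_solve(h2(r), p, tol=1e-10).energy for r in rs])
        i = np.argmin(E)
        assert 0 < i < len(rs) - 1

    def test_force_vanishes_at_dimer_minimum(self):
        p = ModelParameters()
        res = minimize_scalar(
            lambda r: scf_solve(h2(r), p, tol=1e-12, max_iter=500).energy,
            bounds=(1.8, 3.5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        F = forces(h2(res.x), p, tol=1e-12)
        assert np.max(np.abs(F)) < 1e-6

    def test_net_force_is_zero(self):
        g = cluster_template("tetra")
        p = ModelParameters()
        F = forces(g, p, tol=1e-10)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-8)

    def test_total_energy_formula_consistency(self):
        g, p = atom2e()
        res = scf_solve(g, p, tol=1e-10)
        H0 = build_core(g, p)
        assert total_energy(res.D_ao, H0, H0, g, p) == pytest.approx(-1.8, abs=1e-12)


class TestVelocityVerlet:
    def test_zero_force_gives_uniform_motion(self):
        g = Geometry((1,), np.zeros((1, 3)))
        v = np.array([[0.01, 0.0, 0.0]])
        state = MDState(g, v, np.array([1.0]), np.zeros((1, 3)), 0.0)
        ff = lambda geom: (np.zeros((1, 3)), 0.0)
        for _ in range(10):
            state = velocity_verlet_step(state, 0.5, ff)
        assert state.geometry.R[0, 0] == pytest.approx(0.05, abs=1e-14)
        assert np.allclose(state.velocities, v)

    @staticmethod
    def _harmonic(k):
        def ff(geom):
            x = geom.R
            return -k * x, float(0.5 * k * np.sum(x * x))
        return ff

    def test_harmonic_energy_error_scales_as_dt_squared(self):
        k = 0.5  # hartree/bohr^2
        drifts = []
        for dt in (0.2, 0.1):
            g = Geometry((1,), np.array([[1.0, 0.0, 0.0]]))
            state = MDState(g, np.zeros((1, 3)), np.array([1.0]),
                            -k * g.R, 0.5 * k)
            e0 = state.total_energy()
            emax = 0.0
            for _ in range(200):
                state = velocity_verlet_step(state, dt, self._harmonic(k))
                emax = max(emax, abs(state.total_energy() - e0))
            drifts.append(emax)
        assert drifts[1] < drifts[0] / 2.5  # ~ dt^2

    def test_time_reversibility(self):
        k = 0.3
        g = Geometry((1,), np.array([[0.8, 0.2, -0.1]]))
        state = MDState(g, np.array([[0.0, 0.01, 0.0]]), np.array([1.0]),
                        -k * g.R, float(0.5 * k * np.sum(g.R**2)))
        R0, V0 = state.geometry.R.copy(), state.velocities.copy()
        for _ in range(50):
            state = velocity_verlet_step(state, 0.25, self._harmonic(k))
        state = MDState(state.geometry, -state.velocities, state.masses,
                        state.forces, state.potential_energy)
        for _ in range(50):
            state = velocity_verlet_step(state, 0.25, self._harmonic(k))
        assert np.allclose(state.geometry.R, R0, atol=1e-10)
        assert np.allclose(state.velocities, -V0, atol=1e-10)


class TestTrajectory:
    def test_zero_steps_gives_initial_frame_only(self):
        traj = generate_trajectory("tetra", n_steps=0, dt=0.5, seed=3)
        assert len(traj.geometries) == 1 and traj.n_steps == 0

    def test_fixed_seed_is_deterministic(self):
        t1 = generate_trajectory("tetra", n_steps=5, dt=0.5, seed=11)
        t2 = generate_trajectory("tetra", n_steps=5, dt=0.5, seed=11)
        assert np.array_equal(t1.total, t2.total)
        assert np.array_equal(t1.geometries[-1].R, t2.geometries[-1].R)

    def test_zero_dt_freezes_geometry(self):
        traj = generate_trajectory("tetra", n_steps=3, dt=0.0, seed=0)
        for g in traj.geometries[1:]:
            assert np.allclose(g.R, traj.geometries[0].R, atol=1e-14)

    def test_nve_energy_drift_is_tiny_with_tight_scf(self):
        # 100 fs at dt = 0.1 fs, SCF to 1e-10: secular drift below 1e-5 Ha
        traj = generate_trajectory(
            "tetra", n_steps=1000, dt=0.1, seed=5, force_tol=1e-10,
            store_densities=False,
        )
        slope = np.polyfit(traj.times, traj.total, 1)[0]  # Ha/fs
        assert abs(slope * traj.times[-1]) < 1e-5
        assert np.max(np.abs(traj.total - traj.total[0])) < 1e-4

    def test_smaller_dt_improves_previous_density_guess(self):
        errs = {}
        for dt in (0.5, 0.25):
            traj = generate_trajectory("tetra", n_steps=40, dt=dt, seed=7)
            probe = probe_guess_strategy(traj, PreviousDensityGuess(), 1e-8)
            errs[dt] = np.nanmean(probe.guess_errors)
        assert errs[0.25] < errs[0.5]


class TestGuessStrategies:
    def test_iteration_count_monotone_in_guess_quality(self):
        # restarting from the converged density can never take more
        # iterations than the core guess
        traj = generate_trajectory("tetra", n_steps=10, dt=0.5, seed=2)
        p = traj.params
        for g, D in zip(traj.geometries, traj.densities):
            core = scf_solve(g, p, tol=1e-8)
            warm = scf_solve(g, p, D_guess=D, tol=1e-8)
            assert warm.iterations <= core.iterations

    def test_gext_guess_beats_previous_density(self):
        traj = generate_trajectory("chain6", n_steps=60, dt=0.5, seed=4,
                                   store_densities=False)
        r_scf = 1e-7
        res = {}
        for name in ("previous", "gext6"):
            probe = probe_guess_strategy(traj, make_strategy(name, r_scf), r_scf)
            res[name] = probe.iterations[8:].mean()
        assert res["gext6"] < res["previous"]

    def test_core_strategy_always_returns_none(self):
        s = CoreGuess()
        assert s.guess(cluster_template("tetra"), np.eye(4)) is None

    def test_make_strategy_labels(self):
        assert make_strategy("gext4", 1e-7).name == "gext4"
        with pytest.raises(KeyError):
            make_strategy("magic", 1e-7)

    def test_gext_guesses_are_legal_densities(self):
        traj = generate_trajectory("tetra", n_steps=30, dt=0.5, seed=9,
                                   store_densities=False)
        strategy = make_strategy("gext4", 1e-7)
        probe = probe_guess_strategy(traj, strategy, 1e-7)
        assert probe.idempotency_defects is not None
        assert len(probe.idempotency_defects) > 0
        assert np.max(probe.idempotency_defects) < 1e-10
        assert np.max(probe.trace_errors) < 1e-10


def test_acceleration_conversion_constant():
    # 1 hartree/bohr on 1 amu = 0.937583 bohr/fs^2
    assert ACC_CONV == pytest.approx(0.9375828, rel=1e-5)
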