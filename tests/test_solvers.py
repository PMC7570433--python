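"""Time-stepping schemes: weight identities, classical limits, fractional
relaxation oracles, equilibrium preservation, and memory structure."""

import math

import numpy as np
import pytest

from fractumor.model import HEADLINE_PARAMS, equilibria, rhs
from fractumor.solvers import (
    BlowUpError,
    SolverGrid,
    SolverSpec,
    Trajectory,
    abc_pi_weights,
    abm_weights,
    simulate,
    solve,
    solve_abc_pi,
    solve_caputo_abm,
    solve_cfc_two_step,
    solve_classical_reference,
    solve_ff_exponential,
    solve_ff_mittag_leffler,
    solve_ff_power,
)
from fractumor.special import abc_relaxation_exact, mittag_leffler, normalization_B

FRACTIONAL_SOLVERS = {
    "caputo_abm": lambda f, y0, g, a, t: solve_caputo_abm(f, y0, g, a),
    "cfc_two_step": lambda f, y0, g, a, t: solve_cfc_two_step(f, y0, g, a),
    "abc_pi": lambda f, y0, g, a, t: solve_abc_pi(f, y0, g, a),
    "ff_power": solve_ff_power,
    "ff_exp": solve_ff_exponential,
    "ff_ml": solve_ff_mittag_leffler,
}


class TestGridAndSpec:
    def test_grid_closure_and_times(self):
        g = SolverGrid(1.0, 0.1)
        assert g.n_steps == 10
        assert g.times[0] == 0.0
        assert g.times[-1] == pytest.approx(1.0, abs=1e-12)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            SolverGrid(1.0, -0.1)
        with pytest.raises(ValueError):
            SolverGrid(1.0, 0.3)  # 1.0/0.3 is not an integer step count

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SolverSpec("caputo_abm", alpha=1.5)
        with pytest.raises(ValueError):
            SolverSpec("caputo_abm", alpha=0.9, tau=0.5)  # tau unused here
        with pytest.raises(ValueError):
            SolverSpec("no_such_scheme")


class TestAbmWeights:
    def test_classical_limit_rectangle_and_trapezoid(self):
        h, k = 0.02, 7
        theta, gamma = abm_weights(1.0, h, k)
        assert np.allclose(theta.values, h, atol=1e-15)
        expected = np.full(k + 2, h)
        expected[0] = expected[-1] = h / 2
        assert np.allclose(gamma.values, expected, atol=1e-15)

    @pytest.mark.parametrize("alpha", [0.3, 0.6, 0.95])
    def test_end_weight_and_positivity(self, alpha):
        h, k = 0.05, 9
        theta, gamma = abm_weights(alpha, h, k)
        assert gamma.values[-1] == pytest.approx(h**alpha / (alpha * (alpha + 1)), rel=1e-14)
        assert np.all(theta.values > 0)
        assert np.all(gamma.values > 0)


class TestAbcWeights:
    def test_classical_limit_is_trapezoid(self):
        w = abc_pi_weights(1.0, 0.1, 8).values
        assert w[0] == pytest.approx(0.5)   # p_n
        assert w[1] == pytest.approx(0.5)   # q_0
        assert np.allclose(w[2:], 1.0)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8, 1.0])
    def test_q_weights_positive(self, alpha):
        w = abc_pi_weights(alpha, 0.05, 40)
        assert np.all(w.values[1:] > 0)  # q_j > 0 by convexity of j^(alpha+1)


class TestClassicalLimits:
    def test_all_schemes_recover_exponential_decay(self, relax_field):
        g = SolverGrid(1.0, 0.01)
        for name, fn in FRACTIONAL_SOLVERS.items():
            traj = fn(relax_field, [1.0], g, 1.0, 1.0)
            err = abs(traj.states[-1, 0] - math.exp(-1))
            assert err < 1e-4, (name, err)

    def test_reference_solver_matches_closed_form(self, relax_field):
        traj = solve_classical_reference(relax_field, [1.0], SolverGrid(2.0, 0.01))
        assert np.allclose(traj.states[:, 0], np.exp(-traj.times), atol=1e-9)

    @pytest.mark.parametrize("name", ["cfc_two_step", "ff_exp"])
    def test_two_step_schemes_are_second_order(self, name, relax_field):
        errs = []
        for h in (0.02, 0.01, 0.005):
            traj = FRACTIONAL_SOLVERS[name](relax_field, [1.0], SolverGrid(1.0, h), 1.0, 1.0)
            errs.append(abs(traj.states[-1, 0] - math.exp(-1)))
        slopes = [math.log2(a / b) for a, b in zip(errs, errs[1:])]
        for s in slopes:
            assert abs(s - 2.0) <= 0.3

    def test_ff_power_classical_limit_matches_two_step_lagrange_reference(self, relax_field):
        """Independent scalar reimplementation of the two-point-Lagrange
        product-integration update at alpha = tau = 1."""
        g = SolverGrid(1.0, 0.02)
        n = g.n_steps
        y = [1.0]
        K = [-1.0]
        for k in range(n):
            Kprev = [K[0]] + K[:-1]
            acc = sum(3 * K[z] - Kprev[z] for z in range(k + 1))
            y.append(1.0 + (g.h / 2) * acc)
            K.append(-y[-1])
        traj = solve_ff_power(relax_field, [1.0], g, 1.0, 1.0)
        assert np.allclose(traj.states[:, 0], y, atol=1e-10)

    def test_ff_ml_reduces_to_ff_power_at_unit_orders(self, headline):
        g = SolverGrid(5.0, 0.01)
        f = lambda t, y: rhs(t, y, headline)
        a = solve_ff_power(f, [0.1, 0.1, 0.1], g, 1.0, 1.0)
        b = solve_ff_mittag_leffler(f, [0.1, 0.1, 0.1], g, 1.0, 1.0)
        assert np.max(np.abs(a.states - b.states)) < 1e-8

    def test_ff_exp_at_tau_one_equals_cfc(self, headline):
        g = SolverGrid(5.0, 0.01)
        f = lambda t, y: rhs(t, y, headline)
        a = solve_cfc_two_step(f, [0.1, 0.1, 0.1], g, 1.0)
        b = solve_ff_exponential(f, [0.1, 0.1, 0.1], g, 1.0, 1.0)
        assert np.max(np.abs(a.states - b.states)) < 1e-10


class TestFractionalRelaxation:
    @pytest.mark.parametrize("alpha", [0.7, 0.8, 0.9])
    def test_abm_converges_to_mittag_leffler(self, alpha, relax_field):
        exact = mittag_leffler(alpha, -1.0)
        errs = []
        for h in (0.04, 0.02, 0.01, 0.005):
            traj = solve_caputo_abm(relax_field, [1.0], SolverGrid(1.0, h), alpha)
            errs.append(abs(traj.states[-1, 0] - exact))
        assert all(a > b for a, b in zip(errs, errs[1:]))
        # error at least roughly first order in h
        assert errs[0] / errs[-1] > 4

    @pytest.mark.parametrize("alpha", [0.7, 0.8, 0.9])
    def test_abc_converges_to_its_exact_relaxation_solution(self, alpha, relax_field):
        exact = abc_relaxation_exact(alpha, -1.0, 1.0)
        errs = []
        for h in (0.04, 0.02, 0.01, 0.005):
            traj = solve_abc_pi(relax_field, [1.0], SolverGrid(1.0, h), alpha)
            errs.append(abs(traj.states[-1, 0] - exact))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_abc_classical_limit_equals_trapezoid_rule(self, relax_field):
        """At alpha = 1 the p, q weights telescope to the local trapezoid
        recursion y_{n+1} = y_n (1 - h/2)/(1 + h/2) for dy/dt = -y."""
        h = 0.01
        g = SolverGrid(1.0, h)
        traj = solve_abc_pi(relax_field, [1.0], g, 1.0, tol=1e-15)
        ratio = (1 - h / 2) / (1 + h / 2)
        exact = ratio ** np.arange(g.n_steps + 1)
        assert np.max(np.abs(traj.states[:, 0] - exact)) < 1e-12


class TestStructuralProperties:
    @pytest.mark.parametrize("name", sorted(FRACTIONAL_SOLVERS))
    def test_zero_field_gives_constant_trajectory(self, name):
        f = lambda t, y: np.zeros_like(y)
        traj = FRACTIONAL_SOLVERS[name](f, [0.3, 0.7, 0.1], SolverGrid(2.0, 0.05), 0.8, 0.9)
        assert np.array_equal(traj.states, np.tile([0.3, 0.7, 0.1], (41, 1)))

    @pytest.mark.parametrize("name", sorted(FRACTIONAL_SOLVERS))
    def test_equilibrium_preserved_exactly(self, name, headline):
        """Starting exactly on the tumor-free equilibrium, every scheme
        returns the constant trajectory."""
        f = lambda t, y: rhs(t, y, headline)
        traj = FRACTIONAL_SOLVERS[name](f, [0.0, 1.0, 0.0], SolverGrid(3.0, 0.05), 0.9, 0.95)
        assert np.max(np.abs(traj.states - [0.0, 1.0, 0.0])) < 1e-12

    def test_blow_up_reports_step_index(self):
        f = lambda t, y: y * y
        with pytest.raises(BlowUpError) as exc:
            solve_caputo_abm(f, [2.0], SolverGrid(10.0, 0.1), 1.0)
        assert exc.value.step > 0

    def test_abc_full_history_matters(self, relax_field):
        """Deliberate-bug check: truncating the convolution history to a
        sliding window changes the solution by far more than solver
        tolerance -- the memory of the fractional operator is real."""
        alpha, h, tfin = 0.6, 0.02, 5.0
        g = SolverGrid(tfin, h)
        full = solve_abc_pi(relax_field, [1.0], g, alpha)

        # truncated reimplementation: same p, q weights, window of 25 nodes
        n = g.n_steps
        g2 = math.gamma(alpha + 2)
        pref = alpha * h**alpha / normalization_B(alpha)
        idx = np.arange(1, n + 1, dtype=float)
        p = ((idx - 1) ** (alpha + 1) - idx**alpha * (idx - alpha - 1)) / g2
        q = np.empty(n)
        q[0] = 1.0 / g2 + (1.0 - alpha) / (alpha * h**alpha)
        j = np.arange(1, n, dtype=float)
        q[1:] = ((j - 1) ** (alpha + 1) - 2 * j ** (alpha + 1) + (j + 1) ** (alpha + 1)) / g2
        window = 25
        y = np.empty(n + 1)
        F = np.empty(n + 1)
        y[0], F[0] = 1.0, -1.0
        for step in range(1, n + 1):
            lo = max(1, step - window)
            hist = q[step - np.arange(lo, step)] @ F[lo:step] if step > 1 else 0.0
            base = 1.0 + pref * (p[step - 1] * F[0] + hist)
            cur = base
            for _ in range(50):
                nxt = base + pref * q[0] * (-cur)
                if abs(nxt - cur) < 1e-12:
                    cur = nxt
                    break
                cur = nxt
            y[step] = cur
            F[step] = -cur
        assert abs(full.states[-1, 0] - y[-1]) > 1e-6

    def test_ff_ml_trajectories_remain_bounded_in_oscillatory_regime(self, headline):
        traj = solve_ff_mittag_leffler(
            lambda t, y: rhs(t, y, headline), [0.1, 0.1, 0.1],
            SolverGrid(300.0, 0.005), 0.95, 0.95,
        )
        assert traj.states.min() >= 0.0
        assert traj.states.max() <= 1.5

    def test_reference_keeps_positive_octant(self, headline):
        traj = solve_classical_reference(
            lambda t, y: rhs(t, y, headline), [0.1, 0.1, 0.1], SolverGrid(500.0, 0.05)
        )
        assert traj.states.min() >= -1e-10


class TestDispatchAndIO:
    def test_simulate_attaches_provenance(self, headline):
        g = SolverGrid(1.0, 0.01)
        traj = simulate(headline, [0.1, 0.1, 0.1], g, SolverSpec("cfc_two_step", alpha=0.9))
        assert traj.scheme == "cfc_two_step"
        assert traj.params["b12"] == 1.0
        assert np.array_equal(traj.initial, [0.1, 0.1, 0.1])
        assert len(traj.times) == g.n_steps + 1

    def test_csv_roundtrip_bit_for_bit(self, headline, tmp_path):
        traj = simulate(
            headline, [0.1, 0.1, 0.1], SolverGrid(1.0, 0.01), SolverSpec("caputo_abm", alpha=0.85)
        )
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        back = Trajectory.read_csv(path)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.states, traj.states)

    def test_identical_config_gives_identical_bytes(self, headline, tmp_path):
        spec = SolverSpec("abc_pi", alpha=0.9)
        g = SolverGrid(1.0, 0.01)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate(headline, [0.1, 0.1, 0.1], g, spec).write_csv(p1)
        simulate(headline, [0.1, 0.1, 0.1], g, spec).write_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
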