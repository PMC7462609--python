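"""Finite-difference machinery: grids, operators, stepping, flux, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gddm
from gddm import (GDDMSpec, Drift, Noise, Bound, StabilityError, build_grid,
                  build_operator, check_forward_stability, extract_flux,
                  select_method, solve, step)
from gddm.solver import SCHEME_ALPHA, TridiagonalOperator


def _const_spec(mu=0.0, sigma=1.0, B=1.0):
    return GDDMSpec(drift=Drift(lambda x, t, c, p: mu),
                    noise=Noise(lambda x, t, c, p: sigma),
                    bound=Bound(lambda t, c, p: B))


# ---------------------------------------------------------------- grid
def test_grid_direct_construction():
    grid = build_grid(_const_spec(), {}, dx=0.5, dt=0.01, t_dur=2.0)
    np.testing.assert_allclose(grid.x, [-0.5, 0.0, 0.5])
    assert grid.n_steps == 200


def test_grid_dx_adjusted_to_keep_zero_on_grid():
    grid = build_grid(_const_spec(), {}, dx=0.3, dt=0.01, t_dur=2.0)
    assert grid.dx == pytest.approx(0.25)
    np.testing.assert_allclose(grid.x, np.arange(-0.75, 0.76, 0.25), atol=1e-12)
    assert 0.0 in grid.x


def test_grid_rejects_nonpositive_bound():
    with pytest.raises(ValueError, match="B\\(0\\)"):
        build_grid(_const_spec(B=-1.0), {}, dx=0.1, dt=0.01, t_dur=1.0)


# ------------------------------------------------------------ operator
def test_operator_entries_diffusion_only():
    """nu = D dt/dx^2 = 5 for sigma=1, dx=dt=0.1: diagonal 10, off-diagonals -5."""
    spec = _const_spec()
    grid = build_grid(spec, {}, dx=0.1, dt=0.1, t_dur=1.0)
    op = build_operator(spec, grid, {})
    np.testing.assert_allclose(op.nu, 5.0)
    np.testing.assert_allclose(op.chi, 0.0)
    ab = op.lhs_banded(0.0)  # I + M for backward Euler
    np.testing.assert_allclose(ab[1], 1.0 + 10.0)
    np.testing.assert_allclose(ab[0, 1:], -5.0)
    np.testing.assert_allclose(ab[2, :-1], -5.0)


def test_operator_entries_benchmark_parameterization():
    spec = _const_spec(mu=2.0, sigma=1.5)
    grid = build_grid(spec, {}, dx=0.01, dt=0.01, t_dur=1.0)
    op = build_operator(spec, grid, {})
    np.testing.assert_allclose(op.nu, 112.5)
    np.testing.assert_allclose(op.chi, 2.0)


def test_operator_vanishing_noise_reduces_to_advection():
    spec = _const_spec(mu=1.0, sigma=1e-9)
    grid = build_grid(spec, {}, dx=0.1, dt=0.1, t_dur=1.0)
    op = build_operator(spec, grid, {})
    assert np.all(op.nu < 1e-15)
    np.testing.assert_allclose(op.chi, 1.0)


# ------------------------------------------------------------ stability
def test_forward_stability_examples():
    # dt = 0.43 dx^2 with sigma=1.5: ratio = 1.125*0.43 < 1/2
    spec = _const_spec(sigma=1.5)
    grid = build_grid(spec, {}, dx=0.1, dt=0.43 * 0.1**2, t_dur=0.86)
    stable, ratio = check_forward_stability(spec, grid, {})
    assert stable and ratio == pytest.approx(0.48375)
    # dt = dx = 0.01: ratio = 112.5
    grid2 = build_grid(spec, {}, dx=0.01, dt=0.01, t_dur=2.0)
    stable2, ratio2 = check_forward_stability(spec, grid2, {})
    assert not stable2 and ratio2 == pytest.approx(112.5)
    # vanishing diffusion is always stable
    grid3 = build_grid(_const_spec(sigma=1e-12), {}, dx=0.01, dt=0.5, t_dur=2.0)
    stable3, ratio3 = check_forward_stability(_const_spec(sigma=1e-12),
                                              grid3, {})
    assert stable3 and ratio3 == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------- stepping
def test_zero_operator_is_identity():
    op = TridiagonalOperator(np.zeros(7), np.zeros(7))
    P = np.linspace(0, 1, 7)
    for alpha in SCHEME_ALPHA.values():
        np.testing.assert_array_equal(step(P, op, alpha), P)


def test_backward_step_matches_dense_solve():
    """One implicit step equals a dense linear solve of (I + M) P' = P."""
    rng = np.random.default_rng(3)
    nu = rng.uniform(0.5, 2.0, 7)
    chi = rng.uniform(-0.5, 0.5, 7)
    op = TridiagonalOperator(nu, chi)
    P = rng.dirichlet(np.ones(7))
    M = np.zeros((7, 7))
    for j in range(7):
        M[j, j] = 2 * nu[j]
        if j + 1 < 7:
            M[j, j + 1] = -nu[j + 1] + chi[j + 1] / 2
        if j - 1 >= 0:
            M[j, j - 1] = -nu[j - 1] - chi[j - 1] / 2
    expected = np.linalg.solve(np.eye(7) + M, P)
    np.testing.assert_allclose(step(P, op, 0.0), expected, rtol=1e-12)


def test_step_size_mismatch_rejected():
    op = TridiagonalOperator(np.ones(5), np.zeros(5))
    with pytest.raises(ValueError, match="does not match"):
        step(np.ones(4), op, 0.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.sampled_from([1.0, 0.0, 0.5]))
def test_flux_closes_conservation_for_any_operator(seed, alpha):
    """sum(P_old) = sum(P_new) + flux_up + flux_lo to rounding, all schemes."""
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 30)
    op = TridiagonalOperator(rng.uniform(0.0, 3.0, n),
                             rng.uniform(-1.0, 1.0, n))
    P = rng.dirichlet(np.ones(n))
    P_new = step(P, op, alpha)
    q_top = alpha * P[-1] + (1 - alpha) * P_new[-1]
    q_bot = alpha * P[0] + (1 - alpha) * P_new[0]
    up = (op.nu[-1] + op.chi[-1] / 2) * q_top
    lo = (op.nu[0] - op.chi[0] / 2) * q_bot
    assert P.sum() == pytest.approx(P_new.sum() + up + lo, abs=1e-12)
    flux_up, flux_lo = extract_flux(P, P_new, op, alpha)
    assert flux_up >= 0.0 and flux_lo >= 0.0


# ------------------------------------------------------------ selection
def test_method_priority_order():
    assert select_method(GDDMSpec()) == "analytic"
    leaky = GDDMSpec(drift=Drift(lambda x, t, c, p: -0.5 * np.asarray(x),
                                 x_dependent=True))
    assert select_method(leaky) == "crank_nicolson"
    assert select_method(gddm.get_model("gddm_leak_collapse").spec) \
        == "backward_euler"


# ---------------------------------------------------------------- solve
def test_driftless_solution_is_symmetric():
    # implicit LU sweeps run left to right, so symmetry holds to rounding
    sol = solve(GDDMSpec(), {}, dx=0.01, dt=0.01, method="backward_euler")
    np.testing.assert_allclose(sol.upper, sol.lower, rtol=1e-10, atol=1e-15)


def test_reflection_swaps_choice_distributions():
    a = solve(_const_spec(mu=1.5), {}, dx=0.02, dt=0.02,
              method="crank_nicolson")
    b = solve(_const_spec(mu=-1.5), {}, dx=0.02, dt=0.02,
              method="crank_nicolson")
    np.testing.assert_allclose(a.upper, b.lower, rtol=1e-10, atol=1e-15)
    np.testing.assert_allclose(a.lower, b.upper, rtol=1e-10, atol=1e-15)


@pytest.mark.parametrize("method", ["backward_euler", "crank_nicolson"])
def test_benchmark_choice_probability(method, benchmark_entry):
    sol = solve(benchmark_entry.spec, {}, dx=0.005, dt=0.005, method=method)
    assert sol.prob_upper == pytest.approx(
        gddm.choice_probability_upper(2.0, 1.5, 1.0), abs=2e-3)
    assert sol.total_mass == pytest.approx(1.0, abs=1e-9)


def test_forced_unstable_forward_euler_refused(benchmark_entry):
    with pytest.raises(StabilityError, match="112.5"):
        solve(benchmark_entry.spec, {}, dx=0.01, dt=0.01,
              method="forward_euler")


def test_stable_forward_euler_agrees_with_backward(benchmark_entry):
    dx = 0.02
    dt = 0.3 * dx**2 / 1.125  # ratio 0.3, comfortably stable
    fe = solve(benchmark_entry.spec, {}, dx=dx, dt=dt, method="forward_euler")
    be = solve(benchmark_entry.spec, {}, dx=dx, dt=dt, method="backward_euler")
    assert np.abs(fe.upper - be.upper).max() < 1e-5
    assert fe.prob_upper == pytest.approx(be.prob_upper, abs=1e-4)


def test_crank_nicolson_refused_for_moving_bounds():
    spec = gddm.get_model("gddm_leak_collapse").spec
    with pytest.raises(ValueError, match="time-varying"):
        solve(spec, {"coherence": 0.256}, dx=0.02, dt=0.02,
              method="crank_nicolson")


def test_validation_failure_blocks_solve():
    spec = GDDMSpec(noise=Noise(lambda x, t, c, p: -1.0))
    with pytest.raises(ValueError, match="noise-positivity"):
        solve(spec, {}, dx=0.05, dt=0.05)


@pytest.mark.parametrize("method", ["analytic", "backward_euler",
                                    "crank_nicolson"])
def test_conservation_across_methods(method, benchmark_entry):
    sol = solve(benchmark_entry.spec, {}, dx=0.02, dt=0.02, method=method)
    assert sol.total_mass == pytest.approx(1.0, abs=1e-9)
    assert sol.upper.min() >= 0 and sol.lower.min() >= 0


def test_solution_provenance_recorded(benchmark_entry):
    sol = solve(benchmark_entry.spec, {}, dx=0.03, dt=0.02,
                method="backward_euler")
    assert sol.method == "backward_euler"
    assert sol.meta["requested_dx"] == 0.03
    assert sol.dx <= 0.03  # adjusted downward to divide 2 B0
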