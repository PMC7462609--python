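"""Model-zoo structure: parameter counts, defaults validity, nesting."""

import numpy as np
import pytest

import gddm
from gddm import Parameter, ParameterSet, solve, validate_model
from gddm.solver import build_grid


EXPECTED_COUNTS = {
    "gddm_leak_collapse": 6,
    "ddm": 3,
    "full_ddm": 11,
    "ddm_per_level_drift": 8,
    "ddm_per_condition": 18,
}

_CONDS = {
    "gddm_leak_collapse": {"coherence": 0.256},
    "ddm": {"coherence": 0.256},
    "full_ddm": {"coherence_level": 2},
    "ddm_per_level_drift": {"coherence_level": 2},
    "ddm_per_condition": {"coherence_level": 2},
    "benchmark_constant": {},
    "coherence_scan": {"coherence": 0.3},
}


@pytest.mark.parametrize("name,count", sorted(EXPECTED_COUNTS.items()))
def test_declared_parameter_counts(name, count):
    entry = gddm.get_model(name)
    assert entry.n_params == count
    assert len(entry.spec.params) == count


@pytest.mark.parametrize("name", sorted(_CONDS))
def test_default_models_validate_cleanly(name):
    entry = gddm.get_model(name)
    conditions = _CONDS[name]
    grid = build_grid(entry.spec, conditions, 0.02, 0.02, 2.0)
    assert validate_model(entry.spec, grid, conditions) == []


@pytest.mark.parametrize("name", sorted(_CONDS))
def test_all_zoo_entries_solve_and_conserve(name):
    entry = gddm.get_model(name)
    sol = entry.solve(_CONDS[name], dx=0.01, dt=0.01)
    assert sol.total_mass == pytest.approx(1.0, abs=1e-9)


def test_unknown_model_name():
    with pytest.raises(KeyError, match="available"):
        gddm.get_model("nope")


def test_gddm_zero_coherence_drift_is_pure_leak():
    entry = gddm.get_model("gddm_leak_collapse")
    p = entry.spec.params
    x = np.array([-0.5, 0.0, 0.5])
    mu = entry.spec.drift(x, 0.0, {"coherence": 0.0}, p)
    np.testing.assert_allclose(mu, -p["leak"] * x)


def test_gddm_reduces_to_plain_ddm():
    """leak=0, tau=inf, alpha=1 recovers the 3-parameter DDM exactly."""
    g = gddm.get_model("gddm_leak_collapse", C_max=0.512)
    pg = ParameterSet(mu0=Parameter(5.0 * 0.512, 0, 40),
                      alpha=Parameter(1.0, 0, 5),
                      leak=Parameter(0.0, -5, 20),
                      B0=Parameter(1.0, 0.3, 3),
                      tau=Parameter(np.inf, 0.1, np.inf),
                      t_nd=Parameter(0.2, 0, 1))
    d = gddm.get_model("ddm")
    c = {"coherence": 0.256}
    sg = solve(g.spec, c, dx=0.01, dt=0.01, method="backward_euler", params=pg)
    sd = solve(d.spec, c, dx=0.01, dt=0.01, method="backward_euler")
    assert np.abs(sg.upper - sd.upper).max() <= 1e-9
    assert np.abs(sg.lower - sd.lower).max() <= 1e-9


def _full_ddm_params(s_v=0.0, s_z=0.0, s_T=0.0):
    drifts = {f"mu{j}": Parameter(v, -40, 40)
              for j, v in enumerate([0.0, 0.32, 0.64, 1.28, 2.56, 5.12])}
    return ParameterSet(**drifts, B0=Parameter(1.0, 0.3, 3),
                        t_nd=Parameter(0.2, 0, 1),
                        s_v=Parameter(s_v, 0, 5), s_z=Parameter(s_z, 0, 0.29),
                        s_T=Parameter(s_T, 0, 0.19))


def test_full_ddm_without_variability_reduces_to_shared_form():
    f = gddm.get_model("full_ddm")
    e8 = gddm.get_model("ddm_per_level_drift")
    c = {"coherence_level": 3}
    sf = f.solve(c, params=_full_ddm_params(), dx=0.01, dt=0.01,
                 method="crank_nicolson")
    s8 = solve(e8.spec, c, dx=0.01, dt=0.01, method="crank_nicolson")
    assert np.abs(sf.upper - s8.upper).max() <= 1e-9
    assert np.abs(sf.lower - s8.lower).max() <= 1e-9


def test_drift_variability_widens_rt_distribution():
    f = gddm.get_model("full_ddm")
    c = {"coherence_level": 4}
    narrow = f.solve(c, params=_full_ddm_params(), dx=0.01, dt=0.01)
    wide = f.solve(c, params=_full_ddm_params(s_v=1.5), dx=0.01, dt=0.01)
    assert wide.total_mass == pytest.approx(1.0, abs=1e-9)

    def rt_var(sol):
        m = sol.upper + sol.lower
        mean = np.sum(m * sol.t_bin_mids) / m.sum()
        return np.sum(m * (sol.t_bin_mids - mean) ** 2) / m.sum()

    assert rt_var(wide) > rt_var(narrow)


def test_per_level_shared_drift_equals_plain_ddm():
    """mu_j = mu0 * C_j makes the 8-parameter form match the 3-parameter one."""
    e8 = gddm.get_model("ddm_per_level_drift")
    mu0, C_j = 5.0, 0.128
    p8 = e8.spec.params.with_values([mu0 * c for c in
                                     [0.0, 0.032, 0.064, 0.128, 0.256, 0.512]]
                                    + [1.0, 0.2])
    d = gddm.get_model("ddm")
    s8 = solve(e8.spec, {"coherence_level": 3}, dx=0.01, dt=0.01,
               method="crank_nicolson", params=p8)
    sd = solve(d.spec, {"coherence": C_j}, dx=0.01, dt=0.01,
               method="crank_nicolson")
    assert np.abs(s8.upper - sd.upper).max() <= 1e-12


def test_per_condition_entries_are_independent_analytic_ddms():
    entry = gddm.get_model("ddm_per_condition")
    for j in (0, 3, 5):
        sol = entry.solve({"coherence_level": j}, dx=0.01, dt=0.01)
        assert sol.method == "analytic"
    a = entry.solve({"coherence_level": 1}, dx=0.01, dt=0.01)
    entry.solve({"coherence_level": 4}, dx=0.01, dt=0.01)
    b = entry.solve({"coherence_level": 1}, dx=0.01, dt=0.01)
    np.testing.assert_array_equal(a.upper, b.upper)  # order-independence


def test_benchmark_and_scan_models():
    b = gddm.get_model("benchmark_constant")
    assert gddm.check_analytic_eligibility(b.spec).eligible
    scan = gddm.get_model("coherence_scan")
    sol = scan.solve({"coherence": 0.0}, dx=0.01, dt=0.01,
                     method="backward_euler")
    np.testing.assert_allclose(sol.upper, sol.lower, rtol=1e-10, atol=1e-15)
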