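"""Overlay semantics, likelihoods, information criteria and fitting."""

import numpy as np
import pytest

import gddm
from gddm import (GDDMSpec, NonDecisionOverlay, Parameter, ParameterSet,
                  RTDataset, SolutionPDF, UniformMixtureOverlay, bic, fit,
                  mse_objective, negative_log_likelihood)
import pandas as pd


def _flat_solution(n_bins=100, dt=0.02, upper_mass=1.0, lower_mass=0.0,
                   undecided=0.0):
    return SolutionPDF(dt=dt,
                       upper=np.full(n_bins, upper_mass / n_bins),
                       lower=np.full(n_bins, lower_mass / n_bins),
                       undecided=undecided)


class _FixedModel:
    """Entry-like stub returning a fixed solution; counts solve calls."""

    def __init__(self, solution, params=None):
        self.spec = GDDMSpec(params=params or ParameterSet())
        self.solution = solution
        self.calls = 0

    def solve(self, conditions=None, params=None, **kw):
        self.calls += 1
        return self.solution


# ------------------------------------------------------------- overlays
def test_identity_overlays_change_nothing():
    sol = _flat_solution(upper_mass=0.6, lower_mass=0.3, undecided=0.1)
    out = NonDecisionOverlay(t_nd=0.0).apply(sol, {}, ParameterSet())
    out = UniformMixtureOverlay(w=1.0).apply(out, {}, ParameterSet())
    np.testing.assert_array_equal(out.upper, sol.upper)
    np.testing.assert_array_equal(out.lower, sol.lower)
    assert out.undecided == sol.undecided


def test_mixture_weights_total_mass():
    """w=0.95 on a fully decided solution keeps total mass exactly one."""
    sol = _flat_solution(upper_mass=0.7, lower_mass=0.3)
    out = UniformMixtureOverlay(w=0.95).apply(sol, {}, ParameterSet())
    assert out.total_mass == pytest.approx(1.0, abs=1e-15)
    assert out.prob_upper == pytest.approx(0.95 * 0.7 + 0.025)


def test_shift_semantics_zeroes_leading_bins():
    sol = _flat_solution(n_bins=200, dt=0.01)
    out = NonDecisionOverlay(t_nd=0.3).apply(sol, {}, ParameterSet())
    assert np.all(out.upper[:30] == 0.0)
    np.testing.assert_allclose(out.upper[30:], sol.upper[:-30])
    assert out.total_mass == pytest.approx(sol.total_mass, abs=1e-12)


def test_shift_beyond_duration_rejected():
    sol = _flat_solution(n_bins=10, dt=0.1)
    with pytest.raises(ValueError, match="t_dur"):
        NonDecisionOverlay(t_nd=1.0).apply(sol, {}, ParameterSet())


def test_jittered_shift_spreads_mass():
    sol = SolutionPDF(dt=0.01, upper=np.eye(1, 100, 0)[0], lower=np.zeros(100),
                      undecided=0.0)
    out = NonDecisionOverlay(t_nd=0.2, width=0.02).apply(sol, {},
                                                         ParameterSet())
    support = np.flatnonzero(out.upper)
    assert support.tolist() == [18, 19, 20, 21, 22]
    np.testing.assert_allclose(out.upper[support], 0.2)


def test_overlay_parameters_resolved_by_name_and_callable():
    sol = _flat_solution(n_bins=100, dt=0.01)
    params = ParameterSet(t_nd0=0.1, t_nd1=0.5)
    ov = NonDecisionOverlay(
        t_nd=lambda cond, p: p[f"t_nd{int(cond['level'])}"])
    out0 = ov.apply(sol, {"level": 0}, params)
    out1 = ov.apply(sol, {"level": 1}, params)
    assert np.flatnonzero(out0.upper)[0] == 10
    assert np.flatnonzero(out1.upper)[0] == 50


# ---------------------------------------------------------- likelihoods
def test_unit_density_trial_has_zero_nll():
    # all upper mass uniform over 2 s at density 0.5/s -> use 1 s of mass 1
    model = _FixedModel(SolutionPDF(dt=0.01, upper=np.full(100, 0.01),
                                    lower=np.zeros(100), undecided=0.0))
    ds = RTDataset(pd.DataFrame({"rt": [0.5], "choice": [1]}))
    assert negative_log_likelihood(model, ds, t_dur=1.0) == pytest.approx(0.0,
                                                                          abs=1e-12)


def test_pure_lapse_nll_is_log4_per_trial():
    """A near-total lapse mixture over 2 s gives density 1/4 per second."""
    diffusion = SolutionPDF(dt=0.01, upper=np.zeros(200), lower=np.zeros(200),
                            undecided=1.0)
    lapsed = UniformMixtureOverlay(w=1e-9).apply(diffusion, {}, ParameterSet())
    model = _FixedModel(lapsed)
    ds = RTDataset(pd.DataFrame({"rt": [0.3, 1.2, 1.9], "choice": [1, 0, 1]}))
    nll = negative_log_likelihood(model, ds, t_dur=2.0)
    assert nll == pytest.approx(3 * np.log(4.0), rel=1e-6)


def test_zero_density_without_mixture_is_an_error():
    model = _FixedModel(SolutionPDF(dt=0.01, upper=np.full(100, 0.01),
                                    lower=np.zeros(100), undecided=0.0))
    ds = RTDataset(pd.DataFrame({"rt": [0.5], "choice": [0]}))  # lower: dens 0
    with pytest.raises(ValueError, match="mixture"):
        negative_log_likelihood(model, ds, t_dur=1.0)


def test_solutions_cached_once_per_condition():
    model = _FixedModel(_flat_solution())
    ds = RTDataset(pd.DataFrame({"rt": [0.5, 0.6, 0.7, 0.8],
                                 "choice": [1, 1, 1, 1],
                                 "coherence": [0.1, 0.1, 0.2, 0.2]}))
    negative_log_likelihood(model, ds, t_dur=2.0, _cache={})
    assert model.calls == 2  # once per distinct condition, not per trial


def test_likelihood_dominance_at_generating_parameters(small_ddm_dataset):
    """Self-generated data is best explained near the generating parameters."""
    ds, truth = small_ddm_dataset
    entry = gddm.get_model("ddm")
    t = [truth["params"]["mu0"], truth["params"]["B0"], truth["params"]["t_nd"]]
    nll_true = negative_log_likelihood(entry, ds,
                                       params=entry.spec.params.with_values(t))
    for factor in (0.8, 1.2):
        pert = entry.spec.params.with_values([v * factor for v in t])
        assert nll_true <= negative_log_likelihood(entry, ds, params=pert)


# ------------------------------------------------------------------ mse
def test_mse_zero_when_model_equals_histogram():
    ds = RTDataset(pd.DataFrame({"rt": [0.25, 0.75], "choice": [1, 0]}))
    upper = np.zeros(100)
    lower = np.zeros(100)
    upper[24] = 0.5
    lower[74] = 0.5
    model = _FixedModel(SolutionPDF(dt=0.01, upper=upper, lower=lower,
                                    undecided=0.0))
    assert mse_objective(model, ds, dt_bin=0.01, t_dur=1.0) == pytest.approx(
        0.0, abs=1e-18)


def test_mse_invariant_to_condition_order(small_ddm_dataset):
    ds, _ = small_ddm_dataset
    entry = gddm.get_model("ddm")
    shuffled = RTDataset(ds.df.sample(frac=1.0, random_state=0))
    a = mse_objective(entry, ds, dt_bin=0.02)
    b = mse_objective(entry, shuffled, dt_bin=0.02)
    assert a == pytest.approx(b, rel=1e-12)


# ------------------------------------------------------------------ bic
def test_bic_formula_and_monotonicity():
    assert bic(500.0, 0, 1000) == 1000.0
    assert bic(500.0, 6, 1000) == pytest.approx(6 * np.log(1000) + 1000)
    assert bic(500.0, 7, 1000) > bic(500.0, 6, 1000)
    with pytest.raises(ValueError):
        bic(1.0, -1, 10)


# ------------------------------------------------------------------ fit
def test_single_parameter_drift_recovery():
    """A drift-only fit on self-generated data recovers mu0 within 0.1."""
    def drift(x, t, c, p):
        return p["mu0"] * c["coherence"]

    spec = GDDMSpec(name="drift_only", drift=gddm.Drift(drift),
                    overlays=(NonDecisionOverlay(t_nd=0.2),
                              UniformMixtureOverlay(w=0.95)),
                    params=ParameterSet(mu0=Parameter(1.0, 0.0, 40.0)),
                    required_conditions=("coherence",))
    truth = spec.params.with_values([5.0])
    sol = gddm.solve(spec, {"coherence": 0.512}, dx=0.005, dt=0.005,
                     params=truth)
    samp = gddm.sample_from_solution(sol, 5000, seed=21)
    from gddm.io import sample_to_dataset
    ds = sample_to_dataset(samp, {"coherence": 0.512})
    res = fit(spec, ds, seed=22, maxiter=40, tol=1e-4)
    assert res.params["mu0"] == pytest.approx(5.0, abs=0.1)
    assert np.isfinite(res.nll)
    assert res.bic == pytest.approx(bic(res.nll, 1, ds.n))


def test_fit_deterministic_given_seed(small_ddm_dataset):
    ds, _ = small_ddm_dataset
    entry = gddm.get_model("ddm")
    a = fit(entry, ds, seed=5, maxiter=3, tol=1e-2)
    b = fit(entry, ds, seed=5, maxiter=3, tol=1e-2)
    assert a.params.values_vector().tolist() == b.params.values_vector().tolist()
    assert a.nll == b.nll


def test_differential_evolution_requires_finite_bounds():
    spec = GDDMSpec(params=ParameterSet(a=Parameter(0.0)))  # unbounded
    ds = RTDataset(pd.DataFrame({"rt": [0.5], "choice": [1]}))
    with pytest.raises(ValueError, match="finite bounds"):
        fit(spec, ds)


def test_rt_beyond_duration_rejected():
    entry = gddm.get_model("ddm")
    ds = RTDataset(pd.DataFrame({"rt": [2.5], "choice": [1],
                                 "coherence": [0.1]}))
    with pytest.raises(ValueError, match="t_dur"):
        negative_log_likelihood(entry, ds, t_dur=2.0)
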