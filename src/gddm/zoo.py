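"""Pre-built model constructors for perceptual decision-making fits.

The zoo covers the standard model ladder for random-dot motion data:

* ``gddm_leak_collapse`` -- 6 parameters: coherence-nonlinear drift with a
  leak term, exponentially collapsing bounds, non-decision time, and a
  fixed 0.95/0.05 uniform-lapse mixture.
* ``ddm`` -- the 3-parameter standard DDM (shared drift scale mu0 * C,
  constant bound, non-decision time, same lapse mixture).
* ``full_ddm`` -- 11 parameters: one drift per coherence level plus
  across-trial variability in drift (normal, s_v), starting point
  (uniform, s_z) and non-decision time (uniform, s_T).
* ``ddm_per_level_drift`` -- 8 parameters: one drift per coherence level,
  shared bound and non-decision time.
* ``ddm_per_condition`` -- 18 parameters: independent (drift, bound,
  non-decision time) triples per coherence level; no lapse mixture.
* ``benchmark_constant`` / ``coherence_scan`` -- fixed-coefficient models
  used for accuracy and parallelism benchmarking.

Across-trial drift variability does not fit the Fokker-Planck state space,
so ``full_ddm`` discretizes the normal drift distribution into quadrature
points, solves each, and mixes the solutions by weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import (Bound, Drift, GDDMSpec, InitialCondition, Noise, Parameter,
                    ParameterSet)
from .overlays import NonDecisionOverlay, UniformMixtureOverlay
from . import solver

__all__ = ["ZooEntry", "REGISTRY", "get_model", "make_gddm", "make_ddm",
           "make_full_ddm", "make_ddm_per_level_drift",
           "make_ddm_per_condition", "make_benchmark", "make_coherence_scan",
           "DRIFT_VARIABILITY_POINTS"]

#: Quadrature points used to discretize normal across-trial drift variability.
DRIFT_VARIABILITY_POINTS = 11

#: Fixed diffusion weight of the lapse mixture in the fitted models.
LAPSE_MIX_W = 0.95


@dataclass(frozen=True)
class ZooEntry:
    """A named model constructor output: spec, declared size, solve hook."""

    name: str
    spec: GDDMSpec
    n_params: int
    required_conditions: tuple[str, ...]
    description: str = ""
    _solver: Callable | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.spec.params) != self.n_params:
            raise ValueError(
                f"{self.name}: ParameterSet has {len(self.spec.params)} "
                f"entries, declared {self.n_params}")

    def solve(self, conditions=None, params=None, dx=0.005, dt=0.005,
              t_dur=2.0, method="auto"):
        if self._solver is not None:
            return self._solver(self.spec, conditions, params, dx, dt, t_dur,
                                method)
        return solver.solve(self.spec, conditions, dx=dx, dt=dt, t_dur=t_dur,
                            method=method, params=params)


# ----------------------------------------------------------------------
def make_gddm(C_max: float = 0.512) -> ZooEntry:
    """Leaky integration + collapsing bounds GDDM (6 parameters).

    Drift mu0 * (C / C_max)**alpha - leak * x, unit noise, bound
    B0 * exp(-t / tau), point-mass start, non-decision shift t_nd and the
    fixed 0.95/0.05 lapse mixture.  C_max is the task's maximum coherence.
    """
    if C_max <= 0:
        raise ValueError("C_max must be positive")

    def drift(x, t, cond, p):
        stim = p["mu0"] * (cond["coherence"] / C_max) ** p["alpha"] \
            if cond["coherence"] > 0 else 0.0
        return stim - p["leak"] * np.asarray(x)

    def bound(t, cond, p):
        return p["B0"] * np.exp(-t / p["tau"])

    params = ParameterSet(
        mu0=Parameter(8.0, 0.0, 40.0),
        alpha=Parameter(1.0, 0.0, 5.0),
        leak=Parameter(1.0, -5.0, 20.0),
        B0=Parameter(1.0, 0.3, 3.0),
        tau=Parameter(1.0, 0.1, 10.0),
        t_nd=Parameter(0.25, 0.0, 1.0),
    )
    spec = GDDMSpec(
        name="gddm_leak_collapse",
        drift=Drift(drift, x_dependent=True, t_dependent=False),
        bound=Bound(bound, t_dependent=True),
        overlays=(NonDecisionOverlay(t_nd="t_nd"),
                  UniformMixtureOverlay(w=LAPSE_MIX_W)),
        params=params,
        required_conditions=("coherence",),
    )
    return ZooEntry("gddm_leak_collapse", spec, 6, ("coherence",),
                    "leaky, collapsing-bound GDDM with coherence nonlinearity")


def make_ddm() -> ZooEntry:
    """Standard 3-parameter DDM: drift mu0 * C, constant bound B0, shift t_nd."""

    def drift(x, t, cond, p):
        return p["mu0"] * cond["coherence"]

    params = ParameterSet(
        mu0=Parameter(5.0, 0.0, 40.0),
        B0=Parameter(1.0, 0.3, 3.0),
        t_nd=Parameter(0.2, 0.0, 1.0),
    )
    spec = GDDMSpec(
        name="ddm",
        drift=Drift(drift),
        bound=Bound(lambda t, c, p: p["B0"]),
        overlays=(NonDecisionOverlay(t_nd="t_nd"),
                  UniformMixtureOverlay(w=LAPSE_MIX_W)),
        params=params,
        required_conditions=("coherence",),
    )
    return ZooEntry("ddm", spec, 3, ("coherence",),
                    "standard DDM with shared drift scale")


def _uniform_start_ic(x_grid, cond, p):
    """Uniform starting density over [-s_z, s_z], overlap-weighted onto cells."""
    s_z = p["s_z"]
    x = np.asarray(x_grid, dtype=float)
    dx = x[1] - x[0] if x.size > 1 else 1.0
    if s_z <= dx / 2:
        masses = np.zeros_like(x)
        masses[int(np.argmin(np.abs(x)))] = 1.0
        return masses
    left = np.maximum(x - dx / 2, -s_z)
    right = np.minimum(x + dx / 2, s_z)
    masses = np.clip(right - left, 0.0, None)
    return masses / masses.sum()


def _per_level_drift(x, t, cond, p):
    j = int(cond["coherence_level"])
    return p[f"mu{j}"] + cond.get("_drift_offset", 0.0)


def _default_level_drifts() -> dict:
    # spread resembling mu0=10 at coherences {0, .032, .064, .128, .256, .512}
    vals = [0.0, 0.32, 0.64, 1.28, 2.56, 5.12]
    return {f"mu{j}": Parameter(v, -40.0, 40.0) for j, v in enumerate(vals)}


def _solve_drift_mixture(spec, conditions, params, dx, dt, t_dur, method):
    """Quadrature over normal across-trial drift variability.

    Discretizes N(mu_j, s_v^2) at DRIFT_VARIABILITY_POINTS points spanning
    +/- 3 s_v, with renormalized normal weights; solves the Fokker-Planck
    equation per point and mixes the (pre-overlay) solutions, then applies
    the overlay chain once.
    """
    from .overlays import apply_overlay_chain

    conditions = {} if conditions is None else conditions
    params = spec.params if params is None else params
    s_v = params["s_v"]
    if s_v <= 0:
        return solver.solve(spec, conditions, dx=dx, dt=dt, t_dur=t_dur,
                            method=method, params=params)
    g = np.linspace(-3.0, 3.0, DRIFT_VARIABILITY_POINTS)
    w = np.exp(-0.5 * g**2)
    w /= w.sum()
    mix = None
    for gk, wk in zip(g, w):
        sol_k = solver.solve(spec, {**conditions, "_drift_offset": s_v * gk},
                             dx=dx, dt=dt, t_dur=t_dur, method=method,
                             params=params, with_overlays=False)
        if mix is None:
            mix = sol_k.replace(upper=wk * sol_k.upper,
                                lower=wk * sol_k.lower,
                                undecided=wk * sol_k.undecided,
                                method=sol_k.method + "+drift_mixture")
        else:
            mix = mix.replace(upper=mix.upper + wk * sol_k.upper,
                              lower=mix.lower + wk * sol_k.lower,
                              undecided=mix.undecided + wk * sol_k.undecided)
    return apply_overlay_chain(mix, spec.overlays, conditions, params)


def make_full_ddm(n_coherence_levels: int = 6) -> ZooEntry:
    """The 'full DDM': per-level drifts plus across-trial variability (11 params).

    Variability: drift ~ N(mu_j, s_v^2) (handled by quadrature over
    separate solves), starting point uniform over [-s_z, s_z], non-decision
    time uniform over [t_nd - s_T, t_nd + s_T].  Lapse mixture fixed at
    0.95/0.05.
    """
    if n_coherence_levels < 1:
        raise ValueError("need at least one coherence level")
    drifts = {k: v for k, v in list(_default_level_drifts().items())[:n_coherence_levels]}
    params = ParameterSet(
        **drifts,
        B0=Parameter(1.0, 0.3, 3.0),
        t_nd=Parameter(0.2, 0.0, 1.0),
        s_v=Parameter(0.5, 0.0, 5.0),
        s_z=Parameter(0.1, 0.0, 0.29),
        s_T=Parameter(0.05, 0.0, 0.19),
    )
    spec = GDDMSpec(
        name="full_ddm",
        drift=Drift(_per_level_drift),
        bound=Bound(lambda t, c, p: p["B0"]),
        ic=InitialCondition(_uniform_start_ic, kind="uniform"),
        overlays=(NonDecisionOverlay(t_nd="t_nd", width="s_T"),
                  UniformMixtureOverlay(w=LAPSE_MIX_W)),
        params=params,
        required_conditions=("coherence_level",),
    )
    return ZooEntry("full_ddm", spec, n_coherence_levels + 5,
                    ("coherence_level",),
                    "classic DDM with across-trial variability",
                    _solver=_solve_drift_mixture)


def make_ddm_per_level_drift(n_coherence_levels: int = 6) -> ZooEntry:
    """Per-coherence-level drifts with shared bound and t_nd (8 parameters)."""
    if n_coherence_levels < 1:
        raise ValueError("need at least one coherence level")
    drifts = {k: v for k, v in list(_default_level_drifts().items())[:n_coherence_levels]}
    params = ParameterSet(
        **drifts,
        B0=Parameter(1.0, 0.3, 3.0),
        t_nd=Parameter(0.2, 0.0, 1.0),
    )
    spec = GDDMSpec(
        name="ddm_per_level_drift",
        drift=Drift(_per_level_drift),
        bound=Bound(lambda t, c, p: p["B0"]),
        overlays=(NonDecisionOverlay(t_nd="t_nd"),
                  UniformMixtureOverlay(w=LAPSE_MIX_W)),
        params=params,
        required_conditions=("coherence_level",),
    )
    return ZooEntry("ddm_per_level_drift", spec, n_coherence_levels + 2,
                    ("coherence_level",), "per-level drift DDM")


def make_ddm_per_condition(n_coherence_levels: int = 6) -> ZooEntry:
    """Independent (mu_j, B_j, t_nd_j) triples per coherence level (18 params).

    Each level is its own 3-parameter constant-coefficient DDM; no lapse
    mixture is included.
    """
    if n_coherence_levels < 1:
        raise ValueError("need at least one coherence level")
    entries: dict[str, Parameter] = {}
    for j, v in enumerate([0.0, 0.32, 0.64, 1.28, 2.56, 5.12][:n_coherence_levels]):
        entries[f"mu{j}"] = Parameter(v, -40.0, 40.0)
        entries[f"B{j}"] = Parameter(1.0, 0.3, 3.0)
        entries[f"t_nd{j}"] = Parameter(0.2, 0.0, 1.0)
    params = ParameterSet(**entries)

    def bound(t, cond, p):
        return p[f"B{int(cond['coherence_level'])}"]

    spec = GDDMSpec(
        name="ddm_per_condition",
        drift=Drift(_per_level_drift),
        bound=Bound(bound),
        overlays=(NonDecisionOverlay(
            t_nd=lambda cond, p: p[f"t_nd{int(cond['coherence_level'])}"]),),
        params=params,
        required_conditions=("coherence_level",),
    )
    return ZooEntry("ddm_per_condition", spec, 3 * n_coherence_levels,
                    ("coherence_level",), "independent DDM per coherence level")


def make_benchmark() -> ZooEntry:
    """Constant-coefficient accuracy benchmark: mu=2, sigma=1.5, B=1, 2 s."""
    spec = GDDMSpec(
        name="benchmark_constant",
        drift=Drift(lambda x, t, c, p: 2.0),
        noise=Noise(lambda x, t, c, p: 1.5),
    )
    return ZooEntry("benchmark_constant", spec, 0, (),
                    "closed-form-checkable constant DDM")


def make_coherence_scan() -> ZooEntry:
    """Condition-parallel benchmark: drift 2C, unit noise, unit bounds."""
    spec = GDDMSpec(
        name="coherence_scan",
        drift=Drift(lambda x, t, c, p: 2.0 * c["coherence"]),
        required_conditions=("coherence",),
    )
    return ZooEntry("coherence_scan", spec, 0, ("coherence",),
                    "64-coherence parallel solving benchmark")


REGISTRY: dict[str, Callable[..., ZooEntry]] = {
    "gddm_leak_collapse": make_gddm,
    "ddm": make_ddm,
    "full_ddm": make_full_ddm,
    "ddm_per_level_drift": make_ddm_per_level_drift,
    "ddm_per_condition": make_ddm_per_condition,
    "benchmark_constant": make_benchmark,
    "coherence_scan": make_coherence_scan,
}


def get_model(name: str, **kwargs) -> ZooEntry:
    try:
        ctor = REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: "
                       f"{', '.join(sorted(REGISTRY))}") from None
    return ctor(**kwargs)
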