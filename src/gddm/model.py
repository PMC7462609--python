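"""Core model description for generalized drift-diffusion models (GDDMs).

A GDDM is a first-passage problem for the stochastic process

    dx = mu(x, t, ...) dt + sigma(x, t, ...) dW,

started from a distribution ``X0`` and absorbed at symmetric bounds
``+/- B(t, ...)``, where ``...`` stands for task conditions (e.g. stimulus
coherence) and named fittable parameters.  The model is composed of five
components -- drift, noise, bound, initial condition and an overlay chain --
each an arbitrary function of position, time, conditions and parameters.
The upper bound is labelled "correct" and the lower bound "error".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Conditions",
    "Parameter",
    "ParameterSet",
    "Drift",
    "Noise",
    "Bound",
    "InitialCondition",
    "GDDMSpec",
    "Violation",
    "MissingConditionError",
    "evaluate_components",
    "validate_model",
]

#: Task conditions: a plain name -> value mapping (e.g. {"coherence": 0.256}).
Conditions = Mapping[str, float]


class MissingConditionError(KeyError):
    """A component requested a task condition absent from the mapping."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"required task condition {self.name!r} was not provided"


@dataclass(frozen=True)
class Parameter:
    """A named fittable quantity with box constraints used by optimizers."""

    value: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self):
        if not self.lo <= self.value <= self.hi:
            raise ValueError(
                f"parameter value {self.value} outside bounds [{self.lo}, {self.hi}]"
            )


class ParameterSet(Mapping[str, float]):
    """Named fittable parameters with per-name box constraints.

    Behaves as a read-only mapping from name to *value*; the full
    :class:`Parameter` records (with bounds) are available via
    :meth:`parameter`.  Names are unique by construction.
    """

    def __init__(self, **params: Parameter | float | tuple):
        self._params: dict[str, Parameter] = {}
        for name, p in params.items():
            if isinstance(p, Parameter):
                self._params[name] = p
            elif isinstance(p, tuple):
                self._params[name] = Parameter(*p)
            else:
                self._params[name] = Parameter(float(p))

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self._params[name].value
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v.value:g}" for k, v in self._params.items())
        return f"ParameterSet({inner})"

    # Extras -----------------------------------------------------------
    def parameter(self, name: str) -> Parameter:
        return self._params[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._params)

    def values_vector(self) -> np.ndarray:
        return np.array([p.value for p in self._params.values()], dtype=float)

    def bounds_list(self) -> list[tuple[float, float]]:
        return [(p.lo, p.hi) for p in self._params.values()]

    def with_values(self, values: Sequence[float]) -> "ParameterSet":
        """A copy with the same names/bounds and new values (optimizer hook)."""
        values = list(values)
        if len(values) != len(self._params):
            raise ValueError("value vector length does not match parameter count")
        new = ParameterSet()
        for (name, p), v in zip(self._params.items(), values):
            new._params[name] = Parameter(float(v), p.lo, p.hi)
        return new

    def in_bounds(self) -> bool:
        return all(p.lo <= p.value <= p.hi for p in self._params.values())


@dataclass(frozen=True)
class Drift:
    """Instantaneous drift rate mu(x, t, conditions, params).

    ``fn`` receives a position array ``x`` (position units), scalar time ``t``
    (seconds), the conditions mapping and the :class:`ParameterSet`, and
    returns drift in position units per second, broadcastable against ``x``.
    The default is zero drift.  The dependence flags are declared by the
    model author and spot-checked during validation, not inferred.
    """

    fn: Callable | None = None
    x_dependent: bool = False
    t_dependent: bool = False

    def __call__(self, x, t, conditions: Conditions, params: ParameterSet):
        if self.fn is None:
            return np.zeros_like(np.asarray(x, dtype=float))
        out = self.fn(x, t, conditions, params)
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(x)).copy() \
            if np.shape(out) != np.shape(x) else np.asarray(out, dtype=float)


@dataclass(frozen=True)
class Noise:
    """Instantaneous noise sigma(x, t, conditions, params) > 0.

    Units: position / sqrt(second).  The diffusion coefficient used by the
    Fokker-Planck solvers is D = sigma**2 / 2.  Defaults to 1.
    """

    fn: Callable | None = None
    x_dependent: bool = False
    t_dependent: bool = False

    def __call__(self, x, t, conditions: Conditions, params: ParameterSet):
        if self.fn is None:
            return np.ones_like(np.asarray(x, dtype=float))
        out = self.fn(x, t, conditions, params)
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(x)).copy() \
            if np.shape(out) != np.shape(x) else np.asarray(out, dtype=float)


@dataclass(frozen=True)
class Bound:
    """Symmetric absorbing bound B(t, conditions, params) > 0 at +/- B."""

    fn: Callable | None = None
    t_dependent: bool = False

    def __call__(self, t: float, conditions: Conditions, params: ParameterSet) -> float:
        if self.fn is None:
            return 1.0
        return float(self.fn(t, conditions, params))


@dataclass(frozen=True)
class InitialCondition:
    """Starting distribution X0 over the interior grid points.

    ``fn`` receives the interior grid positions (1-D array), conditions and
    parameters and returns per-point probability masses summing to 1 with
    support strictly inside (-B(0), B(0)).  The default is a point mass at
    x = 0 (``kind`` = "point_mass_center"), which is what makes a model
    eligible for the closed-form solver.
    """

    fn: Callable | None = None
    kind: str = "point_mass_center"

    def __call__(self, x_grid: np.ndarray, conditions: Conditions,
                 params: ParameterSet) -> np.ndarray:
        if self.fn is None:
            masses = np.zeros_like(x_grid)
            i0 = int(np.argmin(np.abs(x_grid)))
            masses[i0] = 1.0
            return masses
        return np.asarray(self.fn(x_grid, conditions, params), dtype=float)


@dataclass(frozen=True)
class GDDMSpec:
    """A GDDM: five components, fittable parameters and required conditions.

    ``overlays`` is a chain of post-processing transforms (non-decision time,
    lapse mixtures; see :mod:`gddm.overlays`) applied, in order, to the
    solved first-passage distribution.
    """

    name: str = "gddm"
    drift: Drift = field(default_factory=Drift)
    noise: Noise = field(default_factory=Noise)
    bound: Bound = field(default_factory=Bound)
    ic: InitialCondition = field(default_factory=InitialCondition)
    overlays: tuple = ()
    params: ParameterSet = field(default_factory=ParameterSet)
    required_conditions: tuple[str, ...] = ()

    def with_params(self, params: ParameterSet) -> "GDDMSpec":
        return replace(self, params=params)

    def check_conditions(self, conditions: Conditions) -> None:
        for name in self.required_conditions:
            if name not in conditions:
                raise MissingConditionError(name)


def evaluate_components(spec: GDDMSpec, x, t: float, conditions: Conditions,
                        params: ParameterSet | None = None):
    """Evaluate (mu, sigma, B) at position(s) ``x`` and time ``t``.

    Pure and repeatable; raises :class:`MissingConditionError` naming any
    absent required condition.
    """
    spec.check_conditions(conditions)
    params = spec.params if params is None else params
    mu = spec.drift(x, t, conditions, params)
    sigma = spec.noise(x, t, conditions, params)
    B = spec.bound(t, conditions, params)
    return mu, sigma, B


@dataclass(frozen=True)
class Violation:
    """One validation failure: which component, where, and which rule."""

    component: str
    location: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.component}] {self.rule} at {self.location}: {self.message}"


def _probe_times(t_dur: float) -> np.ndarray:
    return np.array([0.0, 0.25 * t_dur, 0.5 * t_dur, 0.75 * t_dur, t_dur])


def validate_model(spec: GDDMSpec, grid, conditions: Conditions,
                   params: ParameterSet | None = None) -> list[Violation]:
    """Check model invariants on a grid; return violation records.

    Sampled rules: noise strictly positive and finite; drift finite; bound
    strictly positive for all t in [0, t_dur]; initial condition nonnegative,
    summing to 1 within 1e-12, supported strictly inside (-B(0), B(0));
    dependence flags consistent with the evaluators (spot-checked at random
    positions).  Evaluators that raise or return non-finite values produce a
    violation record rather than a crash.
    """
    params = spec.params if params is None else params
    out: list[Violation] = []
    try:
        spec.check_conditions(conditions)
    except MissingConditionError as e:
        return [Violation("spec", "conditions", "required-condition", str(e))]
    if not params.in_bounds():
        out.append(Violation("params", "parameter_set", "within-bounds",
                             "a parameter value lies outside its fitting bounds"))

    x = np.asarray(grid.x, dtype=float)
    times = _probe_times(grid.t_dur)

    # Bound positivity over time
    for t in times:
        try:
            B = spec.bound(t, conditions, params)
        except Exception as e:  # noqa: BLE001 - report, don't crash
            out.append(Violation("bound", f"t={t:g}", "evaluator-error", repr(e)))
            continue
        if not np.isfinite(B):
            out.append(Violation("bound", f"t={t:g}", "finite", f"B={B!r}"))
        elif B <= 0:
            out.append(Violation("bound", f"t={t:g}", "bound-positivity",
                                 f"B(t)={B:g} <= 0"))

    # Drift finiteness / noise positivity over the sampled grid
    for t in times:
        try:
            mu = spec.drift(x, t, conditions, params)
        except Exception as e:  # noqa: BLE001
            out.append(Violation("drift", f"t={t:g}", "evaluator-error", repr(e)))
        else:
            if not np.all(np.isfinite(mu)):
                j = int(np.argmax(~np.isfinite(np.atleast_1d(mu))))
                out.append(Violation("drift", f"x={x[j]:g}, t={t:g}", "finite",
                                     "drift evaluator returned a non-finite value"))
        try:
            sig = spec.noise(x, t, conditions, params)
        except Exception as e:  # noqa: BLE001
            out.append(Violation("noise", f"t={t:g}", "evaluator-error", repr(e)))
        else:
            sig = np.atleast_1d(sig)
            if not np.all(np.isfinite(sig)):
                j = int(np.argmax(~np.isfinite(sig)))
                out.append(Violation("noise", f"x={x[j]:g}, t={t:g}", "finite",
                                     "noise evaluator returned a non-finite value"))
            elif np.any(sig <= 0):
                j = int(np.argmax(sig <= 0))
                out.append(Violation("noise", f"x={x[j]:g}, t={t:g}",
                                     "noise-positivity",
                                     f"sigma={float(sig[j]):g} <= 0"))

    # Initial condition
    try:
        B0 = spec.bound(0.0, conditions, params)
        x0 = spec.ic(x, conditions, params)
    except Exception as e:  # noqa: BLE001
        out.append(Violation("ic", "t=0", "evaluator-error", repr(e)))
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != x.shape:
            out.append(Violation("ic", "t=0", "shape",
                                 f"expected {x.shape}, got {x0.shape}"))
        else:
            if np.any(x0 < 0):
                j = int(np.argmax(x0 < 0))
                out.append(Violation("ic", f"x={x[j]:g}", "nonnegativity",
                                     f"mass {x0[j]:g} < 0"))
            if abs(float(x0.sum()) - 1.0) > 1e-12:
                out.append(Violation("ic", "t=0", "normalization",
                                     f"masses sum to {float(x0.sum()):.15g}, not 1"))
            if np.isfinite(B0) and B0 > 0:
                outside = (np.abs(x) >= B0) & (x0 > 0)
                if np.any(outside):
                    j = int(np.argmax(outside))
                    out.append(Violation(
                        "ic", f"x={x[j]:g}", "support-inside-bounds",
                        f"initial mass at |x| >= B(0)={B0:g}"))

    # Spot-check declared x-independence (5 random probes per t)
    rng = np.random.default_rng(0)
    probes = rng.uniform(x.min(), x.max(), size=5) if x.size > 1 else x
    for comp_name, comp in (("drift", spec.drift), ("noise", spec.noise)):
        if comp.x_dependent or comp.fn is None:
            continue
        for t in times:
            try:
                vals = np.atleast_1d(comp(probes, t, conditions, params))
            except Exception:  # noqa: BLE001 - already reported above
                break
            if not np.all(np.isfinite(vals)):
                break  # non-finiteness already reported above
            if np.ptp(vals) > 1e-10 * max(1.0, np.max(np.abs(vals))):
                out.append(Violation(comp_name, f"t={t:g}", "flag-consistency",
                                     "declared x-independent but varies with x"))
                break
    if not spec.bound.t_dependent and spec.bound.fn is not None:
        Bs = [spec.bound(t, conditions, params) for t in times]
        if np.isfinite(Bs).all() and np.ptp(Bs) > 1e-10 * max(1.0, max(map(abs, Bs))):
            out.append(Violation("bound", "t-sweep", "flag-consistency",
                                 "declared t-independent but varies with t"))
    return out
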