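"""Full-distribution maximum-likelihood fitting of GDDMs to choice/RT data.

The likelihood of a trial (choice, rt) is the model's per-second RT density
for that choice at that rt, read off the solved distribution (one solve per
distinct task-condition combination, cached per objective evaluation).
Undecided model mass is treated as censoring: it lowers the decided density
but is not renormalized away.  A lapse-mixture overlay keeps the likelihood
finite for outlier RTs; without one, a zero-density trial is an error
rather than a silent -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import GDDMSpec, ParameterSet
from .overlays import UniformMixtureOverlay
from .solution import SolutionPDF
from . import solver

__all__ = ["RTDataset", "FitResult", "negative_log_likelihood",
           "mse_objective", "bic", "fit"]


class RTDataset:
    """Trials of (rt seconds, choice in {1 upper, 0 lower}, conditions).

    Thin wrapper over a DataFrame with required columns ``rt`` and
    ``choice``; every other column is a task condition.
    """

    def __init__(self, df: pd.DataFrame):
        for col in ("rt", "choice"):
            if col not in df.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        rt = pd.to_numeric(df["rt"], errors="coerce")
        if rt.isna().any():
            row = int(np.flatnonzero(rt.isna())[0])
            raise ValueError(f"non-numeric rt in row {row}")
        if (rt <= 0).any():
            row = int(np.flatnonzero(rt <= 0)[0])
            raise ValueError(f"rt must be positive; row {row} has rt={rt.iloc[row]}")
        ch = df["choice"]
        if not ch.isin([0, 1]).all():
            row = int(np.flatnonzero(~ch.isin([0, 1]))[0])
            raise ValueError(f"choice must be 0 (lower) or 1 (upper); row {row} "
                             f"has {ch.iloc[row]!r}")
        self.df = df.reset_index(drop=True).copy()
        self.df["rt"] = rt.astype(float).values
        self.df["choice"] = ch.astype(int).values

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c not in ("rt", "choice"))

    def condition_combinations(self) -> list[dict]:
        names = list(self.condition_names)
        if not names:
            return [{}]
        combos = self.df[names].drop_duplicates().sort_values(names)
        return [dict(zip(names, row)) for row in combos.itertuples(index=False)]

    def trials_for(self, conditions: dict) -> pd.DataFrame:
        mask = np.ones(self.n, dtype=bool)
        for k, v in conditions.items():
            mask &= (self.df[k] == v).values
        return self.df[mask]

    def max_rt(self) -> float:
        return float(self.df["rt"].max())


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    nll: float
    bic: float
    objective: str
    objective_value: float
    optimizer: str
    seed: int
    n_evals: int
    n_trials: int
    meta: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [f"fit of {self.meta.get('model', 'model')}: "
                 f"{self.objective}={self.objective_value:.6g} "
                 f"(nll={self.nll:.6g}, BIC={self.bic:.6g}, "
                 f"k={len(self.params)}, n={self.n_trials})"]
        for name in self.params.names:
            lines.append(f"  {name} = {self.params[name]:.6g}")
        return "\n".join(lines)


def _model_parts(model):
    """Accept either a GDDMSpec or a model-zoo entry."""
    if isinstance(model, GDDMSpec):
        return model, None
    return model.spec, model  # ZooEntry-like: has .spec and .solve


def _solve_model(model, conditions, params, dx, dt, t_dur, method):
    spec, entry = _model_parts(model)
    if entry is not None:
        return entry.solve(conditions, params=params, dx=dx, dt=dt,
                           t_dur=t_dur, method=method)
    return solver.solve(spec, conditions, dx=dx, dt=dt, t_dur=t_dur,
                        method=method, params=params)


def _condition_key(conditions: dict) -> tuple:
    return tuple(sorted(conditions.items()))


def _has_mixture(spec: GDDMSpec) -> bool:
    return any(isinstance(ov, UniformMixtureOverlay) for ov in spec.overlays)


def _trial_density(solution: SolutionPDF, rts: np.ndarray,
                   choices: np.ndarray, interpolate: bool = True) -> np.ndarray:
    """Per-second model density at each observed (choice, rt).

    Bin masses define densities mass/dt at bin midpoints; by default the
    density at an observed rt is linearly interpolated between adjacent
    midpoints (clamped at the edges); ``interpolate=False`` uses the
    nearest bin instead.
    """
    mids = solution.t_bin_mids
    dens = np.empty(rts.size)
    for code, arr in ((1, solution.density_upper()), (0, solution.density_lower())):
        sel = choices == code
        if not np.any(sel):
            continue
        if interpolate:
            dens[sel] = np.interp(rts[sel], mids, arr)
        else:
            idx = np.clip((rts[sel] / solution.dt).astype(int), 0,
                          solution.n_bins - 1)
            dens[sel] = arr[idx]
    return dens


def negative_log_likelihood(model, dataset: RTDataset, dx: float = 0.005,
                            dt: float = 0.005, t_dur: float = 2.0,
                            params: ParameterSet | None = None,
                            method: str = "auto", interpolate: bool = True,
                            _cache: dict | None = None) -> float:
    """-sum_i log f(choice_i, rt_i) under the model's solved distributions."""
    spec, _ = _model_parts(model)
    params = spec.params if params is None else params
    if dataset.max_rt() > t_dur + 1e-9:
        raise ValueError(f"dataset contains rt > t_dur = {t_dur}s; "
                         "increase the fitting duration")
    nll = 0.0
    for conditions in dataset.condition_combinations():
        key = _condition_key(conditions)
        if _cache is not None and key in _cache:
            sol = _cache[key]
        else:
            sol = _solve_model(model, conditions, params, dx, dt, t_dur, method)
            if _cache is not None:
                _cache[key] = sol
        trials = dataset.trials_for(conditions)
        dens = _trial_density(sol, trials["rt"].values,
                              trials["choice"].values, interpolate)
        if np.any(dens <= 0.0):
            if _has_mixture(spec):
                # overlay floor exists but interpolation can still touch 0 at
                # the first bin edge; fall back to the lapse floor density
                floor = np.min(np.concatenate([sol.density_upper(),
                                               sol.density_lower()]))
                dens = np.maximum(dens, max(floor, 1e-300))
            else:
                bad = trials.iloc[int(np.argmax(dens <= 0.0))]
                raise ValueError(
                    f"zero model density at rt={bad['rt']:g}s, "
                    f"choice={int(bad['choice'])} with no lapse mixture; the "
                    "likelihood is overly sensitive to outliers -- add a "
                    "mixture overlay")
        nll -= float(np.log(dens).sum())
    return nll


def mse_objective(model, dataset: RTDataset, dt_bin: float = 0.02,
                  dx: float = 0.005, dt: float = 0.005, t_dur: float = 2.0,
                  params: ParameterSet | None = None, method: str = "auto",
                  _cache: dict | None = None) -> float:
    """Mean squared per-bin mass error between model and empirical histograms.

    For each condition combination and choice, the empirical histogram on
    bins of dt_bin (counts / condition trial count) is compared with the
    model masses rebinned to dt_bin; the mean square is taken over all
    bins, conditions and choices.
    """
    spec, _ = _model_parts(model)
    params = spec.params if params is None else params
    n_bins = int(round(t_dur / dt_bin))
    errs = []
    for conditions in dataset.condition_combinations():
        key = _condition_key(conditions)
        if _cache is not None and key in _cache:
            sol = _cache[key]
        else:
            sol = _solve_model(model, conditions, params, dx, dt, t_dur, method)
            if _cache is not None:
                _cache[key] = sol
        ratio = int(round(dt_bin / sol.dt))
        if abs(ratio * sol.dt - dt_bin) > 1e-9:
            raise ValueError("dt_bin must be a multiple of the solver dt")
        trials = dataset.trials_for(conditions)
        n_cond = len(trials)
        edges = dt_bin * np.arange(n_bins + 1)
        for code, masses in ((1, sol.upper), (0, sol.lower)):
            model_bins = masses[: n_bins * ratio].reshape(n_bins, ratio).sum(axis=1)
            rts = trials.loc[trials["choice"] == code, "rt"].values
            emp, _ = np.histogram(np.clip(rts - 1e-12, 0.0, None), bins=edges)
            errs.append((model_bins - emp / n_cond) ** 2)
    return float(np.mean(np.concatenate(errs)))


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion: k ln(n) + 2 nll."""
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return k * math.log(n) + 2.0 * nll


def fit(model, dataset: RTDataset, objective: str = "nll",
        optimizer: str = "differential_evolution", seed: int = 0,
        dx: float = 0.005, dt: float = 0.005, t_dur: float = 2.0,
        method: str = "auto", maxiter: int = 100, tol: float = 1e-3,
        dt_bin: float = 0.02) -> FitResult:
    """Fit all declared parameters of a model to an RT dataset.

    ``objective`` is "nll" (full-distribution likelihood) or "mse";
    ``optimizer`` is "differential_evolution" (global; requires finite
    bounds on every parameter) or "nelder_mead" (local, started from the
    declared values and restarted once from the best point).  Results are
    deterministic given ``seed``.
    """
    spec, _ = _model_parts(model)
    base = spec.params
    names = base.names
    if not names:
        raise ValueError("model declares no fittable parameters")
    bounds = base.bounds_list()
    n_evals = 0

    def objective_fn(vec) -> float:
        nonlocal n_evals
        n_evals += 1
        vec = np.clip(vec, [b[0] for b in bounds], [b[1] for b in bounds])
        p = base.with_values(vec)
        cache: dict = {}
        try:
            if objective == "nll":
                return negative_log_likelihood(model, dataset, dx, dt, t_dur,
                                               params=p, method=method,
                                               _cache=cache)
            if objective == "mse":
                return mse_objective(model, dataset, dt_bin, dx, dt, t_dur,
                                     params=p, method=method, _cache=cache)
            raise ValueError(f"unknown objective {objective!r}")
        except (solver.NumericalError, ValueError):
            return 1e100  # infeasible corner of the parameter box

    if optimizer == "differential_evolution":
        if not all(np.isfinite(lo) and np.isfinite(hi) for lo, hi in bounds):
            raise ValueError("differential evolution requires finite bounds "
                             "on every fittable parameter")
        res = optimize.differential_evolution(
            objective_fn, bounds, seed=seed, maxiter=maxiter, tol=tol,
            polish=True)
        best_vec, best_val = res.x, float(res.fun)
    elif optimizer == "nelder_mead":
        x0 = base.values_vector()
        res = optimize.minimize(objective_fn, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter * max(1, len(names)),
                                         "xatol": 1e-4, "fatol": tol})
        res2 = optimize.minimize(objective_fn, res.x, method="Nelder-Mead",
                                 options={"maxiter": maxiter * max(1, len(names)),
                                          "xatol": 1e-4, "fatol": tol})
        best_vec, best_val = res2.x, float(res2.fun)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    if not np.isfinite(best_val) or best_val >= 1e100:
        raise RuntimeError("objective was non-finite at every evaluated point; "
                           "check parameter bounds and numerics")
    best_vec = np.clip(best_vec, [b[0] for b in bounds], [b[1] for b in bounds])
    best = base.with_values(best_vec)
    nll = negative_log_likelihood(model, dataset, dx, dt, t_dur, params=best,
                                  method=method, _cache={}) \
        if objective != "nll" else best_val
    return FitResult(params=best, nll=nll, bic=bic(nll, len(names), dataset.n),
                     objective=objective, objective_value=best_val,
                     optimizer=optimizer, seed=seed, n_evals=n_evals,
                     n_trials=dataset.n,
                     meta={"model": spec.name, "dx": dx, "dt": dt,
                           "t_dur": t_dur})
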