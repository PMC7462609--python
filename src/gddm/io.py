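"""File formats, run configuration and the seeded fixture generator.

Formats (all plain delimited text):

* RT dataset: CSV with header; required columns ``rt`` (seconds) and
  ``choice`` (1 = upper/correct, 0 = lower/error); every further column is
  a task condition.
* Solution table: CSV with ``#`` header lines recording method, dx, dt,
  undecided mass and seed, then columns t_bin_end_seconds, mass_upper,
  mass_lower.
* Run configuration: flat YAML mapping; unknown keys are rejected.
* Fit report: ``key: value`` lines (parameters, NLL, BIC, k, n, seed).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, RTDataset
from .model import ParameterSet, Parameter
from .simulate import sample_from_solution
from .solution import SolutionPDF
from .zoo import get_model

__all__ = ["read_rt_dataset", "write_rt_dataset", "sample_to_dataset",
           "write_solution", "read_solution", "RunConfig", "FixtureSpec",
           "generate_fixture", "write_fit_report"]


def read_rt_dataset(path) -> RTDataset:
    """Read a delimited RT dataset; malformed rows are reported by number."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    try:
        return RTDataset(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_rt_dataset(dataset: RTDataset, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        dataset.df.to_csv(fh, index=False)


def sample_to_dataset(sample, conditions: dict | None = None) -> RTDataset:
    """Convert an RTSample's decided trials to an RTDataset (+ condition cols)."""
    decided = sample.choice != -1
    df = pd.DataFrame({"rt": sample.rt[decided],
                       "choice": sample.choice[decided]})
    for name, value in (conditions or {}).items():
        df[name] = value
    return RTDataset(df)


def write_solution(sol: SolutionPDF, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method={sol.method} dx={sol.dx} dt={sol.dt} "
                 f"undecided={sol.undecided:.17g}"
                 + (f" seed={seed}" if seed is not None else "") + "\n")
        pd.DataFrame({"t_bin_end_seconds": sol.t_bin_ends,
                      "mass_upper": sol.upper,
                      "mass_lower": sol.lower}).to_csv(fh, index=False,
                                                       float_format="%.17g")


def read_solution(path) -> SolutionPDF:
    header = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                header[k] = v
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    dt = float(header.get("dt", df["t_bin_end_seconds"].iloc[0]))
    return SolutionPDF(dt=dt, upper=df["mass_upper"].values,
                       lower=df["mass_lower"].values,
                       undecided=float(header.get("undecided", 0.0)),
                       method=header.get("method", "unknown"),
                       dx=float(header["dx"]) if header.get("dx", "None") != "None"
                       else None)


_CONFIG_KEYS = {"model", "model_args", "params", "conditions", "dx", "dt",
                "t_dur", "method", "seed", "output"}


@dataclass
class RunConfig:
    """Flat run configuration for the command-line entry points.

    ``params`` maps parameter names to a value or a [value, lo, hi] triple;
    ``conditions`` maps condition names to values.  Round-trips through
    YAML exactly; unknown keys are rejected on read.
    """

    model: str = "ddm"
    model_args: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    dx: float = 0.005
    dt: float = 0.005
    t_dur: float = 2.0
    method: str = "auto"
    seed: int = 0
    output: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def build_entry(self):
        entry = get_model(self.model, **self.model_args)
        if self.params:
            merged = {}
            for name in entry.spec.params.names:
                p = entry.spec.params.parameter(name)
                merged[name] = p
            for name, v in self.params.items():
                if isinstance(v, (list, tuple)):
                    merged[name] = Parameter(*[float(u) for u in v])
                else:
                    old = merged.get(name)
                    lo, hi = (old.lo, old.hi) if old else (-np.inf, np.inf)
                    merged[name] = Parameter(float(v), lo, hi)
            entry = type(entry)(entry.name,
                                entry.spec.with_params(ParameterSet(**merged)),
                                len(merged), entry.required_conditions,
                                entry.description, entry._solver)
        return entry


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic dataset: generating model, truth, size, seed."""

    model: str = "ddm"
    model_args: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    condition_grid: tuple = ()
    n_per_condition: int = 1000
    seed: int = 0
    dx: float = 0.005
    dt: float = 0.005
    t_dur: float = 2.0


def generate_fixture(fixture: FixtureSpec):
    """Solve the generating model per condition and sample trials from it.

    Returns (RTDataset, truth record).  The truth record holds the
    generating parameter values, per-condition solved choice totals, and
    the seed, for parameter-recovery checks.  Warns (in the record) when
    undecided mass exceeds 0.5 anywhere -- such datasets are heavily
    censored.
    """
    entry = get_model(fixture.model, **fixture.model_args)
    params = entry.spec.params
    if fixture.truth:
        vec = [fixture.truth.get(n, params[n]) for n in params.names]
        params = params.with_values(vec)
    frames = []
    per_condition = {}
    warned = False
    rng = np.random.default_rng(fixture.seed)
    for conditions in fixture.condition_grid or ({},):
        sol = entry.solve(conditions, params=params, dx=fixture.dx,
                          dt=fixture.dt, t_dur=fixture.t_dur)
        if sol.undecided > 0.5:
            warned = True
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample = sample_from_solution(sol, fixture.n_per_condition,
                                      seed=sub_seed)
        frames.append(sample_to_dataset(sample, conditions).df)
        per_condition[str(conditions)] = {
            "prob_upper": sol.prob_upper, "prob_lower": sol.prob_lower,
            "undecided": sol.undecided}
    dataset = RTDataset(pd.concat(frames, ignore_index=True))
    truth = {"model": fixture.model, "model_args": dict(fixture.model_args),
             "params": {n: params[n] for n in params.names},
             "seed": fixture.seed, "n_per_condition": fixture.n_per_condition,
             "per_condition": per_condition,
             "heavily_censored": warned}
    return dataset, truth


def write_fit_report(result: FitResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"model: {result.meta.get('model', '?')}\n")
        fh.write(f"objective: {result.objective}\n")
        fh.write(f"objective_value: {result.objective_value:.12g}\n")
        fh.write(f"nll: {result.nll:.12g}\n")
        fh.write(f"bic: {result.bic:.12g}\n")
        fh.write(f"k: {len(result.params)}\n")
        fh.write(f"n: {result.n_trials}\n")
        fh.write(f"optimizer: {result.optimizer}\n")
        fh.write(f"seed: {result.seed}\n")
        fh.write(f"n_evals: {result.n_evals}\n")
        for name in result.params.names:
            fh.write(f"param {name}: {result.params[name]:.12g}\n")
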