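"""Accuracy sweeps, convergence-order estimation, and parallel solving.

The accuracy methodology: solve a constant-coefficient DDM (which has a
closed-form series solution) over a grid of (dx, dt) settings per scheme,
measure the per-bin MSE against the analytic solution resampled onto the
method's own time grid, and record execution time.  Execution times are
reported but never asserted -- they are hardware facts, not model facts.
The product time x MSE is a tradeoff heuristic only.

Convergence orders are estimated as log-log least-squares slopes of the
RMS error on the *density* scale (bin mass / dt): per-bin masses scale
with dt, so a joint dx = dt sweep on the mass scale would inflate the
slope by one; densities recover the scheme's truncation order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .analytic import solve_analytic
from .model import GDDMSpec
from .simulate import histogram, simulate_trials, smooth_histogram
from .solution import SolutionPDF
from . import solver
from .zoo import ZooEntry, make_benchmark

__all__ = ["SweepRecord", "run_sweep", "tradeoff_product", "convergence_order",
           "parallel_solve", "rms_density_error", "mse_vs_analytic"]


@dataclass(frozen=True)
class SweepRecord:
    method: str
    dx: float | None  # None for trajectory runs
    dt: float
    N: int | None  # trial count for trajectory runs
    mse: float | None  # None when unstable
    rms_density: float | None
    seconds: float
    stable: bool
    meta: dict = field(default_factory=dict)


def _analytic_reference(entry: ZooEntry, dt: float, t_dur: float):
    spec = entry.spec
    mu = float(np.atleast_1d(spec.drift(0.0, 0.0, {}, spec.params))[0])
    sigma = float(np.atleast_1d(spec.noise(0.0, 0.0, {}, spec.params))[0])
    B = spec.bound(0.0, {}, spec.params)
    return solve_analytic(mu, sigma, B, t_dur, dt)


def mse_vs_analytic(sol: SolutionPDF, ref: SolutionPDF) -> float:
    """Per-bin mass MSE over both choices (same time grid required)."""
    if abs(sol.dt - ref.dt) > 1e-12 or sol.n_bins != ref.n_bins:
        raise ValueError("solutions must share their time grid")
    err = np.concatenate([sol.upper - ref.upper, sol.lower - ref.lower])
    return float(np.mean(err**2))


def rms_density_error(sol: SolutionPDF, ref: SolutionPDF) -> float:
    """RMS error of per-second densities over both choices."""
    return float(np.sqrt(mse_vs_analytic(sol, ref))) / sol.dt


def run_sweep(methods=("forward_euler", "backward_euler", "crank_nicolson"),
              dx_list=(0.04, 0.02, 0.01, 0.005), dt_list=None,
              N_list=(1000, 10_000), trajectory_dt=1e-3,
              model: ZooEntry | None = None, t_dur: float = 2.0,
              seed: int = 0) -> list[SweepRecord]:
    """One record per (method, setting) against the analytic oracle.

    Finite-difference methods sweep dx (dt defaults to dx, the empirically
    efficient pairing for the implicit schemes); the "trajectories" method
    sweeps trial counts N at ``trajectory_dt`` and applies the best mean
    filter (an upper bound on smoothing benefit).  Instability is recorded,
    never raised: unstable runs carry ``mse=None``.
    """
    entry = make_benchmark() if model is None else model
    records: list[SweepRecord] = []
    for method in methods:
        if method == "trajectories":
            ref = _analytic_reference(entry, trajectory_dt, t_dur)
            for N in N_list:
                t0 = time.perf_counter()
                sample = simulate_trials(entry.spec, {}, N=N, dt=trajectory_dt,
                                         t_dur=t_dur, seed=seed)
                hu, hl = histogram(sample, trajectory_dt)
                secs = time.perf_counter() - t0
                _, su = smooth_histogram(hu, ref.upper)
                _, sl = smooth_histogram(hl, ref.lower)
                err = np.concatenate([su - ref.upper, sl - ref.lower])
                mse = float(np.mean(err**2))
                records.append(SweepRecord(
                    method="trajectories", dx=None, dt=trajectory_dt, N=N,
                    mse=mse, rms_density=np.sqrt(mse) / trajectory_dt,
                    seconds=secs, stable=True, meta={"seed": seed}))
            continue
        for i, dx in enumerate(dx_list):
            dt = dx if dt_list is None else dt_list[i]
            t0 = time.perf_counter()
            sol = solver.solve(entry.spec, {}, dx=dx, dt=dt, t_dur=t_dur,
                               method=method, verify=False,
                               allow_unstable=True)
            secs = time.perf_counter() - t0
            if sol.meta.get("diverged"):
                records.append(SweepRecord(method=method, dx=dx, dt=dt, N=None,
                                           mse=None, rms_density=None,
                                           seconds=secs, stable=False))
                continue
            ref = _analytic_reference(entry, sol.dt, t_dur)
            mse = mse_vs_analytic(sol, ref)
            records.append(SweepRecord(method=method, dx=sol.dx, dt=sol.dt,
                                       N=None, mse=mse,
                                       rms_density=np.sqrt(mse) / sol.dt,
                                       seconds=secs, stable=True))
    return records


def tradeoff_product(record: SweepRecord) -> float | None:
    """Execution seconds times MSE; the tradeoff heuristic (None if unstable)."""
    if record.mse is None:
        return None
    return record.seconds * record.mse


def convergence_order(step_sizes, errors) -> float:
    """Least-squares slope of log(error) versus log(step size).

    Feed RMS errors so the slope estimates the error order itself (an MSE
    would double it).  Requires at least three step sizes and strictly
    positive errors.
    """
    step_sizes = np.asarray(step_sizes, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if step_sizes.size < 3:
        raise ValueError("need at least 3 step sizes for a slope estimate")
    if np.any(errors <= 0) or np.any(step_sizes <= 0):
        raise ValueError("step sizes and errors must be strictly positive")
    return float(np.polyfit(np.log(step_sizes), np.log(errors), 1)[0])


def _solve_one(spec: GDDMSpec, conditions, kwargs):
    try:
        return solver.solve(spec, conditions, **kwargs)
    except Exception as e:  # noqa: BLE001 - surface the originating condition
        raise RuntimeError(f"solve failed for conditions {conditions!r}: {e}") \
            from e


def parallel_solve(model: GDDMSpec | ZooEntry, condition_list, n_workers: int = 1,
                   **solve_kwargs) -> list[SolutionPDF]:
    """Solve independent conditions, optionally across worker processes.

    Embarrassingly parallel over conditions; outputs are returned in input
    order and are bitwise identical for any worker count (each condition's
    arithmetic is unaffected by scheduling).
    """
    spec = model.spec if isinstance(model, ZooEntry) else model
    if n_workers == 1:
        return [_solve_one(spec, c, solve_kwargs) for c in condition_list]
    return Parallel(n_jobs=n_workers)(
        delayed(_solve_one)(spec, c, solve_kwargs) for c in condition_list)


def plot_tradeoff(records, path):  # pragma: no cover - plotting convenience
    """Log-log execution-time vs error curves per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    methods = sorted({r.method for r in records})
    for m in methods:
        pts = [(r.seconds, r.mse) for r in records if r.method == m and r.stable]
        if not pts:
            continue
        pts.sort()
        ax.loglog([p[0] for p in pts], [p[1] for p in pts], "o-", label=m)
    ax.set_xlabel("execution time (s)")
    ax.set_ylabel("MSE vs analytic solution")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
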