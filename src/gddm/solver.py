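"""Finite-difference Fokker-Planck solvers for GDDM first-passage problems.

The decision-variable density evolves under

    dP/dt = -d/dx (mu P) + d^2/dx^2 (D P),       D = sigma^2 / 2,

with absorbing boundaries at +/- B(t).  Discretizing on interior grid points
{-B0+dx, ..., 0, ..., B0-dx} with centered differences gives the one-step
update in unified matrix form

    (I + (1-alpha) M) P^n = (I - alpha M) P^(n-1)

where M is tridiagonal with row j: main diagonal 2*nu_j, super-diagonal
-nu_(j+1) + chi_(j+1)/2 and sub-diagonal -nu_(j-1) - chi_(j-1)/2, built from
the unitless coefficients nu = D dt/dx^2 and chi = mu dt/dx.  alpha = 1 is
the explicit forward Euler scheme (stable only for D dt/dx^2 < 1/2), alpha =
0 backward Euler, alpha = 1/2 Crank-Nicolson.

Per-step exit masses ("fluxes") through each bound follow from the column
sums of M, so that total probability is conserved identically:

    flux_upper = (nu + chi/2) at x =  B-dx, applied to alpha*P_old + (1-alpha)*P_new
    flux_lower = (nu - chi/2) at x = -B+dx, likewise.

Time-varying bounds are handled (backward Euler only) by propagating on an
inner and an outer grid system bracketing the current bound position and
combining the two solutions with linear interpolation weights; mass stranded
outside a shrinking bound is routed to the corresponding flux.

Crank-Nicolson started from a point mass rings (the classic oscillation of
the scheme for non-smooth data), so its first two steps are each taken as
two half-step backward-Euler updates (Rannacher startup), which restores
smooth, nonnegative solutions while keeping second-order accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .analytic import check_analytic_eligibility, solve_analytic
from .model import Conditions, GDDMSpec, ParameterSet, validate_model
from .overlays import apply_overlay_chain
from .solution import SolutionPDF

__all__ = [
    "Grid",
    "TridiagonalOperator",
    "SCHEME_ALPHA",
    "NumericalError",
    "StabilityError",
    "build_grid",
    "build_operator",
    "check_forward_stability",
    "step",
    "extract_flux",
    "select_method",
    "solve",
]

#: Scheme-weight alpha by method name (the only admissible values).
SCHEME_ALPHA = {"forward_euler": 1.0, "backward_euler": 0.0, "crank_nicolson": 0.5}

#: Verification tolerance for negative state entries, per scheme.  CN keeps a
#: small allowance for residual startup ringing after Rannacher smoothing.
_NEG_TOL = {"forward_euler": 1e-12, "backward_euler": 1e-12, "crank_nicolson": 1e-5}

_ONGRID_RTOL = 1e-12  # bound counts as "on a grid point" within 1e-12 * dx


class NumericalError(RuntimeError):
    pass


class StabilityError(NumericalError):
    pass


@dataclass(frozen=True)
class Grid:
    """Spatial/temporal discretization of the solve domain.

    The requested dx is shrunk to the largest value such that 2*B(0)/dx is
    an even integer, guaranteeing a grid point at x = 0 (where the default
    point-mass initial condition lives); dt is shrunk so it divides t_dur.
    """

    dx: float
    dt: float
    t_dur: float
    x: np.ndarray
    n_steps: int
    B0: float
    requested_dx: float
    requested_dt: float

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def center_index(self) -> int:
        return self.x.size // 2

    @property
    def half_points(self) -> int:
        """Number of grid intervals from 0 to B0 (interior indices run to this - 1)."""
        return self.x.size // 2 + 1


def build_grid(spec: GDDMSpec, conditions: Conditions, dx: float, dt: float,
               t_dur: float, params: ParameterSet | None = None) -> Grid:
    if dx <= 0 or dt <= 0 or t_dur <= 0:
        raise ValueError("dx, dt and t_dur must be positive")
    params = spec.params if params is None else params
    B0 = spec.bound(0.0, conditions, params)
    if not np.isfinite(B0) or B0 <= 0:
        raise ValueError(f"B(0) = {B0!r} must be positive and finite")
    # largest dx' <= dx with B0/dx' integer (so 2 B0/dx' is even and 0 on-grid)
    n_half = int(np.ceil(B0 / dx - 1e-12))
    dx_eff = B0 / n_half
    x = dx_eff * np.arange(-(n_half - 1), n_half)
    n_steps = int(np.ceil(t_dur / dt - 1e-9))
    dt_eff = t_dur / n_steps
    return Grid(dx=dx_eff, dt=dt_eff, t_dur=t_dur, x=x, n_steps=n_steps,
                B0=B0, requested_dx=dx, requested_dt=dt)


@dataclass(frozen=True)
class TridiagonalOperator:
    """Per-point coefficients nu_j = D_j dt/dx^2 and chi_j = mu_j dt/dx."""

    nu: np.ndarray
    chi: np.ndarray

    def __post_init__(self):
        if self.nu.shape != self.chi.shape or self.nu.ndim != 1:
            raise ValueError("nu and chi must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.nu.size

    def apply(self, P: np.ndarray) -> np.ndarray:
        """M @ P for the tridiagonal operator."""
        out = 2.0 * self.nu * P
        out[:-1] += (-self.nu[1:] + 0.5 * self.chi[1:]) * P[1:]
        out[1:] += (-self.nu[:-1] - 0.5 * self.chi[:-1]) * P[:-1]
        return out

    def lhs_banded(self, alpha: float) -> np.ndarray:
        """(I + (1-alpha) M) in scipy solve_banded (1, 1) layout."""
        w = 1.0 - alpha
        ab = np.zeros((3, self.n))
        ab[0, 1:] = w * (-self.nu[1:] + 0.5 * self.chi[1:])
        ab[1, :] = 1.0 + w * 2.0 * self.nu
        ab[2, :-1] = w * (-self.nu[:-1] - 0.5 * self.chi[:-1])
        return ab

    def restrict(self, sl: slice) -> "TridiagonalOperator":
        return TridiagonalOperator(self.nu[sl], self.chi[sl])


def _coefficients(spec, x: np.ndarray, t: float, conditions, params,
                  dt: float, dx: float) -> TridiagonalOperator:
    mu = np.atleast_1d(spec.drift(x, t, conditions, params)).astype(float)
    sigma = np.atleast_1d(spec.noise(x, t, conditions, params)).astype(float)
    if mu.size == 1:
        mu = np.full(x.size, mu[0])
    if sigma.size == 1:
        sigma = np.full(x.size, sigma[0])
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        bad = np.flatnonzero(~(np.isfinite(mu) & np.isfinite(sigma)))[0]
        raise NumericalError(f"non-finite drift/noise at x={x[bad]:g}, t={t:g}")
    D = 0.5 * sigma**2
    return TridiagonalOperator(nu=D * dt / dx**2, chi=mu * dt / dx)


def build_operator(spec: GDDMSpec, grid: Grid, conditions: Conditions,
                   params: ParameterSet | None = None, n: int = 0,
                   t: float | None = None,
                   dt: float | None = None) -> TridiagonalOperator:
    """Coefficients from mu, D = sigma^2/2 evaluated at (x_j, t).

    ``t`` defaults to n*dt; ``dt`` defaults to the grid timestep (the
    half-step CN startup passes dt/2).
    """
    params = spec.params if params is None else params
    dt = grid.dt if dt is None else dt
    t = n * grid.dt if t is None else t
    return _coefficients(spec, grid.x, t, conditions, params, dt, grid.dx)


def check_forward_stability(spec: GDDMSpec, grid: Grid, conditions: Conditions,
                            params: ParameterSet | None = None):
    """(stable, worst ratio): forward Euler requires D dt/dx^2 < 1/2."""
    params = spec.params if params is None else params
    worst = 0.0
    for t in np.linspace(0.0, grid.t_dur, 5):
        sigma = np.atleast_1d(spec.noise(grid.x, t, conditions, params))
        ratio = float(np.max(0.5 * sigma**2) * grid.dt / grid.dx**2)
        worst = max(worst, ratio)
    return worst < 0.5, worst


def step(P: np.ndarray, operator: TridiagonalOperator, alpha: float) -> np.ndarray:
    """One timestep of the unified scheme; returns the new state.

    alpha = 1 is the explicit update; alpha in {0, 0.5} solves the
    tridiagonal system (O(n) banded solve).  The state is not clamped here:
    leaving it untouched preserves the discrete conservation identity
    exactly (see :func:`extract_flux`).
    """
    if alpha not in (0.0, 0.5, 1.0):
        raise ValueError("alpha must be one of 1 (forward), 0 (backward), 0.5 (CN)")
    if operator.n != P.size:
        raise ValueError("operator size does not match the state vector")
    rhs = P - alpha * operator.apply(P) if alpha > 0 else P.copy()
    if alpha == 1.0:
        return rhs
    try:
        return solve_banded((1, 1), operator.lhs_banded(alpha), rhs)
    except np.linalg.LinAlgError as e:  # pragma: no cover - degenerate input
        raise NumericalError(f"singular tridiagonal system: {e}") from e


def extract_flux(P_old: np.ndarray, P_new: np.ndarray,
                 operator: TridiagonalOperator, alpha: float):
    """Per-step exit masses (upper, lower) at the two bounds.

    Derived from the column sums of M so that, before clamping,
    sum(P_old) = sum(P_new) + flux_upper + flux_lower holds to rounding.
    The scheme-consistent boundary state is alpha*P_old + (1-alpha)*P_new.
    Tiny negative fluxes are clamped to zero.
    """
    q_top = alpha * P_old[-1] + (1.0 - alpha) * P_new[-1]
    q_bot = alpha * P_old[0] + (1.0 - alpha) * P_new[0]
    up = (operator.nu[-1] + 0.5 * operator.chi[-1]) * q_top
    lo = (operator.nu[0] - 0.5 * operator.chi[0]) * q_bot
    return max(0.0, float(up)), max(0.0, float(lo))


def select_method(spec: GDDMSpec) -> str:
    """Best applicable solver, in priority order.

    Analytic when eligible; Crank-Nicolson for time-independent bounds;
    backward Euler otherwise.  Forward Euler and trajectory simulation are
    never auto-selected.
    """
    if check_analytic_eligibility(spec):
        return "analytic"
    if not spec.bound.t_dependent:
        return "crank_nicolson"
    return "backward_euler"


@dataclass
class _RunLog:
    clamp_total: float = 0.0
    min_state: float = 0.0
    diverged: bool = False
    extra: dict = field(default_factory=dict)


def _solve_fixed(spec, grid, conditions, params, method, alpha, verify,
                 allow_unstable, log: _RunLog):
    time_invariant = not (spec.drift.t_dependent or spec.noise.t_dependent)
    op = build_operator(spec, grid, conditions, params, t=0.0)
    op_half = None
    P = spec.ic(grid.x, conditions, params).astype(float)
    upper = np.zeros(grid.n_steps)
    lower = np.zeros(grid.n_steps)
    neg_tol = _NEG_TOL[method]
    for n in range(1, grid.n_steps + 1):
        t_eval = {"forward_euler": (n - 1) * grid.dt,
                  "backward_euler": n * grid.dt,
                  "crank_nicolson": (n - 0.5) * grid.dt}[method]
        if not time_invariant:
            op = build_operator(spec, grid, conditions, params, t=t_eval)
        if method == "crank_nicolson" and n <= 2:
            # Rannacher startup: two half-dt backward-Euler sub-steps
            if op_half is None or not time_invariant:
                op_half = build_operator(spec, grid, conditions, params,
                                         t=t_eval, dt=grid.dt / 2.0)
            up = lo = 0.0
            for _ in range(2):
                P_new = step(P, op_half, 0.0)
                du, dl = extract_flux(P, P_new, op_half, 0.0)
                up += du
                lo += dl
                P = P_new
            upper[n - 1], lower[n - 1] = up, lo
        else:
            P_new = step(P, op, alpha)
            upper[n - 1], lower[n - 1] = extract_flux(P, P_new, op, alpha)
            P = P_new
        mn = float(P.min())
        log.min_state = min(log.min_state, mn)
        total = float(P.sum())
        if total > 10.0:
            log.diverged = True
            if allow_unstable:
                break
        if verify and not allow_unstable:
            if mn < -neg_tol:
                raise NumericalError(
                    f"state mass {mn:.3e} below -{neg_tol:g} at step {n} "
                    f"({method})")
            if total > 1.0 + 1e-9:
                raise NumericalError(
                    f"total interior mass {total:.12g} exceeds 1 at step {n}; "
                    f"forward Euler instability? (use check_forward_stability)")
    undecided = float(P.sum())
    return upper, lower, undecided


def _moving_bound_layout(B_n: float, dx: float, n_half: int):
    """Grid systems active at bound B_n, as (half_width, weight) pairs.

    Half-widths are in index units (interior points of a system run over
    {-hw..hw}).  When the bound sits on a grid point (within 1e-12 * dx)
    there is a single system; otherwise the inner system (bound rounded
    down) and outer system (bound rounded up) are combined with the linear
    interpolation weights w_in = (x_{j+1} - B_n)/dx, w_out = (B_n - x_j)/dx.
    """
    m = B_n / dx
    i_near = int(round(m))
    if abs(B_n - i_near * dx) <= _ONGRID_RTOL * dx and 1 <= i_near <= n_half:
        return [(i_near - 1, 1.0)]
    j = int(np.floor(m))
    w_out = (B_n - j * dx) / dx
    w_in = ((j + 1) * dx - B_n) / dx
    return [(j, w_in), (j + 1, w_out)]


def _solve_moving(spec, grid, conditions, params, verify, log: _RunLog):
    """Backward-Euler propagation with time-varying symmetric bounds.

    The state lives on an extended master grid including the points at
    +/- B(0) (zero mass initially; the outer grid system can reach them
    while the bound is still within one dx of B(0)).  Mass stranded outside
    a shrinking bound is routed to the matching side's flux, weighted by
    its grid system's weight.
    """
    n_half = grid.half_points
    dx = grid.dx
    x_ext = dx * np.arange(-n_half, n_half + 1)
    c = n_half  # index of x = 0 in the extended grid
    P = np.zeros(x_ext.size)
    P[1:-1] = spec.ic(grid.x, conditions, params).astype(float)
    upper = np.zeros(grid.n_steps)
    lower = np.zeros(grid.n_steps)
    time_invariant = not (spec.drift.t_dependent or spec.noise.t_dependent)
    op_ext = _coefficients(spec, x_ext, 0.0, conditions, params, grid.dt, dx) \
        if time_invariant else None
    for n in range(1, grid.n_steps + 1):
        t_n = n * grid.dt
        B_n = spec.bound(t_n, conditions, params)
        if not np.isfinite(B_n) or B_n <= dx:
            raise NumericalError(
                f"bound B({t_n:g}) = {B_n!r} leaves no interior grid point "
                f"(domain collapse; B must exceed dx = {dx:g})")
        if B_n > grid.B0 * (1.0 + 1e-12):
            raise NumericalError(
                f"bound B({t_n:g}) = {B_n:g} exceeds B(0) = {grid.B0:g}; "
                "growing bounds beyond the master grid are unsupported")
        op = op_ext if time_invariant else \
            _coefficients(spec, x_ext, t_n, conditions, params, grid.dt, dx)
        up = lo = 0.0
        P_next = np.zeros_like(P)
        for hw, w in _moving_bound_layout(B_n, dx, n_half):
            sl = slice(c - hw, c + hw + 1)
            sub = P[sl]
            dropped_up = float(P[c + hw + 1:].sum())
            dropped_lo = float(P[:c - hw].sum())
            op_sub = op.restrict(sl)
            sub_new = step(sub, op_sub, 0.0)
            du, dl = extract_flux(sub, sub_new, op_sub, 0.0)
            up += w * (du + dropped_up)
            lo += w * (dl + dropped_lo)
            P_next[sl] += w * sub_new
        upper[n - 1], lower[n - 1] = up, lo
        P = P_next
        mn = float(P.min())
        log.min_state = min(log.min_state, mn)
        if verify and mn < -_NEG_TOL["backward_euler"]:
            raise NumericalError(
                f"state mass {mn:.3e} below tolerance at step {n} (moving bounds)")
    return upper, lower, float(P.sum())


def solve(spec: GDDMSpec, conditions: Conditions | None = None,
          dx: float = 0.005, dt: float = 0.005, t_dur: float = 2.0,
          method: str = "auto", params: ParameterSet | None = None,
          verify: bool = True, allow_unstable: bool = False,
          with_overlays: bool = True) -> SolutionPDF:
    """Solve a GDDM's first-passage-time distribution.

    Runs model validation (unless ``verify=False``), builds the grid,
    dispatches to the closed-form or finite-difference path, extracts
    per-step exit masses and finally applies the overlay chain.  Forcing
    ``method="forward_euler"`` outside its stability region is refused
    unless ``allow_unstable=True`` (used by the benchmark sweeps, where
    divergence is recorded rather than raised).
    """
    conditions = {} if conditions is None else conditions
    params = spec.params if params is None else params
    grid = build_grid(spec, conditions, dx, dt, t_dur, params)
    if verify:
        violations = validate_model(spec, grid, conditions, params)
        if violations:
            raise ValueError("model validation failed:\n" +
                             "\n".join(f"  - {v}" for v in violations))
    if method == "auto":
        method = select_method(spec)

    log = _RunLog()
    if method == "analytic":
        elig = check_analytic_eligibility(spec)
        if not elig:
            raise ValueError(f"analytic solver not applicable: {elig.reason}")
        mu = float(np.atleast_1d(spec.drift(0.0, 0.0, conditions, params))[0])
        sigma = float(np.atleast_1d(spec.noise(0.0, 0.0, conditions, params))[0])
        sol = solve_analytic(mu, sigma, grid.B0, grid.t_dur, grid.dt)
        sol = sol.replace(dx=grid.dx,
                          meta={**sol.meta, "requested_dx": grid.requested_dx})
    elif method in SCHEME_ALPHA:
        alpha = SCHEME_ALPHA[method]
        if spec.bound.t_dependent:
            if method != "backward_euler":
                raise ValueError(
                    f"{method} is not supported with time-varying bounds "
                    "(Crank-Nicolson oscillates there; use backward_euler)")
            upper, lower, undecided = _solve_moving(
                spec, grid, conditions, params, verify, log)
        else:
            if method == "forward_euler":
                stable, worst = check_forward_stability(spec, grid, conditions,
                                                        params)
                if not stable and not allow_unstable:
                    raise StabilityError(
                        f"forward Euler unstable: worst D*dt/dx^2 = {worst:.4g} "
                        ">= 1/2; shrink dt or use an implicit scheme")
            upper, lower, undecided = _solve_fixed(
                spec, grid, conditions, params, method, alpha, verify,
                allow_unstable, log)
        clamp = float(np.clip(upper, None, 0.0).sum() +
                      np.clip(lower, None, 0.0).sum())
        sol = SolutionPDF(dt=grid.dt, upper=np.clip(upper, 0.0, None),
                          lower=np.clip(lower, 0.0, None),
                          undecided=undecided, method=method, dx=grid.dx,
                          meta={"requested_dx": grid.requested_dx,
                                "requested_dt": grid.requested_dt,
                                "min_state": log.min_state,
                                "clamp_total": abs(clamp),
                                "diverged": log.diverged})
    else:
        raise ValueError(f"unknown method {method!r}")

    if verify and not log.diverged:
        sol.check(atol=1e-9, total=1.0)
    if with_overlays and spec.overlays:
        sol = apply_overlay_chain(sol, spec.overlays, conditions, params)
        if verify:
            sol.check(atol=1e-9, total=sol.meta.get("overlay_total", 1.0))
    return sol
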