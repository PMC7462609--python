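"""First-passage-time distribution container shared by all solvers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SolutionPDF"]


@dataclass(frozen=True)
class SolutionPDF:
    """Discretized choice/RT distribution of a diffusion decision model.

    ``upper[n-1]`` / ``lower[n-1]`` hold the unitless probability mass
    exiting through the upper ("correct") and lower ("error") bound during
    the n-th time bin ((n-1)*dt, n*dt], for n = 1..t_dur/dt.  ``undecided``
    is the mass still inside the bounds at t_dur.  Before overlays the
    masses and the undecided remainder total 1 (to 1e-9); overlays preserve
    their own stated total.
    """

    dt: float
    upper: np.ndarray
    lower: np.ndarray
    undecided: float
    method: str = "unknown"
    dx: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper/lower bin arrays must have the same length")

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.upper.size

    @property
    def t_dur(self) -> float:
        return self.n_bins * self.dt

    @property
    def t_bin_ends(self) -> np.ndarray:
        return self.dt * np.arange(1, self.n_bins + 1)

    @property
    def t_bin_mids(self) -> np.ndarray:
        return self.dt * (np.arange(self.n_bins) + 0.5)

    @property
    def prob_upper(self) -> float:
        return float(self.upper.sum())

    @property
    def prob_lower(self) -> float:
        return float(self.lower.sum())

    @property
    def total_mass(self) -> float:
        return self.prob_upper + self.prob_lower + self.undecided

    def density_upper(self) -> np.ndarray:
        """Per-second density at bin midpoints."""
        return self.upper / self.dt

    def density_lower(self) -> np.ndarray:
        return self.lower / self.dt

    def cdf_decided(self) -> np.ndarray:
        """Cumulative decided mass (both choices) at bin ends."""
        return np.cumsum(self.upper + self.lower)

    def replace(self, **kw) -> "SolutionPDF":
        return replace(self, **kw)

    def check(self, atol: float = 1e-9, total: float | None = 1.0) -> None:
        """Raise if masses are negative or the total strays from ``total``."""
        if self.upper.min(initial=0.0) < -atol or self.lower.min(initial=0.0) < -atol:
            raise ValueError("negative bin mass in solution")
        if self.undecided < -atol:
            raise ValueError("negative undecided mass in solution")
        if total is not None and abs(self.total_mass - total) > atol:
            raise ValueError(
                f"total mass {self.total_mass:.12g} differs from {total} by more "
                f"than {atol}")
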