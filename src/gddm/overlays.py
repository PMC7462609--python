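"""Overlays: post-processing transforms of solved RT distributions.

An overlay maps a :class:`~gddm.solution.SolutionPDF` to another, given the
task conditions and parameters.  The two workhorses are the non-decision
time shift (afferent/efferent delays outside the diffusion process, with
optional uniform across-trial variability) and the uniform lapse mixture
(a fittable fraction of contaminant responses spread evenly over time and
choices, which keeps full-distribution likelihoods finite for outliers).

Numeric parameters may be given either as literal floats or as the *name*
of an entry in the model's :class:`~gddm.model.ParameterSet`, so the same
overlay object works across optimizer iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solution import SolutionPDF

__all__ = ["Overlay", "NonDecisionOverlay", "UniformMixtureOverlay",
           "apply_overlay_chain"]


def _resolve(value, conditions, params) -> float:
    """A literal float, a parameter name, or a callable(conditions, params)."""
    if isinstance(value, str):
        return float(params[value])
    if callable(value):
        return float(value(conditions, params))
    return float(value)


class Overlay:
    """Base class; subclasses implement :meth:`apply`."""

    def apply(self, solution: SolutionPDF, conditions, params) -> SolutionPDF:
        raise NotImplementedError


def _shifted(arr: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Shift bin masses ``k`` bins later; return (shifted, mass pushed past t_dur)."""
    if k == 0:
        return arr.copy(), 0.0
    out = np.zeros_like(arr)
    out[k:] = arr[: arr.size - k]
    return out, float(arr[arr.size - k:].sum())


@dataclass(frozen=True)
class NonDecisionOverlay(Overlay):
    """Shift the RT distribution later by t_nd seconds.

    The shift is rounded to the nearest whole number of time bins (bias
    below dt/2).  With ``width`` (s_T) > 0 the shift is averaged over
    uniform offsets in [t_nd - s_T, t_nd + s_T] stepping by dt; offsets
    that would be negative are dropped and the remaining weights
    renormalized.  Mass shifted past t_dur is reclassified as undecided,
    so total mass is preserved.
    """

    t_nd: object = 0.0
    width: object = 0.0

    def apply(self, solution: SolutionPDF, conditions, params) -> SolutionPDF:
        t_nd = _resolve(self.t_nd, conditions, params)
        s_T = _resolve(self.width, conditions, params)
        if t_nd < 0 or s_T < 0:
            raise ValueError("non-decision time and its width must be >= 0")
        if t_nd >= solution.t_dur:
            raise ValueError(
                f"non-decision time {t_nd:g}s is not below t_dur = "
                f"{solution.t_dur:g}s")
        dt = solution.dt
        k_lo = int(round((t_nd - s_T) / dt))
        k_hi = int(round((t_nd + s_T) / dt))
        ks = [k for k in range(k_lo, k_hi + 1) if 0 <= k < solution.n_bins]
        if not ks:
            ks = [max(0, min(solution.n_bins - 1, int(round(t_nd / dt))))]
        w = 1.0 / len(ks)
        upper = np.zeros(solution.n_bins)
        lower = np.zeros(solution.n_bins)
        lost = 0.0
        for k in ks:
            su, lu = _shifted(solution.upper, k)
            sl, ll = _shifted(solution.lower, k)
            upper += w * su
            lower += w * sl
            lost += w * (lu + ll)
        return solution.replace(upper=upper, lower=lower,
                                undecided=solution.undecided + lost)


@dataclass(frozen=True)
class UniformMixtureOverlay(Overlay):
    """Mix the diffusion distribution with a uniform lapse distribution.

    The output is w * (diffusion solution) + (1 - w) * lapse, where the
    lapse mass 1 - w is spread uniformly over (0, t_dur] and split evenly
    between the two choices.  Undecided mass is scaled by w.  Total mass
    stays exactly 1 (when the input totals 1) for any t_dur.
    """

    w: object = 0.95

    def apply(self, solution: SolutionPDF, conditions, params) -> SolutionPDF:
        w = _resolve(self.w, conditions, params)
        if not 0.0 < w <= 1.0:
            raise ValueError(f"mixture weight w = {w:g} must be in (0, 1]")
        lapse_per_bin = (1.0 - w) / (2.0 * solution.n_bins)
        return solution.replace(
            upper=w * solution.upper + lapse_per_bin,
            lower=w * solution.lower + lapse_per_bin,
            undecided=w * solution.undecided)


def apply_overlay_chain(solution: SolutionPDF, overlays, conditions,
                        params) -> SolutionPDF:
    """Apply overlays in order, checking output mass invariants."""
    for ov in overlays:
        solution = ov.apply(solution, conditions, params)
        if solution.upper.min(initial=0.0) < -1e-12 or \
           solution.lower.min(initial=0.0) < -1e-12:
            raise ValueError(f"overlay {ov!r} produced negative masses")
        if solution.total_mass > 1.0 + 1e-12:
            raise ValueError(f"overlay {ov!r} produced total mass > 1")
    return solution
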