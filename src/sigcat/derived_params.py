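"""Biologically meaningful descriptors computed from fitted parameters.

For the sigmoidal model the midpoint slope is ``a1 I_max / 4``; the tangent
line through the midpoint with that slope gives the start of growth (its
x-axis intercept), the end of growth (its intercept with ``I_max``) and the
growth duration.  These tangent constructions have a simple geometric
interpretation and give a conservative estimate of the total duration of
growth or decay.

For the double-sigmoidal model the primed fit parameters do not directly
represent midpoints or slopes; the true midpoints are found numerically
(``t_mid1`` where the curve crosses ``I_max/2`` on the rising branch,
``t_mid2`` where it crosses halfway from maximum to final value on the
decaying branch) and the midpoint slopes by central finite differences.
The analogous tangent constructions give growth and decay start/end points
and durations.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .core_models import (
    DoubleSigmoidalParams,
    NumericalFailure,
    SigmoidalParams,
    eval_double_sigmoidal,
    eval_sigmoidal,
    find_tstar,
)

__all__ = [
    "DerivedParameters",
    "derive_sigmoidal",
    "derive_double_sigmoidal",
    "denormalize_derived",
]

_ROOT_XTOL = 1e-10


@dataclass(frozen=True)
class DerivedParameters:
    """Derived curve descriptors; double-sigmoidal-only fields are ``None``
    for sigmoidal fits.  ``available`` is False when a numerical step
    (midpoint root bracketing, slope estimation) failed, in which case the
    affected fields are ``None``."""

    available: bool
    end_ratio: float | None
    # growth phase (both models)
    start_time: float | None
    end_time: float | None
    growth_duration: float | None
    # sigmoidal
    t_mid: float | None = None
    midpoint_slope: float | None = None
    # double-sigmoidal
    t_mid1: float | None = None
    t_mid2: float | None = None
    slope1: float | None = None
    slope2: float | None = None
    t_star: float | None = None
    decay_start_time: float | None = None
    decay_end_time: float | None = None
    decay_duration: float | None = None


def derive_sigmoidal(p: SigmoidalParams, last_obs_time: float) -> DerivedParameters:
    """Closed-form descriptors of a fitted sigmoidal curve.

    The tangent at the midpoint has slope ``a1 I_max / 4`` and passes
    through ``(t_mid, I_max/2)``, giving ``start = t_mid - 2/a1``,
    ``end = t_mid + 2/a1`` and ``duration = 4/a1`` (independent of
    ``I_max`` and ``t_mid``).  ``end_ratio`` is the model prediction at
    the last observation divided by ``I_max``.
    """
    slope = p.a1 * p.I_max / 4.0
    start = p.t_mid - 2.0 / p.a1
    end = p.t_mid + 2.0 / p.a1
    end_ratio = eval_sigmoidal(last_obs_time, p) / p.I_max
    return DerivedParameters(
        available=True,
        end_ratio=float(end_ratio),
        start_time=start,
        end_time=end,
        growth_duration=4.0 / p.a1,
        t_mid=p.t_mid,
        midpoint_slope=slope,
    )


def _bracket_root(func, anchor: float, direction: float, step0: float,
                  max_doublings: int = 200) -> tuple[float, float]:
    """Expand from ``anchor`` in ``direction`` until ``func`` changes sign.

    ``func(anchor)`` must be positive; returns an interval (lo < hi) with a
    sign change.  Raises NumericalFailure if none is found.
    """
    step = step0
    prev = anchor
    for _ in range(max_doublings):
        probe = anchor + direction * step
        if func(probe) < 0.0:
            return (probe, prev) if direction < 0 else (prev, probe)
        prev = probe
        step *= 2.0
    raise NumericalFailure("midpoint root bracketing failed")


def derive_double_sigmoidal(
    p: DoubleSigmoidalParams,
    last_obs_time: float,
    fd_step: float = 1e-6,
) -> DerivedParameters:
    """Numerically derived descriptors of a fitted double-sigmoidal curve.

    ``t_mid1`` is the unique time on the rising branch where the curve
    equals ``I_max/2``; ``t_mid2`` the unique time on the decaying branch
    where it equals ``(I_max + I_final)/2``.  Midpoint slopes come from
    central finite differences with step ``fd_step`` (the default suits
    the normalized time scale; pass ``1e-6 * time_scale`` for raw units).
    Tangent lines at the midpoints give growth and decay start/end points.

    If ``I_final`` equals ``I_max`` the decay midpoint is undefined and
    the result is flagged unavailable.
    """
    try:
        t_star = find_tstar(p)
    except NumericalFailure:
        return DerivedParameters(
            available=False, end_ratio=None, start_time=None, end_time=None,
            growth_duration=None,
        )

    def curve(t: float) -> float:
        return float(eval_double_sigmoidal(t, p, tstar=t_star))

    end_ratio = curve(last_obs_time) / p.I_max
    step0 = max(
        p.t_mid2_prime - p.t_mid1_prime, 1.0 / p.a1_prime, 1.0 / p.a2_prime
    )
    try:
        # rising branch: curve - I_max/2 is positive at t*, negative far left
        half = p.I_max / 2.0
        lo, hi = _bracket_root(lambda t: curve(t) - half, t_star, -1.0, step0)
        t_mid1 = brentq(lambda t: curve(t) - half, lo, hi,
                        xtol=_ROOT_XTOL, maxiter=500)
        # decaying branch: target halfway from maximum to final value
        if not p.I_final < p.I_max:
            raise NumericalFailure("I_final equals I_max; decay midpoint undefined")
        target2 = (p.I_max + p.I_final) / 2.0
        lo, hi = _bracket_root(lambda t: curve(t) - target2, t_star, 1.0, step0)
        t_mid2 = brentq(lambda t: curve(t) - target2, lo, hi,
                        xtol=_ROOT_XTOL, maxiter=500)
        slope1 = (curve(t_mid1 + fd_step) - curve(t_mid1 - fd_step)) / (2 * fd_step)
        slope2 = (curve(t_mid2 + fd_step) - curve(t_mid2 - fd_step)) / (2 * fd_step)
        if not (slope1 > 0.0 and slope2 < 0.0):
            raise NumericalFailure("degenerate midpoint slope estimate")
    except NumericalFailure:
        return DerivedParameters(
            available=False,
            end_ratio=float(end_ratio),
            start_time=None, end_time=None, growth_duration=None,
            t_star=t_star,
        )

    # growth tangent through (t_mid1, I_max/2)
    start = t_mid1 - half / slope1
    end = t_mid1 + half / slope1
    # decay tangent through (t_mid2, (I_max + I_final)/2); slope2 < 0 so the
    # intercept with I_max lies before t_mid2 and with I_final after it
    decay_start = t_mid2 + (p.I_max - target2) / slope2
    decay_end = t_mid2 + (p.I_final - target2) / slope2
    return DerivedParameters(
        available=True,
        end_ratio=float(end_ratio),
        start_time=start,
        end_time=end,
        growth_duration=end - start,
        t_mid1=t_mid1,
        t_mid2=t_mid2,
        slope1=slope1,
        slope2=slope2,
        t_star=t_star,
        decay_start_time=decay_start,
        decay_end_time=decay_end,
        decay_duration=decay_end - decay_start,
    )


def denormalize_derived(d: DerivedParameters, rec) -> DerivedParameters:
    """Map derived descriptors from the normalized to the raw scale.

    Times map affinely (``raw = offset + scale * normalized``), durations
    by the time scale, slopes by ``intensity_scale / time_scale``; the end
    ratio is dimensionless and unchanged.  Exact, because every derived
    quantity is defined geometrically on the curve.
    """
    ts, toff = rec.time_scale, rec.time_offset
    slope_scale = rec.intensity_scale / rec.time_scale

    def time_(v):
        return None if v is None else v * ts + toff

    def dur_(v):
        return None if v is None else v * ts

    def slope_(v):
        return None if v is None else v * slope_scale

    return DerivedParameters(
        available=d.available,
        end_ratio=d.end_ratio,
        start_time=time_(d.start_time),
        end_time=time_(d.end_time),
        growth_duration=dur_(d.growth_duration),
        t_mid=time_(d.t_mid),
        midpoint_slope=slope_(d.midpoint_slope),
        t_mid1=time_(d.t_mid1),
        t_mid2=time_(d.t_mid2),
        slope1=slope_(d.slope1),
        slope2=slope_(d.slope2),
        t_star=time_(d.t_star),
        decay_start_time=time_(d.decay_start_time),
        decay_end_time=time_(d.decay_end_time),
        decay_duration=dur_(d.decay_duration),
    )
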