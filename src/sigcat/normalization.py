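"""Normalization of time courses onto the internal [0,1] x [0,1] scale.

All fitting and every decision threshold (the 0.05 starting-intensity cap,
the 0.85 / 0.75 end-ratio gates, the AIC cutoff) operate on normalized
data; fitted parameters are mapped back to raw units for reporting.

Both axes are min-max scaled: ``x -> (x - min) / (max - min)``, so the
first observation sits at time 0 and the observed intensities span exactly
[0, 1].  This anchors the decision thresholds to the observation window —
in particular "growth starts at a positive time" means growth starts
after the first observation — and keeps the noise floor of background-
subtracted data (which may dip below zero) at the normalized origin
rather than below it.

When the raw minima are nonzero, the raw-scale curve corresponding to a
normalized fit is ``offset + scale * model(normalized time)``; the
"raw-scale parameters" returned by the denormalization helpers are
therefore affine descriptors of that curve (its asymptote, midpoint
location and slope in raw units), not parameters of a zero-baseline
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_models import DoubleSigmoidalParams, SigmoidalParams

__all__ = [
    "TimeCourse",
    "NormalizationRecord",
    "NoSignalError",
    "normalize",
    "denormalize_sigmoidal",
    "denormalize_double_sigmoidal",
    "normalize_sigmoidal",
    "normalize_double_sigmoidal",
]

#: Minimum number of observations: the double-sigmoidal model has six
#: parameters (plus the residual variance), so require strictly more points.
MIN_OBSERVATIONS = 7


class NoSignalError(ValueError):
    """The intensities carry no usable signal (e.g. all equal)."""


@dataclass(frozen=True)
class TimeCourse:
    """A sequence of (time, intensity) observations.

    Times need not be equidistant; they are sorted on construction
    (intensities are reordered along with them).  All values must be
    finite and at least :data:`MIN_OBSERVATIONS` points are required.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __init__(self, times, intensities) -> None:
        t = np.asarray(times, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be equal-length 1-D")
        if t.size < MIN_OBSERVATIONS:
            raise ValueError(
                f"need at least {MIN_OBSERVATIONS} observations, got {t.size}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and intensities must be finite")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "intensities", y[order])

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def max_intensity(self) -> float:
        return float(np.max(self.intensities))

    @property
    def intensity_range(self) -> float:
        return float(np.ptp(self.intensities))


@dataclass(frozen=True)
class NormalizationRecord:
    """The affine maps applied by :func:`normalize`:
    ``raw = offset + scale * normalized`` on each axis."""

    time_scale: float
    intensity_scale: float
    time_offset: float = 0.0
    intensity_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.time_scale > 0 and self.intensity_scale > 0):
            raise ValueError("scales must be positive")


def normalize(tc: TimeCourse) -> tuple[TimeCourse, NormalizationRecord]:
    """Min-max scale both axes onto [0, 1].

    Idempotent: data already spanning [0, 1] on both axes maps to itself
    with unit scales and zero offsets.

    Raises
    ------
    NoSignalError
        If the intensity range is not positive (a flat trace carries no
        signal and has no scale).
    ValueError
        If all observation times coincide.
    """
    t_off = float(np.min(tc.times))
    t_scale = float(np.max(tc.times)) - t_off
    if t_scale <= 0:
        raise ValueError("observation times must not all coincide")
    y_off = float(np.min(tc.intensities))
    y_scale = tc.max_intensity - y_off
    if y_scale <= 0:
        raise NoSignalError("intensity range is not positive")
    tc_norm = TimeCourse(
        (tc.times - t_off) / t_scale, (tc.intensities - y_off) / y_scale
    )
    return tc_norm, NormalizationRecord(
        time_scale=t_scale,
        intensity_scale=y_scale,
        time_offset=t_off,
        intensity_offset=y_off,
    )


def denormalize_sigmoidal(
    p_norm: SigmoidalParams, rec: NormalizationRecord
) -> SigmoidalParams:
    """Map normalized-scale sigmoidal parameters to raw-unit descriptors.

    ``I_max`` carries intensity units (the raw asymptote above the raw
    baseline is ``intensity_offset + intensity_scale * I_max``), ``t_mid``
    time units, and ``a1`` inverse-time units, so the midpoint slope
    ``a1 I_max / 4`` scales by ``intensity_scale / time_scale``.
    """
    return SigmoidalParams(
        I_max=p_norm.I_max * rec.intensity_scale + rec.intensity_offset,
        t_mid=p_norm.t_mid * rec.time_scale + rec.time_offset,
        a1=p_norm.a1 / rec.time_scale,
    )


def denormalize_double_sigmoidal(
    p_norm: DoubleSigmoidalParams, rec: NormalizationRecord
) -> DoubleSigmoidalParams:
    """Map normalized-scale double-sigmoidal parameters to raw units."""
    return DoubleSigmoidalParams(
        I_max=p_norm.I_max * rec.intensity_scale + rec.intensity_offset,
        I_final=p_norm.I_final * rec.intensity_scale + rec.intensity_offset,
        t_mid1_prime=p_norm.t_mid1_prime * rec.time_scale + rec.time_offset,
        t_mid2_prime=p_norm.t_mid2_prime * rec.time_scale + rec.time_offset,
        a1_prime=p_norm.a1_prime / rec.time_scale,
        a2_prime=p_norm.a2_prime / rec.time_scale,
    )


def normalize_sigmoidal(
    p_raw: SigmoidalParams, rec: NormalizationRecord
) -> SigmoidalParams:
    """Inverse of :func:`denormalize_sigmoidal` (raw -> normalized scale)."""
    return SigmoidalParams(
        I_max=(p_raw.I_max - rec.intensity_offset) / rec.intensity_scale,
        t_mid=(p_raw.t_mid - rec.time_offset) / rec.time_scale,
        a1=p_raw.a1 * rec.time_scale,
    )


def normalize_double_sigmoidal(
    p_raw: DoubleSigmoidalParams, rec: NormalizationRecord
) -> DoubleSigmoidalParams:
    """Inverse of :func:`denormalize_double_sigmoidal`."""
    return DoubleSigmoidalParams(
        I_max=(p_raw.I_max - rec.intensity_offset) / rec.intensity_scale,
        I_final=(p_raw.I_final - rec.intensity_offset) / rec.intensity_scale,
        t_mid1_prime=(p_raw.t_mid1_prime - rec.time_offset) / rec.time_scale,
        t_mid2_prime=(p_raw.t_mid2_prime - rec.time_offset) / rec.time_scale,
        a1_prime=p_raw.a1_prime * rec.time_scale,
        a2_prime=p_raw.a2_prime * rec.time_scale,
    )
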