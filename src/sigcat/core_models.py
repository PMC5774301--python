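"""Model functions for sigmoidal and double-sigmoidal intensity curves.

The two fitted models are the three-parameter logistic (Fermi) function

    f_sig(t) = I_max / (1 + exp(-a1 (t - t_mid)))

and a six-parameter double-sigmoidal curve built from the *base*
double-sigmoidal, the product of a rising and a decaying logistic,

    f_base(t) = 1 / [(exp(-a1' (t - t_mid1')) + 1) (exp(a2' (t - t_mid2')) + 1)]

which always has exactly one maximum (at ``t*``) but decays back to zero.
The usable double-sigmoidal cuts f_base at ``t*`` and rescales the two
branches separately so the curve attains ``I_max`` at ``t*`` and tends to
``I_final`` for large times.  The resulting curve is continuous with a
continuous first derivative.

Also provided, purely as numerical oracles for tests: the four-parameter
generalized logistic (rising from ``I_init`` instead of 0) and the naive
product of a generalized rising and decaying logistic, which is *not*
guaranteed to be double-sigmoidal — the corner case that motivates the
cut-and-rescale construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidalParams",
    "DoubleSigmoidalParams",
    "GeneralSigmoidalParams",
    "NumericalFailure",
    "eval_sigmoidal",
    "eval_dsig_base",
    "find_tstar",
    "eval_double_sigmoidal",
    "eval_general_sigmoidal",
    "eval_naive_product",
    "numerical_derivative",
]

# exp() overflows float64 just above 709; clamping keeps every expression
# finite while preserving monotonicity and signs.
_EXP_CLAMP = 700.0


class NumericalFailure(RuntimeError):
    """A guaranteed-convergent numerical procedure failed anyway."""


def _check_finite_scalar(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class SigmoidalParams:
    """Parameters of the three-parameter logistic: maximum, midpoint, slope.

    ``a1`` has inverse-time units and sets the midpoint slope via
    ``dI/dt at t_mid = a1 * I_max / 4``.
    """

    I_max: float
    t_mid: float
    a1: float

    def __post_init__(self) -> None:
        for name in ("I_max", "t_mid", "a1"):
            _check_finite_scalar(name, getattr(self, name))
        if self.I_max <= 0:
            raise ValueError(f"I_max must be > 0, got {self.I_max}")
        if self.a1 <= 0:
            raise ValueError(f"a1 must be > 0, got {self.a1}")


@dataclass(frozen=True)
class DoubleSigmoidalParams:
    """Parameters of the rescaled double-sigmoidal model.

    The primed midpoints and slopes determine, but do not equal, the true
    midpoints and midpoint slopes of the curve; those are computed
    numerically (see :mod:`sigcat.derived_params`).  ``t_mid2_prime`` is
    required to exceed ``t_mid1_prime``.

    ``I_final`` may not exceed ``I_max`` but is allowed to be negative:
    raw-scale descriptors of background-subtracted data can decay to an
    asymptote below zero.  The fitting parameterization keeps
    ``0 <= I_final`` on the normalized scale.
    """

    I_max: float
    I_final: float
    t_mid1_prime: float
    t_mid2_prime: float
    a1_prime: float
    a2_prime: float

    def __post_init__(self) -> None:
        for name in (
            "I_max",
            "I_final",
            "t_mid1_prime",
            "t_mid2_prime",
            "a1_prime",
            "a2_prime",
        ):
            _check_finite_scalar(name, getattr(self, name))
        if self.I_max <= 0:
            raise ValueError(f"I_max must be > 0, got {self.I_max}")
        if not self.I_final <= self.I_max:
            raise ValueError(
                f"I_final must not exceed I_max, got {self.I_final} "
                f"with I_max={self.I_max}"
            )
        if self.a1_prime <= 0 or self.a2_prime <= 0:
            raise ValueError("slope parameters must be > 0")
        if self.t_mid2_prime <= self.t_mid1_prime:
            raise ValueError("t_mid2_prime must be larger than t_mid1_prime")


@dataclass(frozen=True)
class GeneralSigmoidalParams:
    """Four-parameter logistic rising from ``I_init`` to ``I_max``.

    Test oracle only; the fitted sigmoidal model is the ``I_init = 0`` case.
    """

    I_init: float
    I_max: float
    t_mid: float
    a1: float

    def __post_init__(self) -> None:
        for name in ("I_init", "I_max", "t_mid", "a1"):
            _check_finite_scalar(name, getattr(self, name))
        if self.a1 <= 0:
            raise ValueError(f"a1 must be > 0, got {self.a1}")
        if self.I_max <= self.I_init:
            raise ValueError("I_max must exceed I_init")


def _as_finite_array(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("time values must be finite")
    return arr


def eval_sigmoidal(t, p: SigmoidalParams):
    """Evaluate the logistic curve ``I_max / (1 + exp(-a1 (t - t_mid)))``.

    Strictly increasing in ``t`` and bounded in ``(0, I_max)``.
    """
    arr = _as_finite_array(t)
    out = p.I_max * expit(p.a1 * (arr - p.t_mid))
    return out if out.ndim else float(out)


def eval_dsig_base(t, a1_prime: float, a2_prime: float,
                   t_mid1_prime: float, t_mid2_prime: float):
    """Evaluate the base double-sigmoidal (product of two logistics).

    The value lies in ``(0, 1)`` for finite ``t`` and tends to 0 at both
    infinities; it has exactly one local maximum.
    """
    if a1_prime <= 0 or a2_prime <= 0:
        raise ValueError("slope parameters must be > 0")
    if t_mid2_prime <= t_mid1_prime:
        raise ValueError("t_mid2_prime must be larger than t_mid1_prime")
    arr = _as_finite_array(t)
    out = expit(a1_prime * (arr - t_mid1_prime)) * expit(
        -a2_prime * (arr - t_mid2_prime)
    )
    return out if out.ndim else float(out)


def _h(u: float, a1: float, a2: float, L: float) -> float:
    """Derivative-sign function whose unique root locates the maximum of
    the base double-sigmoidal: h(u) = a1 (e^{a2 (L-u)} + 1) - a2 (e^{a1 u} + 1).

    Strictly decreasing in u, +inf at -inf and -inf at +inf; exponents are
    clamped for float safety, which preserves monotonicity and the root
    whenever the root's own exponents are representable.
    """
    e1 = math.exp(min(a2 * (L - u), _EXP_CLAMP))
    e2 = math.exp(min(a1 * u, _EXP_CLAMP))
    return a1 * (e1 + 1.0) - a2 * (e2 + 1.0)


def _solve_ustar(a1: float, a2: float, L: float, xtol: float = 1e-10) -> float:
    """Root of the monotone ``h`` by expanding bracket plus bisection.

    Called once per model evaluation during fitting, so it is written
    with plain scalar math (no callback-based root finder).
    """
    lo, hi = 0.0, L
    # expansion steps scale with where the root can actually sit: if h(0)
    # is already negative the root is left of 0 at distance ~ln(a1/a2)/a2,
    # and symmetrically on the right — never astronomically far
    step = max(L, 1.0 / a2)
    n_expand = 0
    while _h(lo, a1, a2, L) < 0.0:
        lo -= step
        step *= 2.0
        n_expand += 1
        if n_expand > 200:
            raise NumericalFailure("no lower bracket for t* search")
    step = max(L, 1.0 / a1)
    while _h(hi, a1, a2, L) > 0.0:
        hi += step
        step *= 2.0
        n_expand += 1
        if n_expand > 400:
            raise NumericalFailure("no upper bracket for t* search")
    # safeguarded Newton: quadratic near the root, alternated with plain
    # bisection so the bracket provably shrinks (h is strictly decreasing)
    exp_ = math.exp
    u = 0.5 * (lo + hi)
    for i in range(500):
        x1 = a2 * (L - u)
        x2 = a1 * u
        e1 = exp_(x1 if x1 < _EXP_CLAMP else _EXP_CLAMP)
        e2 = exp_(x2 if x2 < _EXP_CLAMP else _EXP_CLAMP)
        h = a1 * (e1 + 1.0) - a2 * (e2 + 1.0)
        if h > 0.0:
            lo = u
        else:
            hi = u
        if hi - lo < xtol:
            break
        if i & 1:
            u = 0.5 * (lo + hi)
        else:
            u_new = u - h / (-a1 * a2 * (e1 + e2))
            u = u_new if lo < u_new < hi else 0.5 * (lo + hi)
    return 0.5 * (lo + hi)


def find_tstar(p: DoubleSigmoidalParams) -> float:
    """Locate the unique maximum ``t*`` of the base double-sigmoidal.

    Solves ``h(u) = 0`` in the shifted variable ``u = t - t_mid1_prime``
    by bracketing plus bisection; monotonicity of ``h`` guarantees the
    root is unique, so this is exact and robust where generic optimization
    is not.

    Raises
    ------
    NumericalFailure
        If no sign-changing bracket is found within the expanding search
        window (cannot occur for valid parameters with representable
        exponents).
    """
    u_star = _solve_ustar(
        p.a1_prime, p.a2_prime, p.t_mid2_prime - p.t_mid1_prime
    )
    return p.t_mid1_prime + u_star


def eval_double_sigmoidal(t, p: DoubleSigmoidalParams, tstar: float | None = None):
    """Evaluate the cut-and-rescaled double-sigmoidal curve.

    For ``t <= t*`` the curve is ``c1 * f_base(t)`` with ``c1 = I_max/f_max``;
    for ``t > t*`` it is ``c2 * f_base(t) + I_final`` with
    ``c2 = (I_max - I_final)/f_max``.  The curve rises from 0 to ``I_max``
    at ``t*`` and decays to ``I_final``; it is continuous with a continuous
    first derivative.

    ``tstar`` may be supplied to avoid recomputing the root in hot loops.
    """
    arr = _as_finite_array(t)
    if tstar is None:
        tstar = find_tstar(p)
    f_max = eval_dsig_base(
        tstar, p.a1_prime, p.a2_prime, p.t_mid1_prime, p.t_mid2_prime
    )
    base = eval_dsig_base(
        arr, p.a1_prime, p.a2_prime, p.t_mid1_prime, p.t_mid2_prime
    )
    c1 = p.I_max / f_max
    c2 = (p.I_max - p.I_final) / f_max
    out = np.where(arr <= tstar, c1 * base, c2 * base + p.I_final)
    return out if out.ndim else float(out)


def eval_general_sigmoidal(t, p: GeneralSigmoidalParams):
    """Four-parameter logistic: ``(I_max - I_init) expit(a1 (t - t_mid)) + I_init``."""
    arr = _as_finite_array(t)
    out = (p.I_max - p.I_init) * expit(p.a1 * (arr - p.t_mid)) + p.I_init
    return out if out.ndim else float(out)


def eval_naive_product(t, I_init: float, I_final: float, I_max: float,
                       a1: float, a2: float, t_mid1: float, t_mid2: float):
    """Literal product of a rising and a decaying generalized logistic.

    Provided only as a test oracle: for some parameter regions (small
    midpoint gap, one steep and one shallow slope) this product develops a
    local minimum and is therefore *not* double-sigmoidal, which is why the
    fitted model uses the cut-and-rescale construction instead.
    """
    if a1 <= 0 or a2 <= 0:
        raise ValueError("slope parameters must be > 0")
    arr = _as_finite_array(t)
    rise = (I_max - I_init) * expit(a1 * (arr - t_mid1)) + I_init
    decay = (1.0 - I_final) * expit(-a2 * (arr - t_mid2)) + I_final
    out = rise * decay
    return out if out.ndim else float(out)


def numerical_derivative(func, t: float, h: float = 1e-6):
    """Central finite difference ``(f(t+h) - f(t-h)) / (2h)``.

    The default step of 1e-6 is chosen for curves on the normalized
    [0, 1] time scale; pass ``h = 1e-6 * time_scale`` for raw-unit curves.
    """
    return (func(t + h) - func(t - h)) / (2.0 * h)
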