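"""Synthetic sigmoidal and double-sigmoidal time courses for benchmarking.

Parameter sets are drawn at random (maxima and midpoints uniform, slopes as
the tangent of a uniform angle in [0, pi/2], so heavy-tailed), intensities
are evaluated over the window t in [3, 30] under one of five temporal
sampling regimes, and noise of a chosen amplitude is added.  Parameter sets
whose *noise-free* curve would, by definition, not be classified as its own
model (no detectable signal, a nonpositive start point, too-high starting
intensity, or — for the double-sigmoidal — decay not detectable within the
window) are rejected and resampled, so every retained set is classifiable
in principle.

All randomness flows from a single seed through a documented
``numpy.random.SeedSequence`` spawn tree (seed -> grid cell -> replicate),
so any individual sample can be regenerated in isolation and full grids
are bit-identical across runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .categorize import DecisionConfig, check_no_signal
from .core_models import (
    DoubleSigmoidalParams,
    SigmoidalParams,
    eval_double_sigmoidal,
    eval_sigmoidal,
)
from .derived_params import derive_double_sigmoidal
from .fitting import DOUBLE_SIGMOIDAL, SIGMOIDAL

__all__ = [
    "SAMPLING_REGIMES",
    "NOISE_TYPES",
    "DEFAULT_AMPLITUDES",
    "N_TIME_POINTS",
    "TIME_WINDOW",
    "ConfigurationError",
    "SimulationSpec",
    "GridSpec",
    "SimulatedSample",
    "sample_sigmoidal_params",
    "sample_double_params",
    "sample_times",
    "add_noise",
    "clean_curve",
    "is_classifiable_as_truth",
    "generate_sample",
    "generate_grid",
    "grid_size",
]

SAMPLING_REGIMES = ("equidistant", "uniform", "beta_early", "beta_center", "beta_late")
NOISE_TYPES = ("additive", "multiplicative")
#: 11 equally spaced noise amplitudes from 0% to 150% of the clean maximum.
DEFAULT_AMPLITUDES = tuple(round(0.15 * i, 2) for i in range(11))
N_TIME_POINTS = 55
TIME_WINDOW = (3.0, 30.0)

_BETA_SHAPES = {
    "beta_early": (0.5, 1.5),
    "beta_center": (2.0, 2.0),
    "beta_late": (1.5, 0.5),
}


class ConfigurationError(RuntimeError):
    """A simulation cell rejects nearly every draw; thresholds and sampling
    ranges are incompatible."""


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation cell: model, temporal sampling, noise model."""

    model_kind: str = SIGMOIDAL
    sampling_regime: str = "equidistant"
    noise_type: str = "additive"
    noise_amplitude: float = 0.0
    n_replicates: int = 50
    seed: int = 0
    multiplicative_mode: str = "centered"

    def __post_init__(self) -> None:
        if self.model_kind not in (SIGMOIDAL, DOUBLE_SIGMOIDAL):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.sampling_regime not in SAMPLING_REGIMES:
            raise ValueError(f"unknown sampling regime {self.sampling_regime!r}")
        if self.noise_type not in NOISE_TYPES:
            raise ValueError(f"unknown noise type {self.noise_type!r}")
        if not (0.0 <= self.noise_amplitude <= 1.5):
            raise ValueError("noise amplitude must lie in [0, 1.5]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.multiplicative_mode not in ("centered", "literal"):
            raise ValueError("multiplicative_mode must be 'centered' or 'literal'")


@dataclass(frozen=True)
class GridSpec:
    """The full benchmark grid: the cross product of models, sampling
    regimes, noise types and amplitudes, with fresh parameter sets per
    cell.  The defaults reproduce the 50 x 2 x 5 x 11 x 2 = 11,000
    parameter-set study grid."""

    models: tuple[str, ...] = (SIGMOIDAL, DOUBLE_SIGMOIDAL)
    regimes: tuple[str, ...] = SAMPLING_REGIMES
    noise_types: tuple[str, ...] = NOISE_TYPES
    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES
    n_replicates: int = 50
    seed: int = 0
    multiplicative_mode: str = "centered"
    decision_cfg: DecisionConfig = field(default_factory=DecisionConfig)


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated time course with its ground truth attached."""

    sample_id: str
    model_kind: str
    sampling_regime: str
    noise_type: str
    noise_amplitude: float
    replicate: int
    true_params: SigmoidalParams | DoubleSigmoidalParams
    times: np.ndarray
    clean_intensities: np.ndarray
    noisy_intensities: np.ndarray


def sample_sigmoidal_params(rng: np.random.Generator) -> SigmoidalParams:
    """Draw sigmoidal truth parameters: ``I_max ~ U[0.3, 20]``,
    ``t_mid ~ U[3, 27]``, ``a1 = tan(theta)`` with ``theta ~ U[0, pi/2]``."""
    i_max = rng.uniform(0.3, 20.0)
    t_mid = rng.uniform(3.0, 27.0)
    a1 = math.tan(rng.uniform(0.0, math.pi / 2.0))
    return SigmoidalParams(I_max=i_max, t_mid=t_mid, a1=a1)


def sample_double_params(rng: np.random.Generator) -> DoubleSigmoidalParams:
    """Draw double-sigmoidal truth parameters.

    ``I_max ~ U[0.3, 20]``; first midpoint ``~ U[3, 26]``; decay slope
    ``a2' ~ U[0.001, 40]``; midpoint distance ``L ~ U[1, 27 - t_mid1']``
    (so the second midpoint never exceeds 27); final-asymptote ratio
    ``~ U[0, 0.85]`` with ``I_final = ratio * I_max``; rising slope
    ``a1' = tan(U[0, pi/2])``.
    """
    i_max = rng.uniform(0.3, 20.0)
    t_mid1 = rng.uniform(3.0, 26.0)
    a2 = rng.uniform(0.001, 40.0)
    L = rng.uniform(1.0, 27.0 - t_mid1)
    ratio = rng.uniform(0.0, 0.85)
    a1 = math.tan(rng.uniform(0.0, math.pi / 2.0))
    return DoubleSigmoidalParams(
        I_max=i_max,
        I_final=ratio * i_max,
        t_mid1_prime=t_mid1,
        t_mid2_prime=t_mid1 + L,
        a1_prime=a1,
        a2_prime=a2,
    )


def sample_times(regime: str, rng: np.random.Generator,
                 n: int = N_TIME_POINTS) -> np.ndarray:
    """Draw ``n`` observation times in [3, 30], sorted.

    ``equidistant``: 3.0, 3.5, ..., 30.0 (55 points); ``uniform``:
    U[3, 30]; the three beta regimes: ``27 * Beta(alpha, beta) + 3`` with
    shapes (0.5, 1.5), (2, 2), (1.5, 0.5) concentrating observations at
    the start, center, or end of the window.
    """
    lo, hi = TIME_WINDOW
    if regime == "equidistant":
        return lo + 0.5 * np.arange(n)
    if regime == "uniform":
        return np.sort(rng.uniform(lo, hi, size=n))
    if regime in _BETA_SHAPES:
        alpha, beta = _BETA_SHAPES[regime]
        return np.sort((hi - lo) * rng.beta(alpha, beta, size=n) + lo)
    raise ValueError(f"unknown sampling regime {regime!r}")


def add_noise(
    intensities,
    noise_type: str,
    amplitude: float,
    rng: np.random.Generator,
    multiplicative_mode: str = "centered",
) -> np.ndarray:
    """Apply one independent noise draw per observation.

    Additive: ``I + u * amplitude * max(I)`` with ``u ~ U[-0.5, 0.5]``.
    Multiplicative: per-point factors ``2**x`` with ``x ~ U[-1, 1]``; the
    default "centered" form ``I * (1 + amplitude * (2**x - 1))`` reduces
    to the identity at amplitude 0, while the "literal" form
    ``I * amplitude * 2**x`` scales the whole signal by the amplitude.
    """
    y = np.asarray(intensities, dtype=float)
    if not (0.0 <= amplitude <= 1.5):
        raise ValueError("amplitude must lie in [0, 1.5]")
    if noise_type == "additive":
        u = rng.uniform(-0.5, 0.5, size=y.size)
        return y + u * amplitude * np.max(y)
    if noise_type == "multiplicative":
        factor = 2.0 ** rng.uniform(-1.0, 1.0, size=y.size)
        if multiplicative_mode == "centered":
            return y * (1.0 + amplitude * (factor - 1.0))
        if multiplicative_mode == "literal":
            return y * (amplitude * factor)
        raise ValueError("multiplicative_mode must be 'centered' or 'literal'")
    raise ValueError(f"unknown noise type {noise_type!r}")


def clean_curve(model_kind: str, params, times: np.ndarray) -> np.ndarray:
    """Noise-free intensities of the truth model at the given times."""
    if model_kind == SIGMOIDAL:
        return eval_sigmoidal(times, params)
    return eval_double_sigmoidal(times, params)


def is_classifiable_as_truth(
    model_kind: str,
    params,
    times: np.ndarray,
    cfg: DecisionConfig | None = None,
) -> bool:
    """Would the noise-free curve, by definition, be classified as its
    own model?

    Applies the decision-tree checks to the truth curve on the same
    min-max normalized scale the classifier uses: the no-signal cutoffs on
    the raw maximum and range; starting intensity below the cap; the
    tangent start of growth (and, for a double-sigmoidal truth, of decay)
    after the first observation; and the end-ratio gate — above 0.85 for
    a sigmoidal truth, below 0.75 for a double-sigmoidal truth.  Used to
    reject by-definition-ambiguous parameter sets before benchmarking.
    """
    if cfg is None:
        cfg = DecisionConfig()
    clean = clean_curve(model_kind, params, times)
    y_min, y_max = float(np.min(clean)), float(np.max(clean))
    y_range = y_max - y_min
    if check_no_signal(y_max, y_range, cfg):
        return False
    t_first, t_last = float(times[0]), float(times[-1])
    # checks are evaluated on the min-max normalized scale the classifier
    # uses, approximating the fitted curve by the truth curve
    start_int = (float(clean[0]) - y_min) / y_range
    if not start_int < cfg.max_start_intensity:
        return False
    end_ratio = (float(clean[-1]) - y_min) / (params.I_max - y_min)

    if model_kind == SIGMOIDAL:
        if not end_ratio > cfg.min_end_ratio_sigmoidal:
            return False
        # tangent start of growth must fall after the first observation
        return params.t_mid - 2.0 / params.a1 > t_first

    if not end_ratio < cfg.max_end_ratio_double:
        return False
    span = t_last - t_first
    derived = derive_double_sigmoidal(params, t_last, fd_step=1e-6 * span)
    if not derived.available:
        return False
    return (
        derived.start_time > t_first
        and t_first < derived.decay_start_time < t_last
    )


_MAX_TRIES_PER_SAMPLE = 1000


def generate_sample(
    spec: SimulationSpec,
    replicate: int,
    rng: np.random.Generator,
    decision_cfg: DecisionConfig | None = None,
) -> SimulatedSample:
    """Draw one accepted parameter set and its clean and noisy vectors.

    Rejected draws (by-definition-unclassifiable parameter sets) are
    resampled from the same stream; more than ~99% rejection raises
    :class:`ConfigurationError`.
    """
    times = sample_times(spec.sampling_regime, rng)
    for _ in range(_MAX_TRIES_PER_SAMPLE):
        if spec.model_kind == SIGMOIDAL:
            params = sample_sigmoidal_params(rng)
        else:
            params = sample_double_params(rng)
        if is_classifiable_as_truth(spec.model_kind, params, times, decision_cfg):
            break
    else:
        raise ConfigurationError(
            f"rejected {_MAX_TRIES_PER_SAMPLE} consecutive parameter draws "
            f"for cell {spec!r}; check thresholds"
        )
    clean = clean_curve(spec.model_kind, params, times)
    noisy = add_noise(
        clean, spec.noise_type, spec.noise_amplitude, rng,
        multiplicative_mode=spec.multiplicative_mode,
    )
    sample_id = (
        f"{spec.model_kind}-{spec.sampling_regime}-{spec.noise_type}"
        f"-a{spec.noise_amplitude:.2f}-r{replicate:03d}"
    )
    return SimulatedSample(
        sample_id=sample_id,
        model_kind=spec.model_kind,
        sampling_regime=spec.sampling_regime,
        noise_type=spec.noise_type,
        noise_amplitude=spec.noise_amplitude,
        replicate=replicate,
        true_params=params,
        times=times,
        clean_intensities=np.asarray(clean, dtype=float),
        noisy_intensities=np.asarray(noisy, dtype=float),
    )


def _cells(grid: GridSpec):
    return list(
        itertools.product(grid.models, grid.regimes, grid.noise_types,
                          grid.amplitudes)
    )


def grid_size(grid: GridSpec) -> int:
    """Number of parameter sets the grid will draw (no generation)."""
    return len(_cells(grid)) * grid.n_replicates


def generate_grid(grid: GridSpec) -> list[SimulatedSample]:
    """Generate every sample of the grid, deterministically.

    Each (model, regime, noise type, amplitude) cell receives
    ``n_replicates`` freshly drawn parameter sets.  The seed tree is
    ``SeedSequence(grid.seed)`` spawned once per cell (in the fixed
    itertools.product order) and once more per replicate.
    """
    root = np.random.SeedSequence(grid.seed)
    cells = _cells(grid)
    cell_seeds = root.spawn(len(cells))
    samples: list[SimulatedSample] = []
    for (model, regime, noise_type, amplitude), cell_seed in zip(cells, cell_seeds):
        spec = SimulationSpec(
            model_kind=model,
            sampling_regime=regime,
            noise_type=noise_type,
            noise_amplitude=amplitude,
            n_replicates=grid.n_replicates,
            seed=grid.seed,
            multiplicative_mode=grid.multiplicative_mode,
        )
        for replicate, rep_seed in enumerate(cell_seed.spawn(grid.n_replicates)):
            rng = np.random.default_rng(rep_seed)
            samples.append(
                generate_sample(spec, replicate, rng, grid.decision_cfg)
            )
    return samples
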