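"""The decision tree labeling a time course.

A curve is labeled ``no_signal`` when its raw maximum intensity or raw
intensity range falls at or below user-set cutoffs.  Otherwise both models
are fitted on the normalized data and each fit must pass a battery of
checks: it converged; its AIC is below a threshold (default -10); its
tangent-derived start of growth (and, for the double-sigmoidal, start of
decay) is positive, with the decay additionally required to begin before
the last observation; its predicted intensity at the first observation is
below a cap (default 0.05, normalized); and its end ratio — prediction at
the last observation over maximum prediction — is above 0.85 (sigmoidal)
or below 0.75 (double-sigmoidal).  If both fits fail the curve is
``ambiguous``; if exactly one passes, that label wins; if both pass, the
lower AIC wins (after optional per-model AIC bonuses; an exact tie goes to
the simpler, sigmoidal, model).

All cutoffs are heuristics and are configurable; none are hardcoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_models import eval_double_sigmoidal, eval_sigmoidal
from .derived_params import (
    DerivedParameters,
    denormalize_derived,
    derive_double_sigmoidal,
    derive_sigmoidal,
)
from .fitting import DOUBLE_SIGMOIDAL, SIGMOIDAL, FitConfig, FitResult, fit_model
from .normalization import NormalizationRecord, NoSignalError, TimeCourse, normalize

__all__ = [
    "NO_SIGNAL",
    "AMBIGUOUS",
    "CATEGORIES",
    "DecisionConfig",
    "ModelAssessment",
    "ClassificationReport",
    "check_no_signal",
    "check_model",
    "decide",
    "fit_and_categorize",
]

NO_SIGNAL = "no_signal"
AMBIGUOUS = "ambiguous"
CATEGORIES = (NO_SIGNAL, SIGMOIDAL, DOUBLE_SIGMOIDAL, AMBIGUOUS)


@dataclass(frozen=True)
class DecisionConfig:
    """Every cutoff of the decision tree.

    ``min_intensity_max`` and ``min_intensity_range`` apply to *raw*
    intensities before normalization; all other thresholds apply on the
    normalized scale.  Comparisons are strict: a fit passes with AIC
    strictly below ``aic_threshold``, end ratio strictly above 0.85
    (sigmoidal) or strictly below 0.75 (double-sigmoidal).
    """

    min_intensity_max: float = 0.1
    min_intensity_range: float = 0.1
    aic_threshold: float = -10.0
    max_start_intensity: float = 0.05
    min_end_ratio_sigmoidal: float = 0.85
    max_end_ratio_double: float = 0.75
    aic_bonus_sigmoidal: float = 0.0
    aic_bonus_double: float = 0.0

    def __post_init__(self) -> None:
        for name in ("min_end_ratio_sigmoidal", "max_end_ratio_double"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class ModelAssessment:
    """One model's fit, derived descriptors, and check outcomes."""

    fit: FitResult
    derived: DerivedParameters | None
    derived_raw: DerivedParameters | None
    start_intensity: float | None
    passed: bool
    checks: dict
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class ClassificationReport:
    """Final category plus every intermediate outcome, replayable."""

    category: str
    decisive_rule: str
    raw_max: float
    raw_range: float
    record: NormalizationRecord | None = None
    sigmoidal: ModelAssessment | None = None
    double: ModelAssessment | None = None
    config: DecisionConfig = field(default_factory=DecisionConfig)


def check_no_signal(raw_max: float, raw_range: float,
                    cfg: DecisionConfig) -> bool:
    """True (no signal) iff the raw maximum or the raw range fails to
    exceed its cutoff — either test failing suffices."""
    return raw_max <= cfg.min_intensity_max or raw_range <= cfg.min_intensity_range


def _start_intensity(fit: FitResult, first_obs_time: float) -> float:
    p = fit.params_normalized
    if fit.model_kind == SIGMOIDAL:
        return float(eval_sigmoidal(first_obs_time, p))
    return float(eval_double_sigmoidal(first_obs_time, p))


def check_model(
    fit: FitResult,
    derived: DerivedParameters | None,
    cfg: DecisionConfig,
    kind: str,
    first_obs_time: float,
    last_obs_time: float = 1.0,
) -> tuple[bool, tuple[str, ...], dict]:
    """Run every acceptance check for one model's fit.

    Returns (passed, reasons-for-failure, per-check booleans).  The
    "starting intensity" is the model's prediction at the earliest
    observed time on the normalized scale.  For the double-sigmoidal
    model the decay must also *begin* before the last observation: a
    fitted maximum beyond the window end can satisfy the end-ratio gate
    purely by extrapolation, claiming a decay the data never shows.
    """
    checks: dict = {}
    reasons: list[str] = []

    checks["converged"] = fit.converged
    if not fit.converged:
        return False, ("no_fit",), checks

    checks["aic"] = fit.aic < cfg.aic_threshold
    if not checks["aic"]:
        reasons.append("aic")

    if derived is None or not derived.available:
        checks["derived_available"] = False
        reasons.append("derived_unavailable")
        return False, tuple(reasons), checks
    checks["derived_available"] = True

    checks["start_time_positive"] = derived.start_time > 0.0
    if not checks["start_time_positive"]:
        reasons.append("start_time")

    if kind == DOUBLE_SIGMOIDAL:
        checks["decay_start_time_positive"] = derived.decay_start_time > 0.0
        if not checks["decay_start_time_positive"]:
            reasons.append("decay_start_time")
        checks["decay_within_window"] = (
            derived.decay_start_time < last_obs_time
        )
        if not checks["decay_within_window"]:
            reasons.append("decay_not_observed")

    start_int = _start_intensity(fit, first_obs_time)
    checks["start_intensity"] = start_int < cfg.max_start_intensity
    if not checks["start_intensity"]:
        reasons.append("start_intensity")

    if kind == SIGMOIDAL:
        checks["end_ratio"] = derived.end_ratio > cfg.min_end_ratio_sigmoidal
    else:
        checks["end_ratio"] = derived.end_ratio < cfg.max_end_ratio_double
    if not checks["end_ratio"]:
        reasons.append("end_ratio")

    return not reasons, tuple(reasons), checks


def decide(
    sig: tuple[bool, FitResult],
    dbl: tuple[bool, FitResult],
    cfg: DecisionConfig,
) -> tuple[str, str]:
    """Combine the two check outcomes into a category.

    Both fail -> ambiguous; exactly one passes -> that label; both pass ->
    the smaller bonus-adjusted AIC wins, with an exact tie going to the
    simpler (sigmoidal) model.  A bonus can bias the comparison but can
    never rescue a model that failed its checks.
    """
    sig_ok, sig_fit = sig
    dbl_ok, dbl_fit = dbl
    if not sig_ok and not dbl_ok:
        return AMBIGUOUS, "both_failed"
    if sig_ok and not dbl_ok:
        return SIGMOIDAL, "only_sigmoidal_passed"
    if dbl_ok and not sig_ok:
        return DOUBLE_SIGMOIDAL, "only_double_passed"
    sig_score = sig_fit.aic + cfg.aic_bonus_sigmoidal
    dbl_score = dbl_fit.aic + cfg.aic_bonus_double
    if dbl_score < sig_score:
        return DOUBLE_SIGMOIDAL, "aic_comparison"
    return SIGMOIDAL, "aic_comparison"


def fit_and_categorize(
    tc: TimeCourse,
    fit_cfg: FitConfig | None = None,
    decision_cfg: DecisionConfig | None = None,
) -> ClassificationReport:
    """Full pipeline: signal check, normalization, both fits, decision.

    The report records raw-scale fitted parameters and derived
    descriptors alongside the normalized ones, plus every intermediate
    check, so the final category can be replayed from the report alone.
    """
    if fit_cfg is None:
        fit_cfg = FitConfig()
    if decision_cfg is None:
        decision_cfg = DecisionConfig()

    raw_max = tc.max_intensity
    raw_range = tc.intensity_range
    if check_no_signal(raw_max, raw_range, decision_cfg):
        return ClassificationReport(
            category=NO_SIGNAL, decisive_rule="no_signal",
            raw_max=raw_max, raw_range=raw_range, config=decision_cfg,
        )
    try:
        tc_norm, rec = normalize(tc)
    except NoSignalError:
        return ClassificationReport(
            category=NO_SIGNAL, decisive_rule="no_signal",
            raw_max=raw_max, raw_range=raw_range, config=decision_cfg,
        )

    first_t = float(tc_norm.times[0])
    last_t = float(tc_norm.times[-1])
    assessments: dict[str, ModelAssessment] = {}
    for kind in (SIGMOIDAL, DOUBLE_SIGMOIDAL):
        fit = fit_model(tc_norm, kind, fit_cfg, rec=rec)
        derived = derived_raw = None
        if fit.converged:
            if kind == SIGMOIDAL:
                derived = derive_sigmoidal(fit.params_normalized, last_t)
            else:
                derived = derive_double_sigmoidal(fit.params_normalized, last_t)
            derived_raw = denormalize_derived(derived, rec)
        passed, reasons, checks = check_model(
            fit, derived, decision_cfg, kind, first_t, last_t
        )
        start_int = (
            _start_intensity(fit, first_t) if fit.converged else None
        )
        assessments[kind] = ModelAssessment(
            fit=fit, derived=derived, derived_raw=derived_raw,
            start_intensity=start_int, passed=passed, checks=checks,
            reasons=reasons,
        )

    category, rule = decide(
        (assessments[SIGMOIDAL].passed, assessments[SIGMOIDAL].fit),
        (assessments[DOUBLE_SIGMOIDAL].passed, assessments[DOUBLE_SIGMOIDAL].fit),
        decision_cfg,
    )
    return ClassificationReport(
        category=category,
        decisive_rule=rule,
        raw_max=raw_max,
        raw_range=raw_range,
        record=rec,
        sigmoidal=assessments[SIGMOIDAL],
        double=assessments[DOUBLE_SIGMOIDAL],
        config=decision_cfg,
    )
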