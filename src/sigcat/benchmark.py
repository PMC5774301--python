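"""Run the classifier over a simulation grid and summarize its accuracy.

For every simulated sample the full pipeline is run on the *noisy* data
and two things are recorded: the predicted category, and the normalized
mean absolute error (NMAE) between the *noise-free* truth curve and the
fitted model's prediction at the sample's observation times,

    NMAE = mean(|clean - predicted|) / max(clean),

computed regardless of whether the predicted category matches the truth.
When the sample is labeled ambiguous the lower-AIC converged fit supplies
the prediction; when neither model converged (or the sample is labeled
no-signal, so no fit was attempted) the NMAE is recorded as missing and
excluded from cell means.

Aggregation is per grid cell (truth model, sampling regime, noise type,
amplitude): the fraction of samples per predicted category and the mean
NMAE — the classifier-robustness and fit-accuracy summaries as functions
of noise level.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .categorize import (
    AMBIGUOUS,
    CATEGORIES,
    ClassificationReport,
    DecisionConfig,
    fit_and_categorize,
)
from .core_models import eval_double_sigmoidal, eval_sigmoidal
from .fitting import DOUBLE_SIGMOIDAL, SIGMOIDAL, FitConfig
from .normalization import TimeCourse
from .simulate import SimulatedSample

__all__ = ["nmae", "prediction_curve", "run_benchmark"]


def nmae(clean, predicted) -> float:
    """Mean absolute error normalized by the maximum of the clean vector.

    Invariant under joint rescaling of both vectors.
    """
    c = np.asarray(clean, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if c.size == 0 or c.shape != p.shape:
        raise ValueError("clean and predicted must be equal-length, nonempty")
    m = float(np.max(c))
    if m <= 0:
        raise ValueError("max(clean) must be positive")
    return float(np.mean(np.abs(c - p)) / m)


def prediction_curve(
    report: ClassificationReport, times: np.ndarray
) -> tuple[str | None, np.ndarray | None]:
    """The fitted curve used for the error metric, on the raw scale.

    Returns ``(model_kind, intensities)``: the chosen model's curve when
    the category is sigmoidal or double-sigmoidal; the lower-AIC converged
    fit when ambiguous; ``(None, None)`` when no converged fit exists.
    """
    candidates = []
    if report.category == SIGMOIDAL:
        candidates = [report.sigmoidal]
    elif report.category == DOUBLE_SIGMOIDAL:
        candidates = [report.double]
    elif report.category == AMBIGUOUS:
        fits = [
            a for a in (report.sigmoidal, report.double)
            if a is not None and a.fit.converged
        ]
        if fits:
            candidates = [min(fits, key=lambda a: a.fit.aic)]
    if not candidates or candidates[0] is None or not candidates[0].fit.converged:
        return None, None
    assessment = candidates[0]
    rec = report.record
    params = assessment.fit.params_normalized
    t_norm = (times - rec.time_offset) / rec.time_scale
    if assessment.fit.model_kind == SIGMOIDAL:
        pred_norm = np.asarray(eval_sigmoidal(t_norm, params))
    else:
        pred_norm = np.asarray(eval_double_sigmoidal(t_norm, params))
    return (
        assessment.fit.model_kind,
        rec.intensity_offset + rec.intensity_scale * pred_norm,
    )


def _record(sample: SimulatedSample, report: ClassificationReport) -> dict:
    kind, pred = prediction_curve(report, sample.times)
    err = (
        nmae(sample.clean_intensities, pred) if pred is not None else math.nan
    )
    row: dict = {
        "sample_id": sample.sample_id,
        "true_model": sample.model_kind,
        "sampling_regime": sample.sampling_regime,
        "noise_type": sample.noise_type,
        "noise_amplitude": sample.noise_amplitude,
        "replicate": sample.replicate,
        "predicted_category": report.category,
        "nmae": err,
        "fitted_model": kind,
    }
    for prefix, assessment in (("sig", report.sigmoidal), ("dbl", report.double)):
        if assessment is None or assessment.fit.params_raw is None:
            continue
        row[f"{prefix}_aic"] = assessment.fit.aic
        row[f"{prefix}_passed"] = assessment.passed
        p = assessment.fit.params_raw
        if assessment.fit.model_kind == SIGMOIDAL:
            row.update(sig_I_max=p.I_max, sig_t_mid=p.t_mid, sig_a1=p.a1)
        else:
            row.update(
                dbl_I_max=p.I_max, dbl_I_final=p.I_final,
                dbl_t_mid1_prime=p.t_mid1_prime, dbl_t_mid2_prime=p.t_mid2_prime,
                dbl_a1_prime=p.a1_prime, dbl_a2_prime=p.a2_prime,
            )
    return row


def run_benchmark(
    samples: Sequence[SimulatedSample],
    fit_cfg: FitConfig | None = None,
    decision_cfg: DecisionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample and aggregate per grid cell.

    Returns ``(records, aggregates)``.  ``records`` has one row per
    sample (truth cell, predicted category, NMAE, fitted raw parameters).
    ``aggregates`` has one row per (true_model, sampling_regime,
    noise_type, noise_amplitude) with ``n``, a ``frac_<category>`` column
    per category (summing to 1), ``mean_nmae`` over non-missing values,
    and ``n_nmae_missing``.  Fit failures are recorded, never raised.
    """
    rows = []
    for sample in samples:
        tc = TimeCourse(sample.times, sample.noisy_intensities)
        report = fit_and_categorize(tc, fit_cfg, decision_cfg)
        rows.append(_record(sample, report))
    records = pd.DataFrame(rows)

    keys = ["true_model", "sampling_regime", "noise_type", "noise_amplitude"]
    agg_rows = []
    for cell, group in records.groupby(keys, sort=True):
        row = dict(zip(keys, cell))
        n = len(group)
        row["n"] = n
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = float((group["predicted_category"] == cat).sum()) / n
        row["mean_nmae"] = float(group["nmae"].mean())  # NaNs excluded
        row["n_nmae_missing"] = int(group["nmae"].isna().sum())
        agg_rows.append(row)
    aggregates = pd.DataFrame(agg_rows)
    return records, aggregates
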