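"""File input/output and configuration.

Time courses are read from delimited text (CSV/TSV) with a header row.
Configuration files are flat key-value YAML whose keys match the
:class:`~sigcat.fitting.FitConfig` and
:class:`~sigcat.categorize.DecisionConfig` field names, so every cutoff of
the decision tree can be adjusted without touching code.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .categorize import DecisionConfig
from .fitting import FitConfig
from .normalization import MIN_OBSERVATIONS, TimeCourse

__all__ = [
    "InputError",
    "read_time_course",
    "write_time_course",
    "load_config",
    "save_config",
    "fit_config_from_mapping",
    "decision_config_from_mapping",
]

logger = logging.getLogger("sigcat")


class InputError(ValueError):
    """Malformed user input (missing columns, unparseable values, too few rows)."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_time_course(
    path: str | Path,
    time_column: str = "time",
    intensity_column: str = "intensity",
) -> TimeCourse:
    """Read a (time, intensity) table from delimited text.

    The delimiter is taken from the extension (tab for .tsv/.tab, comma
    otherwise).  Unparseable numeric fields raise :class:`InputError`
    naming the offending row (0-based data-row index); rows containing
    non-finite values are dropped with a logged warning and count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter_for(path))
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: could not read delimited text: {exc}") from exc
    for col in (time_column, intensity_column):
        if col not in df.columns:
            raise InputError(
                f"{path}: missing column {col!r}; available columns: "
                f"{', '.join(map(str, df.columns))}"
            )
    parsed = {}
    for col in (time_column, intensity_column):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: column {col!r}, row {row}: "
                f"could not parse {df[col].iloc[row]!r} as a number"
            )
        parsed[col] = numeric.to_numpy(dtype=float)
    t, y = parsed[time_column], parsed[intensity_column]
    keep = np.isfinite(t) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
    if keep.sum() < MIN_OBSERVATIONS:
        raise InputError(
            f"{path}: only {int(keep.sum())} usable rows; need at least "
            f"{MIN_OBSERVATIONS}"
        )
    return TimeCourse(t[keep], y[keep])


def write_time_course(tc: TimeCourse, path: str | Path) -> None:
    """Write a time course as two-column delimited text."""
    path = Path(path)
    pd.DataFrame({"time": tc.times, "intensity": tc.intensities}).to_csv(
        path, sep=_delimiter_for(path), index=False
    )


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise InputError(f"{path}: config must be a flat key-value mapping")
    return dict(data)


def save_config(config: Mapping, path: str | Path) -> None:
    """Write a flat key-value mapping as YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def _from_mapping(cls, mapping: Mapping, **overrides):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in names}
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return cls(**kwargs)


def fit_config_from_mapping(mapping: Mapping, **overrides) -> FitConfig:
    """Build a FitConfig from flat config keys (unknown keys ignored)."""
    return _from_mapping(FitConfig, mapping, **overrides)


def decision_config_from_mapping(mapping: Mapping, **overrides) -> DecisionConfig:
    """Build a DecisionConfig from flat config keys (unknown keys ignored)."""
    return _from_mapping(DecisionConfig, mapping, **overrides)
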