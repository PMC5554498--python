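"""Split-half reliability of MPIs via the intraclass correlation coefficient.

Reliability is estimated within-trial: the window series of each trial is
split into odd- and even-indexed windows, each half is aggregated like a
normal MPI, and the two half-scores are correlated across subjects with
ICC(2,1) -- the two-way random-effects, absolute-agreement, single-measure
form.  The odd/even interleave (rather than first half vs second half) keeps
the split robust to slow temporal trends such as the bradykinesia sequence
effect, which would otherwise contaminate a contiguous split.

No Spearman-Brown correction is applied: the quantity reported is the ICC of
the half-scores themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    HANDS,
    MEASUREMENTS,
    MOVEMENTS,
    SubjectSession,
    ValidationError,
    WindowConfig,
    mpi_name,
)
from .features import WindowSeries
from .mpi import AxisMap, aggregate_trial, reference_axis_map, trial_series
from .preprocess import preprocess_trial

__all__ = [
    "ReliabilityResult",
    "split_half_scores",
    "icc",
    "split_half_tables",
    "reliability_table",
]


@dataclass
class ReliabilityResult:
    """ICC of one MPI across subjects; ``in_range`` flags ICC outside [0, 1]."""

    mpi_name: str
    icc: float
    n_subjects: int

    @property
    def in_range(self) -> bool:
        return bool(np.isfinite(self.icc) and 0.0 <= self.icc <= 1.0)


def split_half_scores(series: WindowSeries | np.ndarray,
                      aggregate: str = "mean") -> tuple[float, float]:
    """Aggregate odd- and even-indexed windows separately.

    Raises :class:`ValidationError` for a series with fewer than two windows,
    which cannot be split.
    """
    values = series.values if isinstance(series, WindowSeries) else np.asarray(series, float)
    if values.size < 2:
        raise ValidationError("cannot split a series with fewer than 2 windows")
    return (aggregate_trial(values[0::2], aggregate),
            aggregate_trial(values[1::2], aggregate))


def icc(half1: np.ndarray, half2: np.ndarray) -> float:
    """ICC(2,1) of an ``n x 2`` score matrix given as two columns.

    Two-way random effects, absolute agreement, single measure.  Returns NaN
    (flagged undefined) when the between-subject variance is zero or the
    denominator vanishes.  Requires at least 5 subjects.
    """
    y = np.column_stack([np.asarray(half1, float), np.asarray(half2, float)])
    n, k = y.shape
    if n < 5:
        raise ValidationError(f"ICC needs >= 5 subjects, got {n}")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msb = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_rows <= 0:
        return float("nan")
    denom = msb + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msb - mse) / denom)


def split_half_tables(sessions: Iterable[SubjectSession],
                      axis_map: AxisMap | None = None,
                      config: WindowConfig | None = None,
                      movements: Sequence[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject half-score tables (same layout as a cohort MPI table)."""
    config = config or WindowConfig()
    axis_map = axis_map or reference_axis_map()
    movements = tuple(movements) if movements is not None else MOVEMENTS
    rows1, rows2, index = [], [], []
    for session in sessions:
        h1: dict[str, float] = {}
        h2: dict[str, float] = {}
        for mov in movements:
            for hand in HANDS:
                ptrial = preprocess_trial(session.trial(mov, hand), config)
                for meas in MEASUREMENTS:
                    series = trial_series(ptrial, meas, config, axis_map)
                    a, b = split_half_scores(series, config.aggregate)
                    name = mpi_name(meas, mov, hand)
                    h1[name] = a
                    h2[name] = b
        rows1.append(h1)
        rows2.append(h2)
        index.append(session.subject_id)
    idx = pd.Index(index, name="subject_id")
    return pd.DataFrame(rows1, index=idx), pd.DataFrame(rows2, index=idx)


def reliability_table(sessions: Sequence[SubjectSession],
                      axis_map: AxisMap | None = None,
                      config: WindowConfig | None = None,
                      movements: Sequence[str] | None = None) -> pd.DataFrame:
    """ICC(2,1) per MPI across subjects, as a tidy one-row-per-MPI table."""
    half1, half2 = split_half_tables(sessions, axis_map, config, movements)
    rows = []
    for name in half1.columns:
        value = icc(half1[name].to_numpy(), half2[name].to_numpy())
        rows.append({
            "mpi_name": name,
            "icc": value,
            "n_subjects": len(half1),
            "in_range": bool(np.isfinite(value) and 0.0 <= value <= 1.0),
        })
    return pd.DataFrame(rows).set_index("mpi_name")
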