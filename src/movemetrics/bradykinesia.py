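"""Slowness and sequence-effect quantification from window-series evolution.

Bradykinesia shows up in the temporal evolution of the basic measurements in
two ways: patients need more time to complete a fixed number of repetitions
(slowness, measured as the energy-segmented movement duration), and the
per-repetition amplitude progressively shrinks -- the "sequence effect".

The sequence effect is operationalized as the ordinary-least-squares slope
of the window series against window index, divided by the series mean.  The
normalized slope is a dimensionless fractional change per window, invariant
to positive rescaling of the signal; a negative slope with a significant
two-sided trend test (t-test of the OLS slope, or the Mann-Kendall tau test
as a nonparametric option) is reported as a detected sequence effect.
By default the analysis targets the tapping trials (TT-P, TT-D), whose 30 s
recordings provide enough windows for a stable trend estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    HANDS,
    SubjectSession,
    Trial,
    ValidationError,
    WindowConfig,
)
from .features import WindowSeries
from .mpi import AxisMap, reference_axis_map, trial_series
from .preprocess import energy_segment, preprocess_trial

__all__ = [
    "SequenceEffectResult",
    "movement_duration",
    "sequence_effect",
    "cohort_sequence_table",
]

#: Movements analysed for the sequence effect by default: the tapping tasks.
DEFAULT_SEQUENCE_MOVEMENTS: tuple[str, ...] = ("TT-P", "TT-D")


@dataclass
class SequenceEffectResult:
    measurement: str
    slope_per_window: float  # fraction of the series mean, per window
    trend_p: float
    duration_s: float | None = None
    n_windows: int = 0
    method: str = "ols"

    @property
    def detected(self) -> bool:
        """Sequence effect present: significant negative trend."""
        return bool(np.isfinite(self.slope_per_window)
                    and self.slope_per_window < 0 and self.trend_p < 0.05)


def movement_duration(trial: Trial, config: WindowConfig | None = None,
                      sensor: str = "gyro") -> float:
    """Energy-segmented active duration of a trial, in seconds.

    The gyroscope is the default duration sensor: angular velocity tracks the
    movement itself, whereas EMG burst energy fluctuates with the stochastic
    muscle-activity carrier and gives noisier endpoints.
    """
    config = config or WindowConfig()
    if sensor == "emg":
        sig, rate = trial.emg, trial.sample_rate_emg
        cutoff, order = config.emg_cutoff_hz, config.emg_filter_order
    elif sensor in ("acc", "gyro"):
        sig = trial.acc if sensor == "acc" else trial.gyro
        rate = trial.sample_rate_imu
        cutoff, order = config.imu_cutoff_hz, config.imu_filter_order
    else:
        raise ValidationError(f"unknown sensor {sensor!r}")
    from .preprocess import butterworth_lowpass

    filtered = butterworth_lowpass(sig, rate, cutoff, order)
    start, end = energy_segment(filtered, rate, config.energy_threshold_frac,
                                config.energy_window_ms)
    return (end - start) / rate


def sequence_effect(series: WindowSeries | np.ndarray,
                    method: Literal["ols", "mann-kendall"] = "ols",
                    duration_s: float | None = None) -> SequenceEffectResult:
    """Normalized trend of a window series.

    Requires at least 5 windows.  A series mean of zero leaves the
    normalized slope undefined (NaN, flagged via ``detected`` being False).
    """
    if isinstance(series, WindowSeries):
        values = series.values
        measurement = series.measurement
    else:
        values = np.asarray(series, dtype=float)
        measurement = "emg-mav"
    if values.size < 5:
        raise ValidationError("sequence effect needs >= 5 windows")
    mean = values.mean()
    idx = np.arange(values.size, dtype=float)
    if mean == 0:
        return SequenceEffectResult(measurement=measurement,
                                    slope_per_window=float("nan"),
                                    trend_p=float("nan"),
                                    duration_s=duration_s,
                                    n_windows=values.size, method=method)
    fit = stats.linregress(idx, values)
    slope_norm = float(fit.slope / mean)
    if method == "ols":
        p = float(fit.pvalue)
    elif method == "mann-kendall":
        tau = stats.kendalltau(idx, values)
        p = float(tau.pvalue)
    else:
        raise ValidationError(f"unknown trend method {method!r}")
    return SequenceEffectResult(measurement=measurement,
                                slope_per_window=slope_norm, trend_p=p,
                                duration_s=duration_s,
                                n_windows=int(values.size), method=method)


def cohort_sequence_table(sessions: Iterable[SubjectSession],
                          movements: Sequence[str] = DEFAULT_SEQUENCE_MOVEMENTS,
                          measurements: Sequence[str] = ("emg-mav", "gyro-ssi"),
                          axis_map: AxisMap | None = None,
                          config: WindowConfig | None = None,
                          method: Literal["ols", "mann-kendall"] = "ols"
                          ) -> pd.DataFrame:
    """Per-subject, per-trial sequence-effect slopes, p-values and durations."""
    config = config or WindowConfig()
    axis_map = axis_map or reference_axis_map()
    rows = []
    for session in sessions:
        for movement in movements:
            for hand in HANDS:
                if not session.has_trial(movement, hand):
                    continue
                trial = session.trial(movement, hand)
                duration = movement_duration(trial, config)
                ptrial = preprocess_trial(trial, config)
                for meas in measurements:
                    series = trial_series(ptrial, meas, config, axis_map)
                    res = sequence_effect(series, method=method,
                                          duration_s=duration)
                    rows.append({
                        "subject_id": session.subject_id,
                        "group": session.group,
                        "hy_stage": session.hy_stage,
                        "movement": movement,
                        "hand": hand,
                        "measurement": meas,
                        "slope_per_window": res.slope_per_window,
                        "trend_p": res.trend_p,
                        "duration_s": duration,
                        "n_windows": res.n_windows,
                        "detected": res.detected,
                    })
    return pd.DataFrame(rows)
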