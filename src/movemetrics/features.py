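"""Sliding-window basic measurements.

Seven window-level statistics characterize signal amplitude:

* EMG (on the filtered signal of the channel of interest):
  mean absolute value ``mav = mean(|x|)``, variance ``var = mean(x**2)``
  (the mean square as defined for this protocol -- no mean subtraction),
  and waveform change ``wc = sum(|x[t+1] - x[t]|)``.
* ACC/GYRO (on the time-derivative of the axis of interest): simple square
  integral ``ssi = sum(xdot**2)`` and range ``ran = max(xdot) - min(xdot)``.

The derivative is computed once on the segmented, filtered axis signal and
then windowed, so window boundaries do not lose interior samples; it is
scaled to physical per-second units, which makes SSI and RAN sample-rate
invariant up to discretization.

Windows are ``window_ms`` long with 25 % overlap by default (200 ms / 50 ms
for EMG at 200 Hz, 800 ms / 200 ms for the IMU at 50 Hz); a trailing
remainder shorter than one step is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .data_model import (
    EMG_MEASUREMENTS,
    IMU_MEASUREMENTS,
    MEASUREMENTS,
    ValidationError,
    WindowConfig,
)
from .preprocess import PreprocessedTrial

__all__ = [
    "WindowSeries",
    "sliding_windows",
    "emg_mav",
    "emg_var",
    "emg_wc",
    "time_derivative",
    "ssi",
    "ran",
    "measurement_series",
    "window_series",
]


@dataclass
class WindowSeries:
    """Per-window values of one basic measurement over one trial."""

    measurement: str
    values: np.ndarray
    window_times: np.ndarray  # window start times, seconds from trial start
    movement: str | None = None
    hand: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_times = np.asarray(self.window_times, dtype=float)
        if self.measurement not in MEASUREMENTS:
            raise ValidationError(f"unknown measurement {self.measurement!r}")
        if self.values.shape != self.window_times.shape:
            raise ValidationError("values and window_times must align")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("window values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def sliding_windows(n_samples: int, window: int, step: int) -> np.ndarray:
    """Start indices of full windows: ``floor((n - window)/step) + 1`` spans."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if n_samples < window:
        raise ValueError(f"series of {n_samples} samples shorter than one "
                         f"window ({window})")
    count = (n_samples - window) // step + 1
    return np.arange(count) * step


def _window_view(x: np.ndarray, window: int, step: int) -> np.ndarray:
    starts = sliding_windows(x.shape[-1], window, step)
    return sliding_window_view(x, window, axis=-1)[starts], starts


# -- scalar window statistics ------------------------------------------------

def _check_window(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return w


def emg_mav(window: np.ndarray) -> float:
    """Mean absolute value of one window."""
    w = _check_window(window)
    return float(np.abs(w).mean())


def emg_var(window: np.ndarray) -> float:
    """Mean square of one window (no mean subtraction)."""
    w = _check_window(window)
    return float((w ** 2).mean())


def emg_wc(window: np.ndarray) -> float:
    """Waveform change: total absolute sample-to-sample variation."""
    w = _check_window(window)
    return float(np.abs(np.diff(w)).sum())


def ssi(derivative_window: np.ndarray) -> float:
    """Simple square integral: sum of squared derivative samples."""
    w = _check_window(derivative_window)
    return float((w ** 2).sum())


def ran(derivative_window: np.ndarray) -> float:
    """Range max - min of a derivative window."""
    w = _check_window(derivative_window)
    return float(w.max() - w.min())


def time_derivative(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """First difference scaled to units/second; output is one sample shorter."""
    x = np.asarray(x, dtype=float)
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return np.diff(x, axis=-1) * sample_rate


# -- vectorized per-series evaluation ---------------------------------------

def measurement_series(x: np.ndarray, measurement: str, window: int,
                       step: int) -> np.ndarray:
    """Apply one basic measurement to every sliding window of ``x``."""
    V, _ = _window_view(np.asarray(x, dtype=float), window, step)
    if measurement == "emg-mav":
        return np.abs(V).mean(axis=1)
    if measurement == "emg-var":
        return (V ** 2).mean(axis=1)
    if measurement == "emg-wc":
        return np.abs(np.diff(V, axis=1)).sum(axis=1)
    if measurement in ("acc-ssi", "gyro-ssi"):
        return (V ** 2).sum(axis=1)
    if measurement in ("acc-ran", "gyro-ran"):
        return V.max(axis=1) - V.min(axis=1)
    raise ValidationError(f"unknown measurement {measurement!r}")


def window_series(ptrial: PreprocessedTrial, measurement: str,
                  channel_or_axis: int, config: WindowConfig | None = None) -> WindowSeries:
    """Window series of one measurement on a preprocessed trial.

    ``channel_or_axis`` is a 0-based index: EMG channel 0-7 for the EMG
    measurements, IMU axis 0-2 (x, y, z) for the ACC/GYRO ones.
    """
    config = config or WindowConfig()
    if measurement in EMG_MEASUREMENTS:
        if not 0 <= channel_or_axis < 8:
            raise ValidationError(f"EMG channel index {channel_or_axis} out of range")
        sig = ptrial.emg_active(channel_or_axis)
        rate = ptrial.sample_rate_emg
        window = config.window_samples("emg", rate)
        step = config.step_samples("emg", rate)
        offset = ptrial.emg_span[0]
    elif measurement in IMU_MEASUREMENTS:
        if not 0 <= channel_or_axis < 3:
            raise ValidationError(f"IMU axis index {channel_or_axis} out of range")
        sensor = "acc" if measurement.startswith("acc") else "gyro"
        rate = ptrial.sample_rate_imu
        sig = time_derivative(ptrial.imu_active(sensor, channel_or_axis), rate)
        window = config.window_samples("imu", rate)
        step = config.step_samples("imu", rate)
        offset = ptrial.imu_span[0]
    else:
        raise ValidationError(f"unknown measurement {measurement!r}")
    values = measurement_series(sig, measurement, window, step)
    starts = sliding_windows(sig.shape[-1], window, step)
    times = (starts + offset) / rate
    return WindowSeries(measurement=measurement, values=values,
                        window_times=times, movement=ptrial.movement,
                        hand=ptrial.hand)
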