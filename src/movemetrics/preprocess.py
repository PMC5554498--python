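"""Noise filtering and temporal segmentation of raw sensor signals.

Filtering is a zero-phase (forward-backward) Butterworth low-pass: offline
analysis does not need causality, and zero-phase application avoids the group
delay that would misalign the EMG and IMU window grids.  The effective
attenuation order therefore doubles relative to a single pass.

Segmentation trims the quiet lead-in/lead-out of a trial with an energy
threshold: the signal energy ``sum(x**2)`` is computed in consecutive
non-overlapping short windows (250 ms by default) on the channel-summed
squared signal, and the retained span runs from the first to the last window
whose energy reaches ``energy_threshold_frac`` (0.4) of the maximum window
energy.  Indices are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_model import ConfigError, SegmentationError, Trial, WindowConfig

__all__ = [
    "butterworth_lowpass",
    "energy_segment",
    "PreprocessedTrial",
    "preprocess_trial",
]


def butterworth_lowpass(x: np.ndarray, sample_rate: float, cutoff: float,
                        order: int) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    DC gain is exactly 1 and the output has the same length as the input.
    Raises :class:`ConfigError` if ``cutoff`` is at or above the Nyquist
    frequency, and :class:`ValueError` if the signal is too short for the
    forward-backward edge padding.
    """
    x = np.asarray(x, dtype=float)
    if sample_rate <= 0:
        raise ConfigError("sample_rate must be positive")
    if not 0 < cutoff < sample_rate / 2:
        raise ConfigError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)"
        )
    if order < 1:
        raise ConfigError("filter order must be >= 1")
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for order-{order} "
            f"zero-phase filtering (needs > {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def energy_segment(x: np.ndarray, sample_rate: float,
                   threshold_frac: float = 0.4,
                   window_ms: float = 250.0) -> tuple[int, int]:
    """Active span ``[start, end)`` of a one- or multi-channel signal.

    ``x`` is ``(T,)`` or ``(C, T)``; channels are summed after squaring, so a
    single noisy channel cannot silence the trial.  The result is invariant to
    positive rescaling of the signal.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    if not 0 < threshold_frac <= 1:
        raise ConfigError("threshold_frac must be in (0, 1]")
    w = int(round(window_ms * sample_rate / 1000.0))
    if w < 1:
        raise ConfigError("energy window shorter than one sample")
    n_win = n // w
    if n_win < 1:
        raise SegmentationError("signal shorter than one energy window")
    power = (x[:, : n_win * w] ** 2).sum(axis=0)
    energies = power.reshape(n_win, w).sum(axis=1)
    peak = energies.max()
    if peak <= 0:
        raise SegmentationError("all-zero signal cannot be segmented")
    active = np.flatnonzero(energies >= threshold_frac * peak)
    first, last = int(active[0]), int(active[-1])
    start = first * w
    end = min((last + 1) * w, n)
    return start, end


@dataclass
class PreprocessedTrial:
    """Filtered signals plus the active spans of one trial.

    ``emg``, ``acc`` and ``gyro`` keep the full recording length; ``emg_span``
    and ``imu_span`` are the half-open active sample ranges on the respective
    clocks.  EMG and IMU streams are segmented independently because their
    clocks differ; within the IMU stream, accelerometer and gyroscope rows are
    RMS-normalized before the joint energy computation so neither unit system
    dominates.
    """

    movement: str
    hand: str
    emg: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate_emg: float
    sample_rate_imu: float
    emg_span: tuple[int, int]
    imu_span: tuple[int, int]

    def emg_active(self, channel_index: int) -> np.ndarray:
        s, e = self.emg_span
        return self.emg[channel_index, s:e]

    def imu_active(self, sensor: str, axis: int) -> np.ndarray:
        s, e = self.imu_span
        arr = self.acc if sensor == "acc" else self.gyro
        return arr[axis, s:e]


def _rms_rows(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt((x ** 2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def preprocess_trial(trial: Trial, config: WindowConfig | None = None) -> PreprocessedTrial:
    """Filter all channels of a trial and locate the active spans."""
    config = config or WindowConfig()
    config.validate_rates(trial.sample_rate_emg, trial.sample_rate_imu)
    emg_f = butterworth_lowpass(trial.emg, trial.sample_rate_emg,
                                config.emg_cutoff_hz, config.emg_filter_order)
    acc_f = butterworth_lowpass(trial.acc, trial.sample_rate_imu,
                                config.imu_cutoff_hz, config.imu_filter_order)
    gyro_f = butterworth_lowpass(trial.gyro, trial.sample_rate_imu,
                                 config.imu_cutoff_hz, config.imu_filter_order)
    emg_span = energy_segment(emg_f, trial.sample_rate_emg,
                              config.energy_threshold_frac, config.energy_window_ms)
    imu_stack = np.vstack([_rms_rows(acc_f), _rms_rows(gyro_f)])
    imu_span = energy_segment(imu_stack, trial.sample_rate_imu,
                              config.energy_threshold_frac, config.energy_window_ms)
    return PreprocessedTrial(
        movement=trial.movement,
        hand=trial.hand,
        emg=emg_f,
        acc=acc_f,
        gyro=gyro_f,
        sample_rate_emg=trial.sample_rate_emg,
        sample_rate_imu=trial.sample_rate_imu,
        emg_span=emg_span,
        imu_span=imu_span,
    )
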