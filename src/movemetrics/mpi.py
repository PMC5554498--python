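"""Channel/axis-of-interest selection and assembly of the 84-entry MPI vector.

Every movement performance indicator (MPI) is one basic measurement reduced
to a scalar over the windows of one (movement, hand) trial.  EMG
measurements are extracted from a single channel of interest -- channel 2
for right-hand movements, channel 6 for left-hand movements (the
external-forearm electrodes, fixed after a one-time group-difference
analysis) -- while ACC/GYRO measurements use a per-movement axis of
interest.

The axis of interest can either come from the documented fixed map (the
default, mirroring how the channel convention was frozen) or be selected
data-driven on a reference cohort: per movement and sensor, the axis whose
trial-aggregated measurement maximizes the absolute patient-control group
mean difference, with a two-sided rank-sum check reported alongside.  When
selecting data-driven, do it on a dedicated reference cohort and freeze the
map before any downstream cross-validation, to avoid leaking labels.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    EMG_MEASUREMENTS,
    HANDS,
    IMU_MEASUREMENTS,
    LABEL_COLUMNS,
    MOVEMENTS,
    MPIVector,
    SubjectSession,
    ValidationError,
    WindowConfig,
    mpi_name,
)
from .features import WindowSeries, window_series
from .preprocess import PreprocessedTrial, preprocess_trial
from .synthetic import DOMINANT_AXES

__all__ = [
    "default_emg_channel",
    "emg_channel_index",
    "reference_axis_map",
    "aggregate_trial",
    "trial_series",
    "compute_mpi_vector",
    "build_cohort_table",
    "select_axis_of_interest",
    "select_axis_map",
    "emg_channel_group_differences",
]

AxisMap = Mapping[tuple[str, str], int]


def default_emg_channel(hand: str) -> int:
    """Channel of interest (1-based electrode label): right -> 2, left -> 6."""
    if hand == "R":
        return 2
    if hand == "L":
        return 6
    raise ValidationError(f"unknown hand {hand!r}")


def emg_channel_index(hand: str) -> int:
    """0-based row index of the channel of interest in the EMG matrix."""
    return default_emg_channel(hand) - 1


def reference_axis_map() -> dict[tuple[str, str], int]:
    """The documented fixed (movement, sensor) -> axis map."""
    return {(mov, sensor): axis
            for mov, per_sensor in DOMINANT_AXES.items()
            for sensor, axis in per_sensor.items()}


def aggregate_trial(series: WindowSeries | np.ndarray, how: str = "mean") -> float:
    """Reduce a window series to one scalar MPI value (mean by default)."""
    values = series.values if isinstance(series, WindowSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValidationError("cannot aggregate an empty window series")
    if how == "mean":
        return float(values.mean())
    if how == "median":
        return float(np.median(values))
    if how == "sum":
        return float(values.sum())
    raise ValidationError(f"unknown aggregation {how!r}")


def trial_series(ptrial: PreprocessedTrial, measurement: str,
                 config: WindowConfig, axis_map: AxisMap) -> WindowSeries:
    """Window series of one measurement with the channel/axis convention applied."""
    if measurement in EMG_MEASUREMENTS:
        index = emg_channel_index(ptrial.hand)
    else:
        sensor = "acc" if measurement.startswith("acc") else "gyro"
        index = axis_map[(ptrial.movement, sensor)]
    return window_series(ptrial, measurement, index, config)


def compute_mpi_vector(session: SubjectSession,
                       axis_map: AxisMap | None = None,
                       config: WindowConfig | None = None) -> MPIVector:
    """All 84 MPIs for one subject; requires the full 12-trial session."""
    config = config or WindowConfig()
    axis_map = axis_map or reference_axis_map()
    missing = [(mov, hand) for mov in MOVEMENTS for hand in HANDS
               if not session.has_trial(mov, hand)]
    if missing:
        raise ValidationError(
            f"session {session.subject_id} is missing trials: {missing}"
        )
    values: dict[str, float] = {}
    for mov in MOVEMENTS:
        for hand in HANDS:
            ptrial = preprocess_trial(session.trial(mov, hand), config)
            for meas in EMG_MEASUREMENTS + IMU_MEASUREMENTS:
                series = trial_series(ptrial, meas, config, axis_map)
                values[mpi_name(meas, mov, hand)] = aggregate_trial(
                    series, config.aggregate
                )
    return MPIVector(values)


def _session_mpi_subset(session: SubjectSession, movements: Sequence[str],
                        axis_map: AxisMap, config: WindowConfig) -> dict[str, float]:
    values: dict[str, float] = {}
    for mov in movements:
        for hand in HANDS:
            ptrial = preprocess_trial(session.trial(mov, hand), config)
            for meas in EMG_MEASUREMENTS + IMU_MEASUREMENTS:
                series = trial_series(ptrial, meas, config, axis_map)
                values[mpi_name(meas, mov, hand)] = aggregate_trial(
                    series, config.aggregate
                )
    return values


def build_cohort_table(sessions: Iterable[SubjectSession],
                       axis_map: AxisMap | None = None,
                       config: WindowConfig | None = None,
                       movements: Sequence[str] | None = None) -> pd.DataFrame:
    """Subjects x (MPIs + labels) table; input to every cohort statistic.

    ``movements`` restricts extraction to a protocol subset (the table then
    carries 14 x len(movements) MPI columns instead of 84).
    """
    config = config or WindowConfig()
    axis_map = axis_map or reference_axis_map()
    movements = tuple(movements) if movements is not None else MOVEMENTS
    rows = []
    index = []
    for session in sessions:
        values = _session_mpi_subset(session, movements, axis_map, config)
        values.update({
            "group": session.group,
            "hy_stage": session.hy_stage,
            "affected_side": session.affected_side,
            "updrs3_total": session.updrs3_total,
            "updrs3_brady_sub": session.updrs3_brady_sub,
            "taps_proximal": session.taps_proximal,
            "taps_distal": session.taps_distal,
        })
        rows.append(values)
        index.append(session.subject_id)
    if not rows:
        raise ValidationError("no sessions given")
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    table["hy_stage"] = table["hy_stage"].astype("Int64")
    return table


# ---------------------------------------------------------------------------
# Data-driven channel/axis-of-interest analysis
# ---------------------------------------------------------------------------

def _aggregated_trial_value(session: SubjectSession, movement: str, hand: str,
                            measurement: str, index: int,
                            config: WindowConfig) -> float:
    ptrial = preprocess_trial(session.trial(movement, hand), config)
    series = window_series(ptrial, measurement, index, config)
    return aggregate_trial(series, config.aggregate)


def select_axis_of_interest(sessions: Sequence[SubjectSession], movement: str,
                            sensor: str, measurement: str,
                            config: WindowConfig | None = None,
                            alpha: float = 0.01,
                            override: int | None = None) -> tuple[int, dict]:
    """Axis maximizing the absolute patient-control group-mean difference.

    Subjects contribute the mean of their two hands' trial-aggregated
    measurement values.  Returns ``(axis, evidence)`` where the evidence dict
    carries per-axis group means, the mean differences, the rank-sum p-value
    on the winning axis, and a tie flag (ties break to the lowest axis
    index).  An explicit ``override`` short-circuits the analysis.
    """
    from .group_stats import wilcoxon_ranksum  # local import, avoids cycle

    if sensor not in ("acc", "gyro"):
        raise ValidationError(f"sensor must be 'acc' or 'gyro', got {sensor!r}")
    if measurement not in IMU_MEASUREMENTS or not measurement.startswith(sensor):
        raise ValidationError(
            f"measurement {measurement!r} does not match sensor {sensor!r}"
        )
    if override is not None:
        if not 0 <= override < 3:
            raise ValidationError("axis override out of range")
        return override, {"override": True}
    config = config or WindowConfig()
    groups: dict[str, list[list[float]]] = {"patient": [], "control": []}
    for session in sessions:
        per_axis = [
            np.mean([
                _aggregated_trial_value(session, movement, hand, measurement,
                                        axis, config)
                for hand in HANDS
            ])
            for axis in range(3)
        ]
        groups[session.group].append(per_axis)
    if not groups["patient"] or not groups["control"]:
        raise ValidationError("axis selection needs both patients and controls")
    pat = np.asarray(groups["patient"])
    ctl = np.asarray(groups["control"])
    diffs = np.abs(pat.mean(axis=0) - ctl.mean(axis=0))
    best = int(np.argmax(diffs))
    tie = bool(np.sum(diffs == diffs[best]) > 1)
    test = wilcoxon_ranksum(pat[:, best], ctl[:, best])
    evidence = {
        "patient_means": pat.mean(axis=0).tolist(),
        "control_means": ctl.mean(axis=0).tolist(),
        "abs_mean_differences": diffs.tolist(),
        "p_value": test.p_value,
        "significant": test.p_value < alpha,
        "tie": tie,
        "override": False,
    }
    return best, evidence


def select_axis_map(sessions: Sequence[SubjectSession],
                    config: WindowConfig | None = None,
                    measurements: Mapping[str, str] | None = None,
                    alpha: float = 0.01) -> tuple[dict[tuple[str, str], int], dict]:
    """Data-driven (movement, sensor) -> axis map over the whole protocol.

    ``measurements`` maps sensor -> the measurement used for selection
    (default: the range measurements, acc-ran / gyro-ran).  Compute this on a
    reference cohort and freeze it before fitting classifiers.
    """
    measurements = dict(measurements or {"acc": "acc-ran", "gyro": "gyro-ran"})
    axis_map: dict[tuple[str, str], int] = {}
    evidence: dict = {}
    movements = sorted({t.movement for s in sessions for t in s.trials},
                       key=MOVEMENTS.index)
    for movement in movements:
        for sensor in ("acc", "gyro"):
            axis, ev = select_axis_of_interest(
                sessions, movement, sensor, measurements[sensor], config, alpha
            )
            axis_map[(movement, sensor)] = axis
            evidence[(movement, sensor)] = ev
    return axis_map, evidence


def emg_channel_group_differences(sessions: Sequence[SubjectSession],
                                  movement: str, hand: str,
                                  measurement: str = "emg-mav",
                                  config: WindowConfig | None = None
                                  ) -> pd.DataFrame:
    """Replicates the one-time all-channel analysis behind the 2/6 convention.

    Returns a per-channel table of group means, absolute mean differences and
    rank-sum p-values for one (movement, hand); the channel with the largest
    difference is the data-driven channel of interest.
    """
    from .group_stats import wilcoxon_ranksum

    if measurement not in EMG_MEASUREMENTS:
        raise ValidationError("channel analysis applies to EMG measurements")
    config = config or WindowConfig()
    values: dict[str, list[list[float]]] = {"patient": [], "control": []}
    for session in sessions:
        per_channel = [
            _aggregated_trial_value(session, movement, hand, measurement,
                                    ch, config)
            for ch in range(8)
        ]
        values[session.group].append(per_channel)
    if not values["patient"] or not values["control"]:
        raise ValidationError("channel analysis needs both groups")
    pat = np.asarray(values["patient"])
    ctl = np.asarray(values["control"])
    rows = []
    for ch in range(8):
        test = wilcoxon_ranksum(pat[:, ch], ctl[:, ch])
        rows.append({
            "channel": ch + 1,
            "patient_mean": pat[:, ch].mean(),
            "control_mean": ctl[:, ch].mean(),
            "abs_difference": abs(pat[:, ch].mean() - ctl[:, ch].mean()),
            "p_value": test.p_value,
        })
    return pd.DataFrame(rows).set_index("channel")
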