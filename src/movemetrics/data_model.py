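"""Domain types and plain-text I/O for armband EMG + IMU movement sessions.

The sensor setup mirrors a forearm armband worn during a standardized
six-movement protocol: eight surface-EMG channels sampled at 200 Hz and a
six-axis inertial unit (three-axis accelerometer + three-axis gyroscope)
sampled at 50 Hz.  Each subject performs every movement once with each hand,
so a complete session holds 12 trials.  From every trial, seven window-level
"basic measurements" are reduced to one scalar each, giving the 84 movement
performance indicators (MPIs) that all downstream analyses consume.

On-disk formats are deliberately plain text (comma-separated streams with a
two-line sensor header, flat ``key=value`` manifests and configs) so that
fixtures are inspectable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MOVEMENTS",
    "HANDS",
    "MEASUREMENTS",
    "EMG_MEASUREMENTS",
    "IMU_MEASUREMENTS",
    "MPI_NAMES",
    "LABEL_COLUMNS",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "SegmentationError",
    "Trial",
    "SubjectSession",
    "WindowConfig",
    "MPIVector",
    "mpi_name",
    "parse_mpi_name",
    "read_trial",
    "write_trial",
    "read_session",
    "write_session",
    "read_session_dirs",
    "write_cohort_table",
    "read_cohort_table",
    "validate_cohort_table",
    "read_flat_config",
    "write_flat_config",
]

#: Movement codes of the acquisition protocol: rotation of the hand with the
#: elbow extended / flexed, object grasp-pick-place with easy / heavy load,
#: and the proximal / distal tapping tasks.
MOVEMENTS: tuple[str, ...] = ("RH-EE", "RH-EF", "GPP-EL", "GPP-HL", "TT-P", "TT-D")

HANDS: tuple[str, ...] = ("R", "L")

#: The seven basic measurements.  EMG ones act on the raw (filtered) signal of
#: the channel of interest; ACC/GYRO ones act on the time-derivative of the
#: axis of interest.
EMG_MEASUREMENTS: tuple[str, ...] = ("emg-mav", "emg-var", "emg-wc")
IMU_MEASUREMENTS: tuple[str, ...] = ("acc-ssi", "acc-ran", "gyro-ssi", "gyro-ran")
MEASUREMENTS: tuple[str, ...] = EMG_MEASUREMENTS + IMU_MEASUREMENTS

LABEL_COLUMNS: tuple[str, ...] = (
    "group",
    "hy_stage",
    "affected_side",
    "updrs3_total",
    "updrs3_brady_sub",
    "taps_proximal",
    "taps_distal",
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed range."""


class SegmentationError(ValueError):
    """Temporal segmentation cannot be performed (e.g. an all-zero signal)."""


def mpi_name(measurement: str, movement: str, hand: str) -> str:
    """Canonical MPI key, e.g. ``"gyro-ssi_TT-D_L"``."""
    if measurement not in MEASUREMENTS:
        raise ValidationError(f"unknown measurement {measurement!r}")
    if movement not in MOVEMENTS:
        raise ValidationError(f"unknown movement {movement!r}")
    if hand not in HANDS:
        raise ValidationError(f"unknown hand {hand!r}")
    return f"{measurement}_{movement}_{hand}"


def parse_mpi_name(name: str) -> tuple[str, str, str]:
    """Inverse of :func:`mpi_name`."""
    try:
        measurement, movement, hand = name.split("_")
    except ValueError as exc:
        raise ValidationError(f"malformed MPI name {name!r}") from exc
    mpi_name(measurement, movement, hand)  # validates the parts
    return measurement, movement, hand


#: Fixed MPI order: measurement-major (order of ``MEASUREMENTS``), then
#: movement (protocol order), then hand (R before L).  Length 7*6*2 = 84.
MPI_NAMES: tuple[str, ...] = tuple(
    mpi_name(meas, mov, hand)
    for meas in MEASUREMENTS
    for mov in MOVEMENTS
    for hand in HANDS
)


# ---------------------------------------------------------------------------
# Trials and sessions
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One movement execution by one hand.

    Parameters
    ----------
    movement:
        One of :data:`MOVEMENTS`.
    hand:
        ``"R"`` or ``"L"``.
    emg:
        ``(8, T_emg)`` array of raw signed EMG samples in arbitrary device
        units (no calibration to millivolts is attempted).
    acc, gyro:
        ``(3, T_imu)`` arrays of acceleration (g) and angular velocity
        (deg/s); both share the IMU clock.
    """

    movement: str
    hand: str
    emg: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate_emg: float = 200.0
    sample_rate_imu: float = 50.0

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValidationError(f"unknown movement code {self.movement!r}")
        if self.hand not in HANDS:
            raise ValidationError(f"unknown hand {self.hand!r}")
        if self.sample_rate_emg <= 0 or self.sample_rate_imu <= 0:
            raise ValidationError("sample rates must be positive")
        self.emg = np.asarray(self.emg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.emg.ndim != 2 or self.emg.shape[0] != 8:
            raise ValidationError(
                f"EMG must be (8, T), got shape {self.emg.shape}"
            )
        for name, arr in (("acc", self.acc), ("gyro", self.gyro)):
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValidationError(f"{name} must be (3, T), got {arr.shape}")
        if self.acc.shape[1] != self.gyro.shape[1]:
            raise ValidationError("acc and gyro must have equal length")
        for name, arr in (("emg", self.emg), ("acc", self.acc), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite samples")
        # At least one analysis window (200 ms EMG / 800 ms IMU) must fit.
        min_emg = int(round(0.200 * self.sample_rate_emg))
        min_imu = int(round(0.800 * self.sample_rate_imu))
        if self.n_emg < min_emg:
            raise ValidationError(
                f"EMG too short: {self.n_emg} < one 200 ms window ({min_emg})"
            )
        if self.n_imu < min_imu + 1:  # +1: derivative loses one sample
            raise ValidationError(
                f"IMU too short: {self.n_imu} < one 800 ms window ({min_imu}) + 1"
            )

    @property
    def n_emg(self) -> int:
        return self.emg.shape[1]

    @property
    def n_imu(self) -> int:
        return self.acc.shape[1]


@dataclass
class SubjectSession:
    """Subject metadata plus the trials recorded in one session."""

    subject_id: str
    group: str  # "patient" | "control"
    affected_side: str | None  # "L" | "R" | None (controls)
    hy_stage: int | None  # Hoehn & Yahr 1-3, None for controls
    updrs3_total: int
    updrs3_brady_sub: int
    taps_proximal: int
    taps_distal: int
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.group == "control":
            if self.affected_side is not None or self.hy_stage is not None:
                raise ValidationError(
                    "controls must have affected_side=None and hy_stage=None"
                )
        else:
            if self.affected_side not in HANDS:
                raise ValidationError("patients need affected_side 'L' or 'R'")
            if self.hy_stage not in (1, 2, 3):
                raise ValidationError("patients need hy_stage in {1, 2, 3}")
        for name in ("updrs3_total", "updrs3_brady_sub", "taps_proximal", "taps_distal"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        keys = [(t.movement, t.hand) for t in self.trials]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (movement, hand) trial")

    def trial(self, movement: str, hand: str) -> Trial:
        for t in self.trials:
            if t.movement == movement and t.hand == hand:
                return t
        raise KeyError(f"no trial ({movement}, {hand}) for {self.subject_id}")

    def has_trial(self, movement: str, hand: str) -> bool:
        return any(t.movement == movement and t.hand == hand for t in self.trials)

    @property
    def movements_present(self) -> tuple[str, ...]:
        return tuple(sorted({t.movement for t in self.trials}, key=MOVEMENTS.index))


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class WindowConfig:
    """Filtering, segmentation and windowing parameters.

    Defaults follow the acquisition protocol: 200 ms EMG windows and 800 ms
    IMU windows with 25 % overlap; zero-phase Butterworth low-pass filters of
    order 4 / 20 Hz (EMG) and order 3 / 5 Hz (IMU); energy-based trimming at
    0.4 of the maximum 250 ms-window energy.
    """

    emg_window_ms: float = 200.0
    imu_window_ms: float = 800.0
    overlap_fraction: float = 0.25
    emg_filter_order: int = 4
    emg_cutoff_hz: float = 20.0
    imu_filter_order: int = 3
    imu_cutoff_hz: float = 5.0
    energy_threshold_frac: float = 0.4
    energy_window_ms: float = 250.0
    aggregate: str = "mean"  # window series -> MPI reduction

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if not 0.0 < self.energy_threshold_frac <= 1.0:
            raise ConfigError("energy_threshold_frac must be in (0, 1]")
        for name in ("emg_window_ms", "imu_window_ms", "energy_window_ms",
                     "emg_cutoff_hz", "imu_cutoff_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.aggregate not in ("mean", "median", "sum"):
            raise ConfigError("aggregate must be 'mean', 'median' or 'sum'")

    def window_samples(self, sensor: str, sample_rate: float) -> int:
        ms = self.emg_window_ms if sensor == "emg" else self.imu_window_ms
        w = int(round(ms * sample_rate / 1000.0))
        if w < 1:
            raise ConfigError("window shorter than one sample")
        return w

    def step_samples(self, sensor: str, sample_rate: float) -> int:
        w = self.window_samples(sensor, sample_rate)
        step = w - int(round(self.overlap_fraction * w))
        return max(step, 1)

    def validate_rates(self, sr_emg: float, sr_imu: float) -> None:
        if self.emg_cutoff_hz >= sr_emg / 2:
            raise ConfigError("EMG cutoff at or above Nyquist")
        if self.imu_cutoff_hz >= sr_imu / 2:
            raise ConfigError("IMU cutoff at or above Nyquist")

    def to_file(self, path: str | Path) -> None:
        write_flat_config(path, {f.name: getattr(self, f.name) for f in fields(self)})

    @classmethod
    def from_file(cls, path: str | Path) -> "WindowConfig":
        raw = read_flat_config(path)
        kwargs: dict[str, object] = {}
        for f in fields(cls):
            if f.name in raw:
                val = raw[f.name]
                kwargs[f.name] = val if f.type == "str" else type(getattr(cls(), f.name))(val)
        return cls(**kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# MPI vector
# ---------------------------------------------------------------------------

class MPIVector:
    """The 84 named scalar indicators of one subject, in the fixed order."""

    def __init__(self, values: Mapping[str, float] | pd.Series):
        series = pd.Series(dict(values), dtype=float)
        missing = [n for n in MPI_NAMES if n not in series.index]
        extra = [n for n in series.index if n not in MPI_NAMES]
        if missing or extra:
            raise ValidationError(
                f"MPI vector must have exactly the 84 canonical keys; "
                f"missing={missing[:3]}..., extra={extra[:3]}..."
                if missing or extra else ""
            )
        series = series.reindex(list(MPI_NAMES))
        if not np.all(np.isfinite(series.to_numpy())):
            raise ValidationError("MPI values must be finite")
        if (series.to_numpy() < 0).any():
            raise ValidationError("MPI values must be non-negative")
        self._series = series

    def __len__(self) -> int:
        return len(self._series)

    def __getitem__(self, key: str) -> float:
        return float(self._series[key])

    def to_series(self) -> pd.Series:
        return self._series.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"MPIVector({len(self._series)} indicators)"


# ---------------------------------------------------------------------------
# Flat key=value config files
# ---------------------------------------------------------------------------

def write_flat_config(path: str | Path, mapping: Mapping[str, object]) -> None:
    lines = [f"{k}={v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


# ---------------------------------------------------------------------------
# Sensor stream files
# ---------------------------------------------------------------------------

_STREAM_COLUMNS = {
    "emg": [f"ch{i}" for i in range(1, 9)],
    "acc": ["x", "y", "z"],
    "gyro": ["x", "y", "z"],
}


def _write_stream(path: Path, kind: str, rate: float, data: np.ndarray) -> None:
    cols = _STREAM_COLUMNS[kind]
    with open(path, "w") as fh:
        fh.write(f"sensor,{kind}\n")
        fh.write(f"sample_rate,{rate!r}\n")
        fh.write(",".join(cols) + "\n")
        np.savetxt(fh, np.asarray(data).T, delimiter=",", fmt="%.17g")


def _read_stream(path: Path, kind: str) -> tuple[float, np.ndarray]:
    with open(path) as fh:
        head = fh.readline().strip().split(",")
        if len(head) != 2 or head[0] != "sensor":
            raise FormatError(f"{path}: missing 'sensor,<kind>' header line")
        if head[1] != kind:
            raise FormatError(f"{path}: expected sensor kind {kind!r}, got {head[1]!r}")
        rate_line = fh.readline().strip().split(",")
        if len(rate_line) != 2 or rate_line[0] != "sample_rate":
            raise FormatError(f"{path}: missing 'sample_rate,<Hz>' line")
        try:
            rate = float(rate_line[1])
        except ValueError as exc:
            raise FormatError(f"{path}: bad sample rate {rate_line[1]!r}") from exc
        cols = fh.readline().strip().split(",")
        expected = _STREAM_COLUMNS[kind]
        if cols != expected:
            raise FormatError(
                f"{path}: expected columns {expected}, got {cols}"
            )
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed data rows ({exc})") from exc
    if data.size == 0:
        raise FormatError(f"{path}: no data rows")
    if data.shape[1] != len(expected):
        raise FormatError(
            f"{path}: expected {len(expected)} columns, got {data.shape[1]}"
        )
    return rate, data.T


def write_trial(trial: Trial, directory: str | Path, prefix: str | None = None) -> dict[str, Path]:
    """Write one trial as three CSV streams; returns the paths keyed by sensor."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"{trial.movement}_{trial.hand}"
    paths = {kind: directory / f"{prefix}.{kind}.csv" for kind in ("emg", "acc", "gyro")}
    _write_stream(paths["emg"], "emg", trial.sample_rate_emg, trial.emg)
    _write_stream(paths["acc"], "acc", trial.sample_rate_imu, trial.acc)
    _write_stream(paths["gyro"], "gyro", trial.sample_rate_imu, trial.gyro)
    return paths


def read_trial(directory: str | Path, prefix: str, movement: str, hand: str) -> Trial:
    """Read the three ``<prefix>.{emg,acc,gyro}.csv`` streams into a Trial."""
    directory = Path(directory)
    rates: dict[str, float] = {}
    data: dict[str, np.ndarray] = {}
    for kind in ("emg", "acc", "gyro"):
        path = directory / f"{prefix}.{kind}.csv"
        if not path.exists():
            raise FormatError(f"missing stream file {path}")
        rates[kind], data[kind] = _read_stream(path, kind)
    if rates["acc"] != rates["gyro"]:
        raise FormatError("acc and gyro declare different sample rates")
    return Trial(
        movement=movement,
        hand=hand,
        emg=data["emg"],
        acc=data["acc"],
        gyro=data["gyro"],
        sample_rate_emg=rates["emg"],
        sample_rate_imu=rates["acc"],
    )


# ---------------------------------------------------------------------------
# Session manifests
# ---------------------------------------------------------------------------

def write_session(session: SubjectSession, directory: str | Path) -> Path:
    """Write a session directory: ``session.txt`` manifest + trial streams."""
    directory = Path(directory)
    trials_dir = directory / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        f"subject_id={session.subject_id}",
        f"group={session.group}",
        f"affected_side={session.affected_side or 'none'}",
        f"hy_stage={session.hy_stage if session.hy_stage is not None else 'none'}",
        f"updrs3_total={session.updrs3_total}",
        f"updrs3_brady_sub={session.updrs3_brady_sub}",
        f"taps_proximal={session.taps_proximal}",
        f"taps_distal={session.taps_distal}",
    ]
    for trial in session.trials:
        prefix = f"{trial.movement}_{trial.hand}"
        write_trial(trial, trials_dir, prefix)
        lines.append(f"trial={trial.movement},{trial.hand},trials/{prefix}")
    manifest = directory / "session.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_session(directory: str | Path) -> SubjectSession:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest = directory / "session.txt"
    if not manifest.exists():
        raise FormatError(f"missing manifest {manifest}")
    meta: dict[str, str] = {}
    trial_specs: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(manifest.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{manifest}:{lineno}: expected key=value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "trial":
            parts = [p.strip() for p in val.split(",")]
            if len(parts) != 3:
                raise FormatError(f"{manifest}:{lineno}: trial needs movement,hand,path")
            trial_specs.append((parts[0], parts[1], parts[2]))
        else:
            meta[key] = val
    required = ("subject_id", "group", "affected_side", "hy_stage",
                "updrs3_total", "updrs3_brady_sub", "taps_proximal", "taps_distal")
    missing = [k for k in required if k not in meta]
    if missing:
        raise FormatError(f"{manifest}: missing keys {missing}")
    trials = []
    for movement, hand, rel in trial_specs:
        rel_path = directory / rel
        trials.append(read_trial(rel_path.parent, rel_path.name, movement, hand))
    return SubjectSession(
        subject_id=meta["subject_id"],
        group=meta["group"],
        affected_side=None if meta["affected_side"] == "none" else meta["affected_side"],
        hy_stage=None if meta["hy_stage"] == "none" else int(meta["hy_stage"]),
        updrs3_total=int(meta["updrs3_total"]),
        updrs3_brady_sub=int(meta["updrs3_brady_sub"]),
        taps_proximal=int(meta["taps_proximal"]),
        taps_distal=int(meta["taps_distal"]),
        trials=trials,
    )


def read_session_dirs(root: str | Path) -> list[SubjectSession]:
    """Read every subdirectory of ``root`` containing a ``session.txt``."""
    root = Path(root)
    sessions = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sub / "session.txt").exists():
            sessions.append(read_session(sub))
    if not sessions:
        raise FormatError(f"no session directories under {root}")
    return sessions


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort_table(table: pd.DataFrame, require_full: bool = True) -> None:
    """Check a subjects x (MPIs + labels) table for completeness."""
    if len(table) == 0:
        raise ValidationError("empty cohort table")
    mpi_cols = [c for c in table.columns if c in MPI_NAMES]
    if require_full and len(mpi_cols) != len(MPI_NAMES):
        missing = sorted(set(MPI_NAMES) - set(mpi_cols))
        raise ValidationError(f"cohort table missing MPI columns: {missing[:5]}...")
    if not mpi_cols:
        raise ValidationError("cohort table has no MPI columns")
    if table[mpi_cols].isna().any().any():
        raise ValidationError("cohort table has missing MPI cells")
    for col in ("group",):
        if col not in table.columns:
            raise ValidationError(f"cohort table missing label column {col!r}")


def write_cohort_table(table: pd.DataFrame, path: str | Path,
                       require_full: bool = True) -> None:
    validate_cohort_table(table, require_full=require_full)
    table.to_csv(path, index_label="subject_id", float_format="%.17g")


def read_cohort_table(path: str | Path, require_full: bool = True) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
    if "hy_stage" in table.columns:
        table["hy_stage"] = table["hy_stage"].astype("Int64")
    if "affected_side" in table.columns:
        table["affected_side"] = table["affected_side"].where(
            table["affected_side"].notna(), None
        )
    validate_cohort_table(table, require_full=require_full)
    return table
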