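"""Synthetic cohort generator for armband EMG + IMU movement sessions.

No public recordings exist for this protocol, so the generator emulates the
statistical structure that the downstream analyses assume, with planted,
stage-graded effects:

* reduced movement amplitude in patients (``amplitude_ratio`` per stage),
* slowness: repetition periods stretched by ``slowness_factor`` per stage,
* the bradykinesia "sequence effect": burst ``k`` scaled by
  ``(1 - decrement_per_rep)**k`` in patients,
* left-right asymmetry: the affected hand additionally scaled by
  ``asymmetry_factor`` per stage,
* clinical scores generated as monotone functions of severity with noise.

EMG trials are per-channel gain x burst envelope x band-limited (5-95 Hz)
zero-mean Gaussian noise, plus white sensor noise; no motor-unit physiology
or tremor is modelled.  The burst envelope is a raised-cosine-tapered (Tukey)
pulse per repetition, one repetition per movement period.  Channel gains are
maximal on channel 2 for the right hand and channel 6 for the left hand
(the external-forearm electrodes).  IMU trials are a movement-frequency
sinusoid plus its first harmonic on a fixed movement-specific dominant axis,
with small cross-axis leakage, modulated by the same kind of envelope.

Determinism: a ``seed`` fixes the whole cohort bit-for-bit; the group /
stage / affected-side label structure is computed without randomness and is
therefore identical across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.signal import windows as _windows

from .data_model import (
    ConfigError,
    HANDS,
    MOVEMENTS,
    SubjectSession,
    Trial,
)

__all__ = [
    "GeneratorConfig",
    "SeverityParams",
    "MOVEMENT_PROTOCOL",
    "DOMINANT_AXES",
    "EMG_CHANNEL_GAINS",
    "movement_repetitions",
    "generate_emg_trial",
    "generate_imu_trial",
    "generate_trial",
    "generate_cohort",
]


@dataclass(frozen=True)
class _Protocol:
    period_s: float          # repetition period of an unimpaired subject
    reps: int | None = None  # fixed repetition count, or
    duration_s: float | None = None  # fixed active duration (reps derived)


#: Movement protocol: hand rotations run for a fixed 10 s, grasp-pick-place
#: is repeated exactly five times, tapping alternates for a fixed 30 s.
MOVEMENT_PROTOCOL: dict[str, _Protocol] = {
    "RH-EE": _Protocol(period_s=1.0, duration_s=10.0),
    "RH-EF": _Protocol(period_s=1.0, duration_s=10.0),
    "GPP-EL": _Protocol(period_s=1.0, reps=5),
    "GPP-HL": _Protocol(period_s=1.0, reps=5),
    "TT-P": _Protocol(period_s=1.2, duration_s=30.0),
    "TT-D": _Protocol(period_s=1.0, duration_s=30.0),
}

#: Fixed dominant IMU axis per movement (0=x, 1=y, 2=z).  Hand rotations
#: load ACC y / GYRO x; grasp-pick-place loads ACC z / GYRO y; tapping loads
#: ACC x / GYRO z.  The map is shared by both hands.
DOMINANT_AXES: dict[str, dict[str, int]] = {
    "RH-EE": {"acc": 1, "gyro": 0},
    "RH-EF": {"acc": 1, "gyro": 0},
    "GPP-EL": {"acc": 2, "gyro": 1},
    "GPP-HL": {"acc": 2, "gyro": 1},
    "TT-P": {"acc": 0, "gyro": 2},
    "TT-D": {"acc": 0, "gyro": 2},
}

#: Relative EMG channel gains (channels 1-8 in electrode order).  The
#: external-forearm electrode carries the strongest activity: channel 2 for
#: the right hand, channel 6 for the left; neighbouring extensor channels
#: come next, mirroring the electrode ring flipping between forearms.
EMG_CHANNEL_GAINS: dict[str, np.ndarray] = {
    "R": np.array([0.35, 1.00, 0.60, 0.55, 0.35, 0.45, 0.30, 0.30]),
    "L": np.array([0.30, 0.45, 0.35, 0.55, 0.60, 1.00, 0.30, 0.35]),
}


@dataclass
class GeneratorConfig:
    """Cohort structure and planted effect sizes.

    Stage-indexed tuples hold values for Hoehn-Yahr stages (1, 2, 3).  All
    ratio parameters must lie in (0, 1].  ``subject_sd`` is the log-scale SD
    of the per-subject overall amplitude factor (between-subject spread);
    ``rep_consistency`` is the coefficient of variation of per-repetition
    burst amplitudes (within-trial consistency, which controls split-half
    reliability); ``period_jitter`` is the log-scale SD of the per-subject
    repetition-period factor.
    """

    n_controls: int = 16
    n_patients_per_stage: tuple[int, int, int] = (6, 6, 5)
    seed: int = 0
    amplitude_ratio: tuple[float, float, float] = (0.7, 0.55, 0.4)
    slowness_factor: tuple[float, float, float] = (1.2, 1.4, 1.7)
    decrement_per_rep: float = 0.05
    asymmetry_factor: tuple[float, float, float] = (0.85, 0.7, 0.55)
    rep_consistency: float = 0.05
    noise_sd: float = 0.02
    subject_sd: float = 0.2
    period_jitter: float = 0.05
    emg_amplitude: float = 1.0
    acc_amplitude: float = 0.5    # g
    gyro_amplitude: float = 120.0  # deg/s
    leakage: float = 0.2
    harmonic_ratio: float = 0.3
    pad_s: float = 1.0
    taper: float = 0.4  # Tukey taper fraction of each burst
    tt_tonic: float = 0.6  # tonic envelope floor during tapping movements

    def __post_init__(self) -> None:
        if self.n_controls < 0 or any(n < 0 for n in self.n_patients_per_stage):
            raise ConfigError("cohort sizes must be >= 0")
        for name in ("amplitude_ratio", "asymmetry_factor"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(not 0 < v <= 1 for v in vals):
                raise ConfigError(f"{name} entries must lie in (0, 1]")
        if any(s < 1 for s in self.slowness_factor):
            raise ConfigError("slowness_factor entries must be >= 1")
        if not 0 <= self.decrement_per_rep < 1:
            raise ConfigError("decrement_per_rep must be in [0, 1)")
        if self.rep_consistency < 0 or self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigError("spread parameters must be >= 0")
        if not 0 <= self.leakage <= 1:
            raise ConfigError("leakage must be in [0, 1]")
        if not 0 < self.taper <= 1:
            raise ConfigError("taper must be in (0, 1]")
        if not 0 <= self.tt_tonic < 1:
            raise ConfigError("tt_tonic must be in [0, 1)")
        if self.pad_s < 0.5:
            raise ConfigError("pad_s must be >= 0.5 s of quiet padding")


@dataclass
class SeverityParams:
    """Per-trial severity: resolved effect sizes for one (subject, hand).

    ``amplitude`` is the overall burst amplitude multiplier (subject factor x
    stage amplitude ratio x asymmetry if the hand is affected) relative to
    the sensor base amplitude; ``period_scale`` multiplies the movement's
    base repetition period.
    """

    amplitude: float = 1.0
    period_scale: float = 1.0
    decrement_per_rep: float = 0.0
    rep_consistency: float = 0.05
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be > 0")
        if self.period_scale <= 0:
            raise ConfigError("period_scale must be > 0")
        if not 0 <= self.decrement_per_rep < 1:
            raise ConfigError("decrement_per_rep must be in [0, 1)")


def movement_repetitions(movement: str, period_scale: float) -> tuple[int, float]:
    """Repetition count and effective period for a movement at a severity.

    Fixed-count movements (GPP) keep their count and stretch in time;
    fixed-duration movements (RH, TT) keep their recording length and fit
    fewer, slower repetitions.
    """
    proto = MOVEMENT_PROTOCOL[movement]
    period = proto.period_s * period_scale
    if proto.reps is not None:
        return proto.reps, period
    reps = max(1, int(proto.duration_s / period))
    return reps, period


def _burst_envelope(n: int, rate: float, period: float, rep_amps: np.ndarray,
                    pad_s: float, taper: float, floor: float = 0.0) -> np.ndarray:
    """Per-repetition raised-cosine-tapered bursts on a quiet baseline.

    ``floor`` adds a tonic component: within repetition ``k`` the envelope is
    ``rep_amps[k] * (floor + (1 - floor) * tukey)``, modelling muscles that do
    not fully relax between fast alternating repetitions.
    """
    env = np.zeros(n)
    for k, amp in enumerate(rep_amps):
        i0 = int(round((pad_s + k * period) * rate))
        i1 = min(int(round((pad_s + (k + 1) * period) * rate)), n)
        m = i1 - i0
        if m <= 0:
            break
        env[i0:i1] = amp * (floor + (1.0 - floor) * _windows.tukey(m, alpha=taper))
    return env


def _rep_amplitudes(params: SeverityParams, reps: int,
                    rng: np.random.Generator) -> np.ndarray:
    k = np.arange(reps)
    decay = (1.0 - params.decrement_per_rep) ** k
    jitter = 1.0 + rng.normal(0.0, params.rep_consistency, size=reps)
    return params.amplitude * decay * np.clip(jitter, 0.05, None)


_EMG_BAND = (5.0, 95.0)


def _bandlimited_noise(shape: tuple[int, ...], rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise band-limited to 5-95 Hz."""
    white = rng.standard_normal(shape)
    sos = _signal.butter(4, _EMG_BAND, btype="bandpass", fs=rate, output="sos")
    x = _signal.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def generate_emg_trial(movement: str, hand: str, params: SeverityParams,
                       seed: int | np.random.Generator,
                       config: GeneratorConfig | None = None) -> np.ndarray:
    """Raw ``(8, T)`` EMG matrix for one trial at 200 Hz."""
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if movement not in MOVEMENTS:
        raise ConfigError(f"unknown movement {movement!r}")
    if hand not in HANDS:
        raise ConfigError(f"unknown hand {hand!r}")
    rate = 200.0
    reps, period = movement_repetitions(movement, params.period_scale)
    n = int(round((2 * config.pad_s + reps * period) * rate))
    rep_amps = _rep_amplitudes(params, reps, rng) * config.emg_amplitude
    floor = config.tt_tonic if movement.startswith("TT") else 0.0
    env = _burst_envelope(n, rate, period, rep_amps, config.pad_s,
                          config.taper, floor)
    gains = EMG_CHANNEL_GAINS[hand]
    carrier = _bandlimited_noise((8, n), rate, rng)
    emg = gains[:, None] * env[None, :] * carrier
    if params.noise_sd > 0:
        emg = emg + params.noise_sd * config.emg_amplitude * rng.standard_normal((8, n))
    return emg


def generate_imu_trial(movement: str, hand: str, params: SeverityParams,
                       seed: int | np.random.Generator,
                       config: GeneratorConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Raw ``(3, T)`` acceleration and angular-velocity matrices at 50 Hz."""
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if movement not in MOVEMENTS:
        raise ConfigError(f"unknown movement {movement!r}")
    rate = 50.0
    reps, period = movement_repetitions(movement, params.period_scale)
    n = int(round((2 * config.pad_s + reps * period) * rate))
    t = np.arange(n) / rate - config.pad_s
    phase = 2 * np.pi * t / period
    osc = np.sin(phase) + config.harmonic_ratio * np.sin(2 * phase)
    osc_quad = np.cos(phase) + config.harmonic_ratio * np.cos(2 * phase)
    out = []
    for sensor, base_amp in (("acc", config.acc_amplitude),
                             ("gyro", config.gyro_amplitude)):
        rep_amps = _rep_amplitudes(params, reps, rng) * base_amp
        floor = config.tt_tonic if movement.startswith("TT") else 0.0
        env = _burst_envelope(n, rate, period, rep_amps, config.pad_s,
                              config.taper, floor)
        dom = DOMINANT_AXES[movement][sensor]
        arr = np.zeros((3, n))
        arr[dom] = env * osc
        for axis in range(3):
            if axis != dom:
                arr[axis] = config.leakage * env * osc_quad
        if params.noise_sd > 0:
            arr = arr + params.noise_sd * base_amp * rng.standard_normal((3, n))
        out.append(arr)
    return out[0], out[1]


def generate_trial(movement: str, hand: str, params: SeverityParams,
                   seed: int | np.random.Generator,
                   config: GeneratorConfig | None = None) -> Trial:
    """Full Trial (EMG + IMU) for one (movement, hand) at one severity."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    emg = generate_emg_trial(movement, hand, params, rng, config)
    acc, gyro = generate_imu_trial(movement, hand, params, rng, config)
    return Trial(movement=movement, hand=hand, emg=emg, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _label_structure(config: GeneratorConfig) -> list[dict]:
    """Deterministic (seed-independent) subject labels.

    Patients cycle affected sides right, right, left..., giving roughly the
    2:1 right:left ratio typical of a movement-disorder clinic sample.
    """
    labels: list[dict] = []
    for i in range(config.n_controls):
        labels.append({"subject_id": f"C{i + 1:02d}", "group": "control",
                       "stage": None, "affected": None})
    idx = 0
    for stage, count in zip((1, 2, 3), config.n_patients_per_stage):
        for _ in range(count):
            side = "L" if idx % 3 == 2 else "R"
            labels.append({"subject_id": f"P{idx + 1:02d}", "group": "patient",
                           "stage": stage, "affected": side})
            idx += 1
    return labels


def severity_for(config: GeneratorConfig, stage: int | None, affected: bool,
                 subject_amp: float, subject_period: float) -> SeverityParams:
    """Resolve per-hand severity from stage labels and subject factors."""
    amp = subject_amp
    period = subject_period
    decrement = 0.0
    if stage is not None:
        amp *= config.amplitude_ratio[stage - 1]
        period *= config.slowness_factor[stage - 1]
        decrement = config.decrement_per_rep
        if affected:
            amp *= config.asymmetry_factor[stage - 1]
    return SeverityParams(
        amplitude=amp,
        period_scale=period,
        decrement_per_rep=decrement,
        rep_consistency=config.rep_consistency,
        noise_sd=config.noise_sd,
    )


def _clinical_scores(config: GeneratorConfig, stage: int | None,
                     subject_amp: float,
                     rng: np.random.Generator) -> dict[str, int]:
    """Monotone-in-severity clinical scores with noise.

    Values are calibrated only for ordering (rank correlations, stage
    trends), not claimed clinically realistic.
    """
    s = 0 if stage is None else stage
    ratio = 1.0 if stage is None else config.amplitude_ratio[stage - 1]
    updrs = int(round(8 + 11 * s + rng.normal(0, 3))) if s else \
        int(round(max(0.0, rng.normal(2, 1.5))))
    brady = int(round(2 + 4 * s + rng.normal(0, 1.5))) if s else \
        int(round(max(0.0, rng.normal(1, 0.8))))
    tap_p = int(round(1 / MOVEMENT_PROTOCOL["TT-P"].period_s * 30
                      * ratio * subject_amp + rng.normal(0, 2)))
    tap_d = int(round(1 / MOVEMENT_PROTOCOL["TT-D"].period_s * 30
                      * ratio * subject_amp + rng.normal(0, 2)))
    return {
        "updrs3_total": max(0, updrs),
        "updrs3_brady_sub": max(0, brady),
        "taps_proximal": max(0, tap_p),
        "taps_distal": max(0, tap_d),
    }


def generate_cohort(config: GeneratorConfig | None = None,
                    movements: Sequence[str] | None = None) -> list[SubjectSession]:
    """Generate the full synthetic cohort.

    ``movements`` restricts the trials generated per subject (both hands are
    always generated); the default is the complete six-movement protocol.
    """
    config = config or GeneratorConfig()
    movements = tuple(movements) if movements is not None else MOVEMENTS
    unknown = [m for m in movements if m not in MOVEMENTS]
    if unknown:
        raise ConfigError(f"unknown movements {unknown}")
    labels = _label_structure(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(labels))
    sessions: list[SubjectSession] = []
    for label, child in zip(labels, children):
        rng = np.random.default_rng(child)
        subject_amp = float(np.exp(rng.normal(0.0, config.subject_sd)))
        subject_period = float(np.exp(rng.normal(0.0, config.period_jitter)))
        scores = _clinical_scores(config, label["stage"], subject_amp, rng)
        trials = []
        for movement in movements:
            for hand in HANDS:
                affected = label["affected"] == hand
                params = severity_for(config, label["stage"], affected,
                                      subject_amp, subject_period)
                trials.append(generate_trial(movement, hand, params, rng, config))
        sessions.append(SubjectSession(
            subject_id=label["subject_id"],
            group=label["group"],
            affected_side=label["affected"],
            hy_stage=label["stage"],
            trials=trials,
            **scores,
        ))
    return sessions
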