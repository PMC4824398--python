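"""Core container types shared across the pipeline.

All streams are plain numpy arrays with an explicit sampling rate; insole
frames run at 120 Hz and accelerometer frames at 50 Hz. Sign conventions
for accelerations: vertical positive up, anteroposterior (AP) positive
anterior, mediolateral (ML) positive toward the participant's right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INSOLE_FS_HZ = 120.0
ACCEL_FS_HZ = 50.0

#: Accelerometer body sites, in canonical order.
ACCEL_SITES = ("head", "pelvis", "left_shank", "right_shank")

#: Walking conditions: single task and dual task (verbal fluency load).
CONDITIONS = ("ST", "DT")


@dataclass
class ClinicalFeatures:
    """Clinical assessment outcomes for one participant.

    abc_score
        Activities-specific Balance Confidence scale, 0-100.
    champs_frequency, champs_calories
        CHAMPS-derived weekly activity frequency and caloric expenditure.
    sixmwt_distance_m
        Six minute walk test distance in metres.
    st_walk_time_s, dt_walk_time_s
        Time to complete the 7.62 m walk without / with the cognitive load.
    fear_of_falling
        Self-ranked fear of falling, integer 0 (none) to 10 (high).
    """

    abc_score: float
    champs_frequency: float
    champs_calories: float
    sixmwt_distance_m: float
    st_walk_time_s: float
    dt_walk_time_s: float
    fear_of_falling: int

    FIELDS = (
        "abc_score",
        "champs_frequency",
        "champs_calories",
        "sixmwt_distance_m",
        "st_walk_time_s",
        "dt_walk_time_s",
        "fear_of_falling",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass
class SubjectProfile:
    """Latent gait parameters of one synthetic participant.

    The profile drives the generator: stride timing statistics, stance
    fraction, left/right asymmetry, the even/odd harmonic mix of the
    acceleration signals (``harmonic_purity``), additive acceleration noise
    (``noise_sd``, m/s^2) and the expected number of injected centre-of-
    pressure irregularities per stance.
    """

    subject_id: str
    is_faller: bool
    mass_kg: float
    stride_time_mean_s: float
    stride_time_cv_pct: float
    stance_fraction: float
    step_asymmetry_pct: float
    harmonic_purity: float
    noise_sd: float
    clinical: ClinicalFeatures
    pd_per_stance: float = 0.0
    ml_dev_per_stance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.8 <= self.stride_time_mean_s <= 2.0:
            raise ValueError("stride_time_mean_s must lie in [0.8, 2.0] s")
        if not 0.55 <= self.stance_fraction <= 0.70:
            raise ValueError("stance_fraction must lie in [0.55, 0.70]")
        if not 0.0 <= self.harmonic_purity <= 1.0:
            raise ValueError("harmonic_purity must lie in [0, 1]")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")


@dataclass
class InsoleStream:
    """Per-frame total vertical force and centre of pressure for one foot.

    ``cop_ap_mm``/``cop_ml_mm`` are insole-frame coordinates (AP increasing
    anteriorly); they are only meaningful where ``valid`` is True, i.e.
    while the foot is loaded above the contact threshold.
    """

    total_force_n: np.ndarray
    cop_ap_mm: np.ndarray
    cop_ml_mm: np.ndarray
    valid: np.ndarray
    fs_hz: float = INSOLE_FS_HZ

    def __post_init__(self) -> None:
        n = len(self.total_force_n)
        if not (len(self.cop_ap_mm) == len(self.cop_ml_mm) == len(self.valid) == n):
            raise ValueError("insole stream arrays must have equal length")
        if np.any(np.asarray(self.total_force_n) < 0):
            raise ValueError("total force must be non-negative")

    def __len__(self) -> int:
        return len(self.total_force_n)


@dataclass
class AccelStream:
    """Tri-axial acceleration stream for one body site (m/s^2)."""

    vertical: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    fs_hz: float = ACCEL_FS_HZ

    AXES = ("vertical", "ap", "ml")

    def __post_init__(self) -> None:
        n = len(self.vertical)
        if not (len(self.ap) == len(self.ml) == n):
            raise ValueError("accel stream axes must have equal length")
        for axis in self.AXES:
            if not np.all(np.isfinite(getattr(self, axis))):
                raise ValueError(f"non-finite values in {axis} axis")

    def axis(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def __len__(self) -> int:
        return len(self.vertical)


@dataclass
class GaitEvents:
    """Foot-strike / foot-off frame indices for one foot.

    Events alternate FS < FO < next FS. ``foot_off_frames[i]`` is the first
    frame *after* the i-th stance, so stance i occupies
    ``[foot_strike_frames[i], foot_off_frames[i])``.
    """

    foot_strike_frames: np.ndarray
    foot_off_frames: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        fs = np.asarray(self.foot_strike_frames)
        fo = np.asarray(self.foot_off_frames)
        if len(fs) != len(fo):
            raise ValueError("foot strike and foot off counts differ")
        if len(fs) and (np.any(fo <= fs) or np.any(fs[1:] <= fo[:-1])):
            raise ValueError("events must alternate FS < FO < next FS")

    @property
    def n_stances(self) -> int:
        return len(self.foot_strike_frames)

    def stance_times_s(self) -> np.ndarray:
        return (np.asarray(self.foot_off_frames) - np.asarray(self.foot_strike_frames)) / self.fs_hz

    def stride_times_s(self) -> np.ndarray:
        """Successive foot-strike intervals (one fewer than stances)."""
        return np.diff(np.asarray(self.foot_strike_frames)) / self.fs_hz

    def swing_times_s(self) -> np.ndarray:
        """Per-stride swing = stride - stance, for interior strides."""
        fs = np.asarray(self.foot_strike_frames)
        fo = np.asarray(self.foot_off_frames)
        return (fs[1:] - fo[:-1]) / self.fs_hz


@dataclass
class SensorTrial:
    """One participant x condition recording.

    ``accel`` maps site name to stream; a site absent from the map emulates
    sensor failure. ``ground_truth_events`` is populated by the generator
    only (exact stance boundaries, for validation) and is never consulted
    by the feature pipeline.
    """

    subject_id: str
    condition: str
    insole_left: InsoleStream | None
    insole_right: InsoleStream | None
    accel: dict[str, AccelStream] = field(default_factory=dict)
    mass_kg: float | None = None
    ground_truth_events: dict[str, GaitEvents] | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for site in self.accel:
            if site not in ACCEL_SITES:
                raise ValueError(f"unknown accelerometer site {site!r}")


@dataclass
class ConfusionMatrix:
    """Binary confusion matrix; faller is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn
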