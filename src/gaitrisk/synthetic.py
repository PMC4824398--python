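"""Synthetic gait-trial generator.

Emulates the sensor set-up of an instrumented over-ground walk: per-foot
plantar-pressure streams (total vertical force + centre of pressure, CoP)
at 120 Hz and tri-axial accelerometers at the head, pelvis and both shanks
at 50 Hz, plus seven clinical assessment outcomes per participant.

The generative model is deliberately simple and fully parameterised so
every downstream feature has known ground truth:

* Total force during stance follows a double-bump ("M") curve
  ``sin(pi*tau) * (1 + d*cos(2*pi*tau))`` over normalised stance time
  ``tau``, zero during swing — two force peaks around early/late stance
  and a mid-stance valley, as in a typical vertical ground-reaction curve.
* The CoP advances anteriorly at constant rate during stance; posterior
  and mediolateral irregularities are injected as square pulses of known
  count, amplitude and width, so CoP-deviation features have exact
  expected values.
* Accelerations are a harmonic series at the (stride-varying) stride
  frequency. ``harmonic_purity`` sets the even/odd amplitude share and
  thereby controls the ratio of even to odd harmonics downstream; a
  stride-phase amplitude modulation makes the two steps of a stride
  distinguishable, as left/right steps are in real signals. White noise
  of standard deviation ``noise_sd`` is added per axis.

Faller vs non-faller differences enter only through the configured effect
sizes in ``DEFAULT_EFFECTS`` / ``DEFAULT_CLINICAL_EFFECTS``. No cohort
publishes per-group distributions for these gait parameters, so the
default effect sizes are invented, directionally standard values; they are
meant to be overridden through ``effect_config``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .types import (
    ACCEL_FS_HZ,
    ACCEL_SITES,
    CONDITIONS,
    INSOLE_FS_HZ,
    AccelStream,
    ClinicalFeatures,
    GaitEvents,
    InsoleStream,
    SensorTrial,
    SubjectProfile,
)

GRAVITY_M_S2 = 9.81

#: Peak total force as a multiple of body weight.
FORCE_PEAK_BW = 1.15
#: Depth of the mid-stance valley in the double-bump force curve.
M_CURVE_DEPTH = 0.4
#: Relative contact threshold (fraction of body weight) used to flag CoP
#: validity; shared with the event detector's default.
CONTACT_THRESHOLD_BW = 0.05

#: CoP anterior progression during one stance, insole frame (mm).
COP_AP_START_MM = 30.0
COP_AP_TRAVEL_MM = 180.0
COP_ML_AMPLITUDE_MM = 2.0

#: Injected CoP irregularities: posterior pulses (strictly negative AP
#: steps) and ML pulses exceeding the 0.5 mm/frame dual threshold.
PD_PULSE_FRAMES = 3
PD_PULSE_RATE_MM_PER_FRAME = 1.0
ML_PULSE_FRAMES = 2
ML_PULSE_RATE_MM_PER_FRAME = 0.8

#: Dual-task modifiers: stride-time variability is inflated and gait
#: slows slightly under the concurrent cognitive load.
DT_CV_MULTIPLIER = 1.5
DT_STRIDE_TIME_MULTIPLIER = 1.05

#: Harmonic amplitude template (harmonic order -> base weight) and
#: per-site, per-axis scales in m/s^2. Shank signals are largest,
#: head signals most attenuated.
HARMONIC_WEIGHTS = {1: 0.5, 2: 1.0, 3: 0.35, 4: 0.45, 5: 0.15, 6: 0.2}
STRIDE_MODULATION = 0.3
SITE_AXIS_SCALE = {
    "head": {"vertical": 1.2, "ap": 0.8, "ml": 0.6},
    "pelvis": {"vertical": 2.2, "ap": 1.4, "ml": 1.0},
    "left_shank": {"vertical": 3.0, "ap": 2.0, "ml": 1.2},
    "right_shank": {"vertical": 3.0, "ap": 2.0, "ml": 1.2},
}


def _m_curve(tau: np.ndarray) -> np.ndarray:
    """Normalised double-bump stance force profile, peak value 1."""
    s = np.sin(np.pi * tau) * (1.0 + M_CURVE_DEPTH * np.cos(2.0 * np.pi * tau))
    return s / _M_CURVE_PEAK


_tau_grid = np.linspace(0.0, 1.0, 4001)
_M_CURVE_PEAK = float(
    np.max(np.sin(np.pi * _tau_grid) * (1.0 + M_CURVE_DEPTH * np.cos(2.0 * np.pi * _tau_grid)))
)


# --------------------------------------------------------------------------
# Effect-size configuration
# --------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Truncated-normal draw specification per group."""

    non_faller_mean: float
    faller_mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator, is_faller: bool) -> float:
        mean = self.faller_mean if is_faller else self.non_faller_mean
        return float(np.clip(rng.normal(mean, self.sd), self.lo, self.hi))


# Synthetic defaults — invented, directionally standard effect sizes; no
# per-group gait distributions are published for the cohort being emulated.
DEFAULT_EFFECTS: dict[str, EffectSpec] = {
    "stride_time_mean_s": EffectSpec(1.05, 1.12, 0.06, 0.85, 1.50),
    "stride_time_cv_pct": EffectSpec(2.0, 4.0, 0.5, 0.3, 10.0),
    "stance_fraction": EffectSpec(0.620, 0.645, 0.012, 0.56, 0.69),
    "step_asymmetry_pct": EffectSpec(1.0, 3.0, 0.7, 0.0, 12.0),
    "harmonic_purity": EffectSpec(0.72, 0.58, 0.05, 0.05, 0.95),
    "noise_sd": EffectSpec(0.15, 0.35, 0.06, 0.01, 1.0),
    "mass_kg": EffectSpec(73.1, 71.9, 13.5, 45.0, 110.0),
    "pd_per_stance": EffectSpec(0.3, 1.2, 0.3, 0.0, 4.0),
    "ml_dev_per_stance": EffectSpec(0.5, 1.5, 0.4, 0.0, 5.0),
}

DEFAULT_CLINICAL_EFFECTS: dict[str, EffectSpec] = {
    "abc_score": EffectSpec(92.0, 80.0, 8.0, 0.0, 100.0),
    "champs_frequency": EffectSpec(20.0, 14.0, 5.0, 0.0, 60.0),
    "champs_calories": EffectSpec(3000.0, 2000.0, 800.0, 0.0, 10000.0),
    "sixmwt_distance_m": EffectSpec(455.8, 446.6, 100.0, 150.0, 800.0),
    "st_walk_time_s": EffectSpec(6.3, 7.3, 0.9, 4.0, 15.0),
    "dt_cost_s": EffectSpec(0.7, 1.4, 0.5, 0.0, 6.0),
    "fear_of_falling": EffectSpec(1.2, 4.0, 1.5, 0.0, 10.0),
}


def merge_effects(overrides: dict | None) -> tuple[dict[str, EffectSpec], dict[str, EffectSpec]]:
    """Merge user overrides into the default gait and clinical effect maps.

    Overrides are keyed by parameter name; each value may be an
    :class:`EffectSpec` or a partial dict of its fields.
    """
    gait = copy.deepcopy(DEFAULT_EFFECTS)
    clinical = copy.deepcopy(DEFAULT_CLINICAL_EFFECTS)
    for name, spec in (overrides or {}).items():
        target = gait if name in gait else clinical if name in clinical else None
        if target is None:
            raise ValueError(f"unknown effect parameter {name!r}")
        if isinstance(spec, EffectSpec):
            target[name] = spec
        else:
            base = target[name]
            target[name] = EffectSpec(
                spec.get("non_faller_mean", base.non_faller_mean),
                spec.get("faller_mean", base.faller_mean),
                spec.get("sd", base.sd),
                spec.get("lo", base.lo),
                spec.get("hi", base.hi),
            )
    return gait, clinical


def null_effects() -> dict[str, dict[str, float]]:
    """Effect config with every faller mean equal to the non-faller mean.

    Makes the two groups statistically exchangeable, so any downstream
    classifier should perform at chance.
    """
    out: dict[str, dict[str, float]] = {}
    for name, spec in {**DEFAULT_EFFECTS, **DEFAULT_CLINICAL_EFFECTS}.items():
        out[name] = {"faller_mean": spec.non_faller_mean}
    return out


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------

def _place_pulses(
    rng: np.random.Generator, n: int, lo: int, hi: int, width: int, min_gap: int = 2
) -> list[int]:
    """Choose up to ``n`` non-overlapping pulse start frames in [lo, hi)."""
    starts: list[int] = []
    if hi - lo <= width:
        return starts
    candidates = rng.permutation(np.arange(lo, hi - width))
    for c in candidates:
        if len(starts) >= n:
            break
        if all(abs(int(c) - s) >= width + min_gap for s in starts):
            starts.append(int(c))
    return sorted(starts)


def _stance_cop(
    rng: np.random.Generator,
    n_frames: int,
    n_pd: int,
    n_ml: int,
) -> tuple[np.ndarray, np.ndarray]:
    """CoP AP/ML trajectories for one stance, built from per-frame steps."""
    # Anterior progression: constant positive step, then injected posterior
    # pulses replace the step with a known negative rate.
    ap_step = np.full(n_frames, COP_AP_TRAVEL_MM / max(n_frames, 1))
    margin = max(2, n_frames // 5)
    for s in _place_pulses(rng, n_pd, margin, n_frames - margin, PD_PULSE_FRAMES):
        ap_step[s : s + PD_PULSE_FRAMES] = -PD_PULSE_RATE_MM_PER_FRAME
    ap = COP_AP_START_MM + np.cumsum(ap_step)

    tau = np.arange(n_frames) / max(n_frames - 1, 1)
    ml_base = COP_ML_AMPLITUDE_MM * np.sin(2.0 * np.pi * tau)
    ml_step = np.diff(ml_base, prepend=ml_base[0] if n_frames else 0.0)
    for s in _place_pulses(rng, n_ml, margin, n_frames - margin, ML_PULSE_FRAMES):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ml_step[s : s + ML_PULSE_FRAMES] = sign * ML_PULSE_RATE_MM_PER_FRAME
    ml = np.cumsum(ml_step)
    return ap, ml


def _foot_streams(
    rng: np.random.Generator,
    fs_times: np.ndarray,
    fo_times: np.ndarray,
    n_frames: int,
    mass_kg: float,
    pd_per_stance: float,
    ml_dev_per_stance: float,
) -> tuple[InsoleStream, GaitEvents]:
    force = np.zeros(n_frames)
    cop_ap = np.zeros(n_frames)
    cop_ml = np.zeros(n_frames)
    peak_force = FORCE_PEAK_BW * mass_kg * GRAVITY_M_S2
    threshold = CONTACT_THRESHOLD_BW * mass_kg * GRAVITY_M_S2

    gt_fs, gt_fo = [], []
    for t_fs, t_fo in zip(fs_times, fo_times):
        f0 = int(np.ceil(t_fs * INSOLE_FS_HZ - 1e-9))
        f1 = int(np.ceil(t_fo * INSOLE_FS_HZ - 1e-9))
        if f0 < 0 or f1 > n_frames or f1 - f0 < 4:
            continue
        frames = np.arange(f0, f1)
        tau = (frames / INSOLE_FS_HZ - t_fs) / (t_fo - t_fs)
        force[frames] = peak_force * np.clip(_m_curve(tau), 0.0, None)
        n_pd = rng.poisson(pd_per_stance)
        n_ml = rng.poisson(ml_dev_per_stance)
        ap, ml = _stance_cop(rng, len(frames), n_pd, n_ml)
        cop_ap[frames] = ap
        cop_ml[frames] = ml
        gt_fs.append(f0)
        gt_fo.append(f1)

    valid = force >= threshold
    cop_ap[~valid] = 0.0
    cop_ml[~valid] = 0.0
    stream = InsoleStream(force, cop_ap, cop_ml, valid)
    events = GaitEvents(np.asarray(gt_fs), np.asarray(gt_fo), INSOLE_FS_HZ)
    return stream, events


def _stride_phase(times: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Continuous stride phase (strides elapsed) at given times.

    Piecewise-linear: phase k at the k-th stride onset, extrapolated with
    the mean stride period beyond the recorded onsets.
    """
    k = np.arange(len(onsets), dtype=float)
    mean_t = float(np.mean(np.diff(onsets)))
    phase = np.interp(times, onsets, k)
    before = times < onsets[0]
    after = times > onsets[-1]
    phase[before] = (times[before] - onsets[0]) / mean_t
    phase[after] = k[-1] + (times[after] - onsets[-1]) / mean_t
    return phase


def _accel_stream(
    rng: np.random.Generator,
    times: np.ndarray,
    stride_phase: np.ndarray,
    site: str,
    harmonic_purity: float,
    noise_sd: float,
) -> AccelStream:
    h = harmonic_purity
    modulation = 1.0 + STRIDE_MODULATION * np.cos(2.0 * np.pi * stride_phase)
    axes = {}
    for axis in AccelStream.AXES:
        scale = SITE_AXIS_SCALE[site][axis]
        sig = np.zeros_like(times)
        for k, w in HARMONIC_WEIGHTS.items():
            share = h if k % 2 == 0 else 1.0 - h
            amp = 2.0 * scale * w * share
            phi = rng.uniform(0.0, 2.0 * np.pi)
            sig += amp * np.cos(2.0 * np.pi * k * stride_phase + phi)
        sig = modulation * sig + rng.normal(0.0, noise_sd, len(times))
        axes[axis] = sig
    return AccelStream(axes["vertical"], axes["ap"], axes["ml"])


def generate_trial(
    profile: SubjectProfile,
    condition: str,
    duration_s: float,
    seed: int,
    sites: tuple[str, ...] = ACCEL_SITES,
) -> SensorTrial:
    """Generate one synthetic walking trial for a subject profile.

    Deterministic given ``seed``. ``condition`` must be ``"ST"`` or
    ``"DT"``; dual-task trials inflate stride-time variability by
    ``DT_CV_MULTIPLIER`` and slow the stride slightly.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    stride_mean = profile.stride_time_mean_s
    cv = profile.stride_time_cv_pct
    if condition == "DT":
        stride_mean *= DT_STRIDE_TIME_MULTIPLIER
        cv *= DT_CV_MULTIPLIER
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if duration_s < 6.0 * stride_mean:
        raise ValueError("duration_s must cover at least 6 stride periods")

    rng = np.random.default_rng(seed)
    sd = stride_mean * cv / 100.0

    # Common stride-onset clock; both feet share stride durations so the
    # left/right alternation never degenerates.
    t0 = 0.3
    onsets = [t0]
    stride_durations = []
    while onsets[-1] < duration_s:
        T = float(np.clip(rng.normal(stride_mean, sd), 0.5 * stride_mean, 1.5 * stride_mean))
        stride_durations.append(T)
        onsets.append(onsets[-1] + T)
    onsets_arr = np.asarray(onsets)
    durations = np.asarray(stride_durations)

    sf_left = profile.stance_fraction * (1.0 + profile.step_asymmetry_pct / 200.0)
    sf_right = profile.stance_fraction * (1.0 - profile.step_asymmetry_pct / 200.0)
    sf_left = min(sf_left, 0.75)
    sf_right = max(sf_right, 0.45)

    n_frames = int(round(duration_s * INSOLE_FS_HZ))
    left_fs = onsets_arr[:-1]
    left_fo = left_fs + sf_left * durations
    right_fs = onsets_arr[:-1] + 0.5 * durations
    right_fo = right_fs + sf_right * durations

    insole_left, events_left = _foot_streams(
        rng, left_fs, left_fo, n_frames, profile.mass_kg,
        profile.pd_per_stance, profile.ml_dev_per_stance,
    )
    insole_right, events_right = _foot_streams(
        rng, right_fs, right_fo, n_frames, profile.mass_kg,
        profile.pd_per_stance, profile.ml_dev_per_stance,
    )

    n_acc = int(round(duration_s * ACCEL_FS_HZ))
    times = np.arange(n_acc) / ACCEL_FS_HZ
    phase = _stride_phase(times, onsets_arr)
    accel = {
        site: _accel_stream(rng, times, phase, site, profile.harmonic_purity, profile.noise_sd)
        for site in sites
    }

    return SensorTrial(
        subject_id=profile.subject_id,
        condition=condition,
        insole_left=insole_left,
        insole_right=insole_right,
        accel=accel,
        mass_kg=profile.mass_kg,
        ground_truth_events={"left": events_left, "right": events_right},
    )


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """One generated participant: profile, label and per-condition trials."""

    profile: SubjectProfile
    trials: dict[str, SensorTrial] = field(default_factory=dict)

    @property
    def subject_id(self) -> str:
        return self.profile.subject_id

    @property
    def is_faller(self) -> bool:
        return self.profile.is_faller


def _draw_profile(
    rng: np.random.Generator,
    subject_id: str,
    is_faller: bool,
    gait: dict[str, EffectSpec],
    clin: dict[str, EffectSpec],
) -> SubjectProfile:
    g = {name: spec.draw(rng, is_faller) for name, spec in gait.items()}
    c = {name: spec.draw(rng, is_faller) for name, spec in clin.items()}
    st = c["st_walk_time_s"]
    clinical = ClinicalFeatures(
        abc_score=c["abc_score"],
        champs_frequency=c["champs_frequency"],
        champs_calories=c["champs_calories"],
        sixmwt_distance_m=c["sixmwt_distance_m"],
        st_walk_time_s=st,
        dt_walk_time_s=st + c["dt_cost_s"],
        fear_of_falling=int(round(c["fear_of_falling"])),
    )
    return SubjectProfile(
        subject_id=subject_id,
        is_faller=is_faller,
        mass_kg=g["mass_kg"],
        stride_time_mean_s=g["stride_time_mean_s"],
        stride_time_cv_pct=g["stride_time_cv_pct"],
        stance_fraction=g["stance_fraction"],
        step_asymmetry_pct=g["step_asymmetry_pct"],
        harmonic_purity=g["harmonic_purity"],
        noise_sd=g["noise_sd"],
        clinical=clinical,
        pd_per_stance=g["pd_per_stance"],
        ml_dev_per_stance=g["ml_dev_per_stance"],
    )


def generate_cohort(
    n_fallers: int,
    n_non_fallers: int,
    effect_config: dict | None = None,
    seed: int = 0,
    duration_s: float = 10.0,
    conditions: tuple[str, ...] = CONDITIONS,
    sites: tuple[str, ...] = ACCEL_SITES,
    missing_sensors: bool = False,
) -> list[CohortSubject]:
    """Generate a cohort of subjects with one trial per walking condition.

    Faller and non-faller profiles are drawn from truncated normal
    distributions whose means differ by the configured effect sizes.
    With ``missing_sensors=True``, the pelvis stream is dropped for the
    first two non-fallers and the left-shank stream for the third,
    emulating sensor power failures.

    Deterministic given ``seed``; every subject and trial receives an
    independent child seed.
    """
    if n_fallers < 0 or n_non_fallers < 0:
        raise ValueError("subject counts must be non-negative")
    gait, clin = merge_effects(effect_config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_fallers + n_non_fallers)

    labels = [True] * n_fallers + [False] * n_non_fallers
    cohort: list[CohortSubject] = []
    n_non_seen = 0
    for i, (is_faller, child) in enumerate(zip(labels, children)):
        sub_rng = np.random.default_rng(child)
        prefix = "F" if is_faller else "N"
        profile = _draw_profile(sub_rng, f"{prefix}{i:03d}", is_faller, gait, clin)

        trial_sites = sites
        if missing_sensors and not is_faller:
            n_non_seen += 1
            if n_non_seen <= 2:
                trial_sites = tuple(s for s in sites if s != "pelvis")
            elif n_non_seen == 3:
                trial_sites = tuple(s for s in sites if s != "left_shank")

        trials = {}
        for cond in conditions:
            trial_seed = int(sub_rng.integers(0, 2**31 - 1))
            trials[cond] = generate_trial(profile, cond, duration_s, trial_seed, trial_sites)
        cohort.append(CohortSubject(profile=profile, trials=trials))
    return cohort
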