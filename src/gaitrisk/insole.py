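"""Plantar-pressure (insole) gait parameters.

Thirty features per trial, in three families:

* 12 centre-of-pressure (CoP) path features: counts, mean lengths and mean
  durations of posterior and of mediolateral path deviations per stance;
  min/max/mean/median CoP path velocity (optionally normalised by stance
  time); and ensemble AP/ML coefficients of variation of the stance-phase
  CoP path (Winter's formulation over 101 resampled points).
* 11 temporal features: cadence, stride/stance/swing time, percent stance,
  percent double support, absolute double-support time, stride-time
  symmetry index between limbs, and stride-to-stride CoV of stride,
  stance and swing time.
* 7 impulse features I1-I7: time integrals of the total vertical force
  over stance sub-phases bounded by foot strike, the two force peaks, the
  mid-stance minimum and foot off, normalised by body mass (N*s/kg).

Per-stance quantities are computed for each foot and pooled across both
feet's stances before averaging, so each feature is a single number per
(subject, condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import detect_stance_phases, double_support_overlaps
from .io import lowpass_filter
from .types import GaitEvents, InsoleStream, SensorTrial

#: Dual threshold on the first derivative of the CoP ML signal; steps with
#: magnitude above this count toward an ML path deviation.
ML_DEVIATION_THRESHOLD_MM_PER_FRAME = 0.5

#: Cut-off for the light smoothing applied before impulse landmark search.
IMPULSE_SMOOTHING_HZ = 10.0

#: Number of ensemble-average points over the stance phase (0-100%).
ENSEMBLE_POINTS = 101

COP_FEATURES = [
    "pd_count",
    "pd_length_mm",
    "pd_duration_s",
    "ml_dev_count",
    "ml_dev_length_mm",
    "ml_dev_duration_s",
    "cop_vel_min",
    "cop_vel_max",
    "cop_vel_mean",
    "cop_vel_median",
    "cop_cov_ap_pct",
    "cop_cov_ml_pct",
]
TEMPORAL_FEATURES = [
    "cadence_steps_per_min",
    "stride_time_s",
    "stance_time_s",
    "swing_time_s",
    "pct_stance",
    "pct_double_support",
    "double_support_time_s",
    "stride_time_si_pct",
    "cov_stride_pct",
    "cov_stance_pct",
    "cov_swing_pct",
]
IMPULSE_FEATURES = [f"i{k}_nspkg" for k in range(1, 8)]

#: Canonical order of the 30 insole features.
INSOLE_FEATURE_NAMES = COP_FEATURES + TEMPORAL_FEATURES + IMPULSE_FEATURES


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open (start, stop) index pairs."""
    edges = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _stance_cop_arrays(
    insole: InsoleStream, events: GaitEvents
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Valid (ap, ml) CoP samples and duration per stance; short ones skipped."""
    out = []
    for fs, fo in zip(events.foot_strike_frames, events.foot_off_frames):
        sl = slice(int(fs), int(fo))
        valid = np.asarray(insole.valid[sl], dtype=bool)
        if valid.sum() < 3:
            warnings.warn("stance with < 3 valid CoP frames skipped", stacklevel=2)
            continue
        ap = np.asarray(insole.cop_ap_mm[sl])[valid]
        ml = np.asarray(insole.cop_ml_mm[sl])[valid]
        out.append((ap, ml, (int(fo) - int(fs)) / insole.fs_hz))
    return out


# --------------------------------------------------------------------------
# CoP path features
# --------------------------------------------------------------------------

def _deviation_stats(steps: np.ndarray, mask: np.ndarray, fs_hz: float) -> tuple[float, float, float]:
    """(count, mean length in mm, mean duration in s) of masked step runs."""
    runs = _true_runs(mask)
    if not runs:
        return 0.0, 0.0, 0.0
    lengths = [float(np.abs(steps[a:b]).sum()) for a, b in runs]
    durations = [(b - a) / fs_hz for a, b in runs]
    return float(len(runs)), float(np.mean(lengths)), float(np.mean(durations))


def cop_deviation_features(
    insole: InsoleStream,
    events: GaitEvents,
    ml_threshold: float = ML_DEVIATION_THRESHOLD_MM_PER_FRAME,
) -> dict[str, float]:
    """Posterior and mediolateral CoP path deviation features, per-stance
    values averaged over this foot's stances.

    A posterior deviation is a maximal run of strictly negative AP steps
    (the CoP should advance anteriorly); an ML deviation is a maximal run
    of ML steps whose magnitude exceeds the +-0.5 mm/frame dual threshold.
    """
    per_stance = {name: [] for name in COP_FEATURES[:6]}
    for ap, ml, _dur in _stance_cop_arrays(insole, events):
        dap = np.diff(ap)
        dml = np.diff(ml)
        c, l, d = _deviation_stats(dap, dap < 0.0, insole.fs_hz)
        per_stance["pd_count"].append(c)
        per_stance["pd_length_mm"].append(l)
        per_stance["pd_duration_s"].append(d)
        c, l, d = _deviation_stats(dml, np.abs(dml) > ml_threshold, insole.fs_hz)
        per_stance["ml_dev_count"].append(c)
        per_stance["ml_dev_length_mm"].append(l)
        per_stance["ml_dev_duration_s"].append(d)
    return {k: float(np.mean(v)) if v else np.nan for k, v in per_stance.items()}


def cop_velocity_features(
    insole: InsoleStream,
    events: GaitEvents,
    normalize_by_stance_time: bool = True,
) -> dict[str, float]:
    """Min/max/mean/median CoP path speed per stance, averaged over stances.

    Per-frame speed is the Euclidean CoP displacement times the frame
    rate (mm/s). With ``normalize_by_stance_time`` each stance's statistic
    is additionally divided by that stance's duration in seconds — one
    reading of "normalised by stance time" for a quantity that is already
    a rate; the switch disables it.
    """
    stats = {"cop_vel_min": [], "cop_vel_max": [], "cop_vel_mean": [], "cop_vel_median": []}
    for ap, ml, dur in _stance_cop_arrays(insole, events):
        speed = np.hypot(np.diff(ap), np.diff(ml)) * insole.fs_hz
        scale = dur if normalize_by_stance_time else 1.0
        stats["cop_vel_min"].append(float(speed.min()) / scale)
        stats["cop_vel_max"].append(float(speed.max()) / scale)
        stats["cop_vel_mean"].append(float(speed.mean()) / scale)
        stats["cop_vel_median"].append(float(np.median(speed)) / scale)
    return {k: float(np.mean(v)) if v else np.nan for k, v in stats.items()}


def resample_stance(series: np.ndarray, n_points: int = ENSEMBLE_POINTS) -> np.ndarray:
    """Linearly resample one stance's series to 0-100% stance (101 points)."""
    x = np.linspace(0.0, 1.0, len(series))
    return np.interp(np.linspace(0.0, 1.0, n_points), x, series)


def _winter_cov(traces: np.ndarray) -> float:
    """Winter's ensemble CoV%: 100*sqrt(mean(sigma_i^2)) / mean(|mu_i|).

    ``traces`` is stances x points. Population (ddof=0) SDs across
    stances at each normalised time point.
    """
    mu = traces.mean(axis=0)
    sigma2 = traces.var(axis=0, ddof=0)
    denom = float(np.mean(np.abs(mu)))
    if denom == 0.0:
        return np.nan
    return 100.0 * float(np.sqrt(np.mean(sigma2))) / denom


def cop_cov_features(insole: InsoleStream, events: GaitEvents) -> dict[str, float]:
    """Ensemble AP and ML CoP path CoV over the stance phase for one foot.

    Each stance's CoP trace is resampled to 101 points (0-100% stance);
    the across-stance variability is summarised with Winter's CoV. At
    least two stances are required, otherwise the features are missing.
    """
    arrays = _stance_cop_arrays(insole, events)
    if len(arrays) < 2:
        return {"cop_cov_ap_pct": np.nan, "cop_cov_ml_pct": np.nan}
    ap_traces = np.vstack([resample_stance(ap) for ap, _, _ in arrays])
    ml_traces = np.vstack([resample_stance(ml) for _, ml, _ in arrays])
    return {
        "cop_cov_ap_pct": _winter_cov(ap_traces),
        "cop_cov_ml_pct": _winter_cov(ml_traces),
    }


# --------------------------------------------------------------------------
# Temporal features
# --------------------------------------------------------------------------

def _per_foot_times(events: GaitEvents) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stride, stance, swing) times per interior stride of one foot."""
    stride = events.stride_times_s()
    stance = events.stance_times_s()[: len(stride)]
    swing = stride - stance
    return stride, stance, swing


def _cov_pct(values: np.ndarray) -> float:
    """Stride-to-stride coefficient of variation, sample SD (ddof=1)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.mean(values) == 0:
        return np.nan
    return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))


def temporal_features(
    events_left: GaitEvents | None, events_right: GaitEvents | None
) -> dict[str, float]:
    """The 11 temporal gait parameters from both feet's event sets.

    Per-stride times are pooled across feet for means and CoVs; the
    symmetry index and double support need bilateral events and are
    missing (NaN) otherwise.
    """
    sides = []
    for ev in (events_left, events_right):
        if ev is not None and ev.n_stances >= 2:
            sides.append(_per_foot_times(ev))
    if not sides:
        return {name: np.nan for name in TEMPORAL_FEATURES}

    stride = np.concatenate([s[0] for s in sides])
    stance = np.concatenate([s[1] for s in sides])
    swing = np.concatenate([s[2] for s in sides])
    out = {
        "stride_time_s": float(stride.mean()),
        "stance_time_s": float(stance.mean()),
        "swing_time_s": float(swing.mean()),
        "pct_stance": 100.0 * float(np.mean(stance / stride)),
        "cov_stride_pct": _cov_pct(stride),
        "cov_stance_pct": _cov_pct(stance),
        "cov_swing_pct": _cov_pct(swing),
        "cadence_steps_per_min": 120.0 / float(stride.mean()),
    }

    bilateral = (
        events_left is not None
        and events_right is not None
        and events_left.n_stances >= 2
        and events_right.n_stances >= 2
    )
    if bilateral:
        l_mean = float(events_left.stride_times_s().mean())
        r_mean = float(events_right.stride_times_s().mean())
        out["stride_time_si_pct"] = 100.0 * abs(l_mean - r_mean) / (0.5 * (l_mean + r_mean))
        overlaps = double_support_overlaps(events_left, events_right)
        l_strides = events_left.stride_times_s()
        n = min(len(overlaps), len(l_strides))
        if n:
            out["pct_double_support"] = 100.0 * float(np.mean(overlaps[:n] / l_strides[:n]))
            out["double_support_time_s"] = float(np.mean(overlaps[:n]))
        else:
            out["pct_double_support"] = np.nan
            out["double_support_time_s"] = np.nan
    else:
        out["stride_time_si_pct"] = np.nan
        out["pct_double_support"] = np.nan
        out["double_support_time_s"] = np.nan
    return {name: out[name] for name in TEMPORAL_FEATURES}


# --------------------------------------------------------------------------
# Impulse features
# --------------------------------------------------------------------------

@dataclass
class StanceLandmarks:
    """Frame offsets of the impulse-phase boundaries within one stance."""

    first_peak: int
    minimum: int
    second_peak: int


def find_stance_landmarks(force: np.ndarray, fs_hz: float) -> StanceLandmarks | None:
    """Locate first peak, mid-stance minimum and second peak of a stance
    force curve, on a lightly smoothed (10 Hz low-pass) copy.

    Returns None if the curve has no double-bump morphology.
    """
    force = np.asarray(force, dtype=float)
    if len(force) < 8:
        return None
    if len(force) > 30:
        smooth = lowpass_filter(force, fs_hz, IMPULSE_SMOOTHING_HZ, order=4)
    else:
        smooth = force
    # interior local extrema
    d = np.diff(smooth)
    maxima = [i for i in range(1, len(smooth) - 1) if d[i - 1] > 0 >= d[i]]
    if not maxima:
        return None
    p1 = maxima[0]
    minima = [i for i in range(p1 + 1, len(smooth) - 1) if d[i - 1] <= 0 < d[i]]
    if not minima:
        return None
    v = minima[0]
    later_maxima = [i for i in maxima if i > v]
    if not later_maxima:
        return None
    return StanceLandmarks(first_peak=p1, minimum=v, second_peak=later_maxima[0])


def _segment_impulse(force: np.ndarray, fs_hz: float, a: int, b: int) -> float:
    """Trapezoidal integral of force (N) over frames [a, b], in N*s."""
    return float(np.trapezoid(force[a : b + 1])) / fs_hz


def impulse_features(
    insole: InsoleStream, events: GaitEvents, mass_kg: float
) -> dict[str, float]:
    """Impulses I1-I7 (N*s/kg), averaged over this foot's stances.

    I1: foot strike to first force peak; I2: first peak to mid-stance
    minimum; I3: minimum to second peak; I4: second peak to foot off;
    I5 = I1+I2, I6 = I3+I4, I7 = I5+I6 (whole stance). Stances without a
    detectable double bump contribute only to I7; if more than half the
    stances fail, I1-I6 are missing for the trial.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    per = {name: [] for name in IMPULSE_FEATURES}
    n_stances = 0
    n_failed = 0
    for fs, fo in zip(events.foot_strike_frames, events.foot_off_frames):
        force = np.asarray(insole.total_force_n[int(fs) : int(fo)], dtype=float)
        if len(force) < 4:
            continue
        n_stances += 1
        end = len(force) - 1
        per["i7_nspkg"].append(_segment_impulse(force, insole.fs_hz, 0, end) / mass_kg)
        lm = find_stance_landmarks(force, insole.fs_hz)
        if lm is None:
            n_failed += 1
            continue
        i1 = _segment_impulse(force, insole.fs_hz, 0, lm.first_peak) / mass_kg
        i2 = _segment_impulse(force, insole.fs_hz, lm.first_peak, lm.minimum) / mass_kg
        i3 = _segment_impulse(force, insole.fs_hz, lm.minimum, lm.second_peak) / mass_kg
        i4 = _segment_impulse(force, insole.fs_hz, lm.second_peak, end) / mass_kg
        per["i1_nspkg"].append(i1)
        per["i2_nspkg"].append(i2)
        per["i3_nspkg"].append(i3)
        per["i4_nspkg"].append(i4)
        per["i5_nspkg"].append(i1 + i2)
        per["i6_nspkg"].append(i3 + i4)
    out = {k: float(np.mean(v)) if v else np.nan for k, v in per.items()}
    if n_stances and n_failed > 0.5 * n_stances:
        for name in IMPULSE_FEATURES[:6]:
            out[name] = np.nan
    return out


# --------------------------------------------------------------------------
# Trial-level extraction
# --------------------------------------------------------------------------

def _pool(feature_dicts: list[dict[str, float]], names: list[str]) -> dict[str, float]:
    """Average per-foot feature values, ignoring missing feet."""
    out = {}
    for name in names:
        vals = [d[name] for d in feature_dicts if np.isfinite(d.get(name, np.nan))]
        out[name] = float(np.mean(vals)) if vals else np.nan
    return out


def extract_insole_features(
    trial: SensorTrial,
    mass_kg: float | None = None,
    normalize_velocity: bool = True,
    ml_threshold: float = ML_DEVIATION_THRESHOLD_MM_PER_FRAME,
) -> dict[str, float]:
    """Compute all 30 insole features for one trial.

    Stance phases are detected from each foot's force stream; per-stance
    features are computed per foot and averaged across both feet. A trial
    with no insole stream returns all-NaN (the participant is dropped
    from insole-based sensor combinations downstream).
    """
    mass = mass_kg if mass_kg is not None else trial.mass_kg
    if mass is None:
        raise ValueError("body mass required for insole features")
    feet = []
    events_by_side: dict[str, GaitEvents] = {}
    for side, stream in (("left", trial.insole_left), ("right", trial.insole_right)):
        if stream is None:
            continue
        events = detect_stance_phases(stream, mass_kg=mass)
        events_by_side[side] = events
        foot = {}
        foot.update(cop_deviation_features(stream, events, ml_threshold=ml_threshold))
        foot.update(cop_velocity_features(stream, events, normalize_by_stance_time=normalize_velocity))
        foot.update(cop_cov_features(stream, events))
        foot.update(impulse_features(stream, events, mass))
        feet.append(foot)

    out = _pool(feet, COP_FEATURES + IMPULSE_FEATURES) if feet else {
        name: np.nan for name in COP_FEATURES + IMPULSE_FEATURES
    }
    out.update(temporal_features(events_by_side.get("left"), events_by_side.get("right")))
    return {name: out[name] for name in INSOLE_FEATURE_NAMES}
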