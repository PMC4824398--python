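"""Gait-event detection: stance phases from insole force, strides from
accelerations.

The two detectors are independent: accelerometer-only sensor combinations
must produce cadence and stride time without any insole, and insole
features never consult the accelerometers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal

from .errors import InsufficientSignalError
from .io import lowpass_filter
from .types import AccelStream, GaitEvents, InsoleStream

GRAVITY_M_S2 = 9.81

#: Default contact threshold as a fraction of body weight. A conventional
#: stance-detection level; shared with the generator's CoP-validity flag.
DEFAULT_THRESHOLD_FRACTION_BW = 0.05

#: Supra-threshold runs shorter than this are discarded as noise.
MIN_STANCE_S = 0.1


def detect_stance_phases(
    insole: InsoleStream,
    mass_kg: float,
    threshold_fraction_bw: float = DEFAULT_THRESHOLD_FRACTION_BW,
    min_stance_s: float = MIN_STANCE_S,
) -> GaitEvents:
    """Segment stance phases of one foot by force thresholding.

    Foot strike is the first frame of a supra-threshold run and foot off
    the first frame after it. Runs shorter than ``min_stance_s`` are
    treated as noise; runs touching the start or end of the recording are
    partial contacts and discarded. Because the threshold is a fraction
    of body weight, detection is invariant to uniform force scaling
    applied together with mass.
    """
    if not 0.0 < threshold_fraction_bw < 1.0:
        raise ValueError("threshold_fraction_bw must lie in (0, 1)")
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    force = np.asarray(insole.total_force_n, dtype=float)
    threshold = threshold_fraction_bw * mass_kg * GRAVITY_M_S2
    above = force >= threshold

    edges = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # first frame after each run

    min_frames = int(np.ceil(min_stance_s * insole.fs_hz))
    keep_fs, keep_fo = [], []
    for s, e in zip(starts, ends):
        if s == 0 or e == len(force):
            continue  # partial first/last contact
        if e - s < min_frames:
            continue
        keep_fs.append(int(s))
        keep_fo.append(int(e))

    if not keep_fs:
        warnings.warn("no stance phases detected above threshold", stacklevel=2)
    return GaitEvents(np.asarray(keep_fs), np.asarray(keep_fo), insole.fs_hz)


def _dominant_period_samples(x: np.ndarray, fs_hz: float) -> int:
    """Stride period estimate from the autocorrelation of a filtered signal.

    Searches lags between 0.4 s and 4 s and returns the smallest lag whose
    autocorrelation reaches 95% of the range maximum. Preferring the
    smallest near-maximal lag picks the full stride period rather than a
    multiple, while genuine half-period (step) lags fall below the band
    whenever the two steps of a stride are at all distinguishable.
    """
    x = x - x.mean()
    n = len(x)
    lo = max(2, int(round(0.4 * fs_hz)))
    hi = min(int(round(4.0 * fs_hz)), n // 2)
    if hi <= lo:
        raise InsufficientSignalError("series too short for period estimation")
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    band = ac[lo:hi]
    peak = band.max()
    if peak <= 0:
        raise InsufficientSignalError("no periodic structure in signal")
    candidates = np.flatnonzero(band >= 0.95 * peak)
    return int(lo + candidates[0])


def detect_strides_accel(accel: AccelStream) -> tuple[np.ndarray, float]:
    """Stride times and cadence from the vertical acceleration.

    The vertical axis is low-pass filtered (5th-order Butterworth,
    12.5 Hz, zero phase), the stride period is estimated from the
    autocorrelation, and stride boundaries are the dominant peaks found
    with a minimum separation of 0.6 stride periods. Cadence is
    ``120 / mean stride time`` (two steps per stride).

    Returns ``(stride_times_s, cadence_steps_per_min)``.
    """
    x = np.asarray(accel.vertical, dtype=float)
    if len(x) < int(2.0 * accel.fs_hz) or np.std(x) < 1e-12:
        raise InsufficientSignalError("not enough signal to detect strides")
    filtered = lowpass_filter(x, accel.fs_hz, 12.5, 5)
    period = _dominant_period_samples(filtered, accel.fs_hz)
    peaks, _ = sp_signal.find_peaks(filtered, distance=max(1, int(round(0.6 * period))))
    if len(peaks) < 2:
        raise InsufficientSignalError("fewer than two stride peaks detected")
    stride_times = np.diff(peaks) / accel.fs_hz
    cadence = 120.0 / float(np.mean(stride_times))
    return stride_times, cadence


def double_support_overlaps(
    events_left: GaitEvents, events_right: GaitEvents
) -> np.ndarray:
    """Per-(left-)stride double-support duration in seconds.

    For each left stride ``[FS_i, FS_{i+1})`` the total time both feet are
    simultaneously in stance, assuming the two insole streams share a
    synchronized clock.
    """
    fs_hz = events_left.fs_hz
    l_fs = np.asarray(events_left.foot_strike_frames)
    l_fo = np.asarray(events_left.foot_off_frames)
    r_fs = np.asarray(events_right.foot_strike_frames)
    r_fo = np.asarray(events_right.foot_off_frames)
    out = []
    for i in range(len(l_fs) - 1):
        # within this stride the left foot is loaded only during
        # [FS_i, FO_i), so double support is that interval's intersection
        # with the right stances, clipped to the stride window
        left_lo = l_fs[i]
        left_hi = min(l_fs[i + 1], l_fo[i])
        overlap = 0.0
        for j in range(len(r_fs)):
            lo = max(left_lo, r_fs[j])
            hi = min(left_hi, r_fo[j])
            if hi > lo:
                overlap += hi - lo
        out.append(overlap / fs_hz)
    return np.asarray(out)
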