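"""Accelerometer gait parameters: 29 features per body site.

Families:

* 18 descriptive statistics — max, mean and SD of acceleration magnitude
  for each directional half-axis (superior, inferior, anterior,
  posterior, right, left), computed on the filtered signal.
* 2 temporal — cadence and stride time from vertical-axis peak timing.
* 3 FFT quartile — percentage of spectral content at frequencies
  <= 12.5 Hz, per axis, on the unfiltered signal.
* 3 REOH — ratio of even to odd harmonics of stride frequency, per axis,
  on the unfiltered signal; indexes how much of the signal is in phase
  with the stride (gait smoothness).
* 3 MLE — maximum Lyapunov exponent per axis (1/s), Rosenstein's method
  on a delay embedding whose lag comes from the first minimum of the
  average mutual information and whose dimension from the global false
  nearest neighbours criterion; computed on the filtered signal.

Filtering assignment: descriptive statistics and MLE consume the
5th-order 12.5 Hz zero-phase Butterworth output; FFT quartile and REOH
consume the raw signal.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateSignalError, InsufficientSignalError
from .events import detect_strides_accel
from .io import lowpass_filter
from .types import AccelStream

FFT_QUARTILE_CUTOFF_HZ = 12.5
REOH_DEFAULT_HARMONICS = 20

_HALF_AXES = {
    "vertical": ("superior", "inferior"),
    "ap": ("anterior", "posterior"),
    "ml": ("right", "left"),
}

DIRECTIONAL_FEATURES = [
    f"{stat}_{direction}"
    for direction in ("superior", "inferior", "anterior", "posterior", "right", "left")
    for stat in ("max", "mean", "sd")
]

#: Canonical order of the 29 accelerometer features (per site).
ACCEL_FEATURE_NAMES = (
    DIRECTIONAL_FEATURES
    + ["cadence_steps_per_min", "stride_time_s"]
    + ["fftq_vert", "fftq_ap", "fftq_ml"]
    + ["reoh_vert", "reoh_ap", "reoh_ml"]
    + ["mle_vert", "mle_ap", "mle_ml"]
)


# --------------------------------------------------------------------------
# Descriptive statistics
# --------------------------------------------------------------------------

def directional_stats(accel: AccelStream) -> dict[str, float]:
    """Max/mean/SD of acceleration magnitude per directional half-axis.

    The stream is assumed filtered. Each axis is split by sign: e.g.
    superior = positive vertical samples, inferior = magnitudes of
    negative vertical samples. An empty half-axis yields zeros.
    """
    out: dict[str, float] = {}
    for axis, (pos_name, neg_name) in _HALF_AXES.items():
        x = np.asarray(accel.axis(axis), dtype=float)
        for name, part in ((pos_name, x[x > 0]), (neg_name, -x[x < 0])):
            if len(part) == 0:
                out[f"max_{name}"] = 0.0
                out[f"mean_{name}"] = 0.0
                out[f"sd_{name}"] = 0.0
            else:
                out[f"max_{name}"] = float(part.max())
                out[f"mean_{name}"] = float(part.mean())
                out[f"sd_{name}"] = float(part.std(ddof=0))
    return out


# --------------------------------------------------------------------------
# Spectral features (unfiltered input)
# --------------------------------------------------------------------------

def fft_quartile(
    series: np.ndarray,
    fs_hz: float,
    cutoff_hz: float = FFT_QUARTILE_CUTOFF_HZ,
    mode: str = "magnitude",
) -> float:
    """Percentage of spectral content at frequencies <= ``cutoff_hz``.

    DC is excluded; the denominator runs over all positive frequencies up
    to Nyquist. ``mode`` selects summed spectral magnitude (default) or
    power. Amplitude scaling of the input cancels out.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 128:
        raise InsufficientSignalError("fft_quartile needs at least 128 samples")
    if mode not in ("magnitude", "power"):
        raise ValueError("mode must be 'magnitude' or 'power'")
    spectrum = np.abs(np.fft.rfft(series - series.mean()))
    if mode == "power":
        spectrum = spectrum**2
    freqs = np.fft.rfftfreq(len(series), d=1.0 / fs_hz)
    denom = spectrum[freqs > 0].sum()
    if denom == 0:
        return np.nan
    num = spectrum[(freqs > 0) & (freqs <= cutoff_hz)].sum()
    return 100.0 * float(num) / float(denom)


def reoh(
    series: np.ndarray,
    stride_freq_hz: float,
    fs_hz: float,
    n_harmonics: int = REOH_DEFAULT_HARMONICS,
) -> float:
    """Ratio of even to odd harmonics of the stride frequency.

    Harmonic amplitudes A_k are the spectral magnitudes at k times the
    stride frequency (largest magnitude within +-1 frequency bin), for
    k = 1..n_harmonics capped below Nyquist;
    REOH = sum(A_even) / (sum(A_even) + sum(A_odd)), in [0, 1]. Even
    harmonics correspond to step-frequency content, i.e. the component in
    phase with the gait cycle.
    """
    if stride_freq_hz <= 0:
        raise ValueError("stride frequency must be positive")
    series = np.asarray(series, dtype=float)
    spectrum = np.abs(np.fft.rfft(series - series.mean()))
    n = len(series)
    bin_hz = fs_hz / n
    even = odd = 0.0
    for k in range(1, n_harmonics + 1):
        f = k * stride_freq_hz
        if f >= fs_hz / 2.0:
            break
        b = int(round(f / bin_hz))
        lo, hi = max(b - 1, 0), min(b + 2, len(spectrum))
        amp = float(spectrum[lo:hi].max())
        if k % 2 == 0:
            even += amp
        else:
            odd += amp
    total = even + odd
    if total == 0:
        return np.nan
    return even / total


# --------------------------------------------------------------------------
# Delay-embedding machinery
# --------------------------------------------------------------------------

def _binned_mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information (nats) of two series via a joint histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def ami_delay(series: np.ndarray, max_lag: int = 50, n_bins: int = 16) -> int:
    """Embedding delay from the first minimum of the average mutual
    information.

    AMI is evaluated at lags 0..max_lag from a joint histogram of the
    series against its lagged copy; the smallest lag >= 1 that is a local
    minimum is returned. If no local minimum exists (e.g. white noise,
    where AMI is flat and near zero), the argmin over the range is
    returned with a warning.
    """
    series = np.asarray(series, dtype=float)
    if len(series) <= 4 * max_lag:
        max_lag = max(2, len(series) // 4)
    if np.ptp(series) == 0:
        raise DegenerateSignalError("AMI undefined for constant series")
    ami = np.empty(max_lag + 1)
    ami[0] = _binned_mutual_information(series, series, n_bins)
    for tau in range(1, max_lag + 1):
        ami[tau] = _binned_mutual_information(series[:-tau], series[tau:], n_bins)
    for tau in range(1, max_lag):
        if ami[tau] <= ami[tau - 1] and ami[tau] < ami[tau + 1]:
            return tau
    warnings.warn("no AMI local minimum; using argmin over lag range", stacklevel=2)
    return int(np.argmin(ami[1:]) + 1)


def average_mutual_information(
    series: np.ndarray, max_lag: int, n_bins: int = 16
) -> np.ndarray:
    """AMI(tau) for tau = 0..max_lag (nats)."""
    series = np.asarray(series, dtype=float)
    out = np.empty(max_lag + 1)
    out[0] = _binned_mutual_information(series, series, n_bins)
    for tau in range(1, max_lag + 1):
        out[tau] = _binned_mutual_information(series[:-tau], series[tau:], n_bins)
    return out


def _embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay embedding: rows X[i] = (x_i, x_{i+d}, ..., x_{i+(m-1)d})."""
    n = len(series) - (dim - 1) * delay
    if n < 2:
        raise InsufficientSignalError("series too short for requested embedding")
    return np.column_stack([series[j * delay : j * delay + n] for j in range(dim)])


def fnn_dimension(
    series: np.ndarray,
    delay: int,
    max_dim: int = 6,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Embedding dimension via the global false nearest neighbours method.

    For each dimension m, nearest neighbours are found in the
    m-dimensional embedding; a neighbour is false if adding the (m+1)-th
    coordinate stretches the pair by more than ``rtol`` relative to its
    m-dimensional distance, or beyond ``atol`` times the signal's overall
    spread (Kennel's two criteria). Returns the smallest m with a false
    fraction below ``threshold``; if none embeds by ``max_dim`` (as for
    noise, which never does), returns ``max_dim`` with a warning.
    """
    series = np.asarray(series, dtype=float)
    spread = float(series.std())
    if spread == 0:
        raise DegenerateSignalError("FNN undefined for constant series")
    for m in range(1, max_dim + 1):
        n = len(series) - m * delay
        if n < 10:
            warnings.warn("series too short to test higher dimensions", stacklevel=2)
            return m
        emb = _embed(series[: len(series) - delay], m, delay)[:n]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        d_m = dist[:, 1]
        nn = idx[:, 1]
        extra = np.abs(series[np.arange(n) + m * delay] - series[nn + m * delay])
        # exact/near duplicates (periodic signals sampled commensurately)
        # are true neighbours unless the extension separates them
        eps = 1e-9 * spread
        ratio = extra / np.maximum(d_m, eps)
        d_m1 = np.sqrt(d_m**2 + extra**2)
        false = (ratio > rtol) | (d_m1 / spread > atol)
        if np.mean(false) < threshold:
            return m
    warnings.warn(
        f"false-neighbour fraction never fell below {threshold}; returning max_dim",
        stacklevel=2,
    )
    return max_dim


def _mean_period_samples(series: np.ndarray, fs_hz: float) -> float:
    """Mean period (samples) from the power-weighted mean frequency."""
    spectrum = np.abs(np.fft.rfft(series - series.mean())) ** 2
    freqs = np.fft.rfftfreq(len(series), d=1.0 / fs_hz)
    power = spectrum[freqs > 0]
    if power.sum() == 0:
        raise DegenerateSignalError("flat spectrum; mean period undefined")
    mean_freq = float((freqs[freqs > 0] * power).sum() / power.sum())
    return fs_hz / mean_freq


def max_lyapunov(
    series: np.ndarray,
    fs_hz: float,
    delay: int,
    dim: int,
    fit_window: int | None = None,
) -> float:
    """Maximum Lyapunov exponent (1/s) by Rosenstein's method.

    The series is delay-embedded; each point is paired with its nearest
    neighbour at temporal separation greater than the mean period; the
    average log divergence <ln d(j)> is tracked over j steps and the MLE
    is the least-squares slope over the fit window (default: 0 to half
    the mean period), converted to 1/s with the sampling rate.
    """
    series = np.asarray(series, dtype=float)
    emb = _embed(series, dim, delay)
    n = len(emb)
    if n < 100:
        raise InsufficientSignalError("need at least 100 embedded points")
    period = _mean_period_samples(series, fs_hz)
    min_sep = max(1, int(round(period)))
    if fit_window is None:
        fit_window = max(2, int(round(0.5 * period)))

    # nearest neighbour outside the temporal exclusion window, blockwise;
    # near-zero distances (duplicate states from commensurate sampling)
    # are excluded — their log divergence would only measure rounding noise
    eps_dist = 1e-8 * max(float(series.std()), 1e-300)
    nn = np.full(n, -1)
    nn_dist = np.full(n, np.inf)
    block = 512
    idx = np.arange(n)
    for start in range(0, n, block):
        rows = slice(start, min(start + block, n))
        d = np.linalg.norm(emb[rows, None, :] - emb[None, :, :], axis=2)
        mask = np.abs(idx[rows, None] - idx[None, :]) <= min_sep
        d[mask] = np.inf
        d[d < eps_dist] = np.inf
        nn[rows] = np.argmin(d, axis=1)
        nn_dist[rows] = d[np.arange(d.shape[0]), nn[rows]]

    usable = np.flatnonzero(np.isfinite(nn_dist))
    if len(usable) < 10:
        raise InsufficientSignalError("too few neighbour pairs for divergence tracking")

    log_div = []
    for j in range(fit_window + 1):
        valid = usable[(usable + j < n) & (nn[usable] + j < n)]
        if len(valid) < 5:
            break
        d_j = np.linalg.norm(emb[valid + j] - emb[nn[valid] + j], axis=1)
        d_j = d_j[d_j > 0]
        if len(d_j) == 0:
            break
        log_div.append(float(np.mean(np.log(d_j))))
    if len(log_div) < 2:
        raise InsufficientSignalError("divergence curve too short for a slope fit")
    steps = np.arange(len(log_div))
    slope = float(np.polyfit(steps, log_div, 1)[0])
    return slope * fs_hz


def lyapunov_pipeline(
    series: np.ndarray,
    fs_hz: float,
    max_lag: int = 50,
    n_bins: int = 16,
    max_dim: int = 6,
) -> float:
    """AMI delay -> FNN dimension -> Rosenstein MLE, end to end."""
    delay = ami_delay(series, max_lag=max_lag, n_bins=n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dim = fnn_dimension(series, delay, max_dim=max_dim)
    return max_lyapunov(series, fs_hz, delay, dim)


# --------------------------------------------------------------------------
# Site-level extraction
# --------------------------------------------------------------------------

_AXIS_SUFFIX = {"vertical": "vert", "ap": "ap", "ml": "ml"}


def extract_accel_features(accel: AccelStream) -> dict[str, float]:
    """Compute all 29 accelerometer features for one site's stream.

    Stride detection or nonlinear-dynamics failures degrade the affected
    features to NaN rather than aborting the trial.
    """
    filtered = AccelStream(
        vertical=lowpass_filter(accel.vertical, accel.fs_hz),
        ap=lowpass_filter(accel.ap, accel.fs_hz),
        ml=lowpass_filter(accel.ml, accel.fs_hz),
        fs_hz=accel.fs_hz,
    )
    out = directional_stats(filtered)

    try:
        stride_times, cadence = detect_strides_accel(accel)
        stride_time = float(np.mean(stride_times))
    except InsufficientSignalError:
        warnings.warn("stride detection failed; temporal/REOH features missing", stacklevel=2)
        stride_time = np.nan
        cadence = np.nan
    out["cadence_steps_per_min"] = cadence
    out["stride_time_s"] = stride_time

    for axis, suffix in _AXIS_SUFFIX.items():
        raw = np.asarray(accel.axis(axis), dtype=float)
        try:
            out[f"fftq_{suffix}"] = fft_quartile(raw, accel.fs_hz)
        except InsufficientSignalError:
            out[f"fftq_{suffix}"] = np.nan
        if np.isfinite(stride_time) and stride_time > 0:
            out[f"reoh_{suffix}"] = reoh(raw, 1.0 / stride_time, accel.fs_hz)
        else:
            out[f"reoh_{suffix}"] = np.nan
        try:
            out[f"mle_{suffix}"] = lyapunov_pipeline(filtered.axis(axis), accel.fs_hz)
        except (InsufficientSignalError, DegenerateSignalError):
            out[f"mle_{suffix}"] = np.nan
    return {name: out[name] for name in ACCEL_FEATURE_NAMES}
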