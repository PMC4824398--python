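"""The 30 plantar-pressure features against hand-computed oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from gaitrisk.insole import (
    INSOLE_FEATURE_NAMES,
    cop_cov_features,
    cop_deviation_features,
    cop_velocity_features,
    extract_insole_features,
    impulse_features,
    resample_stance,
    temporal_features,
)
from gaitrisk.types import GaitEvents, InsoleStream


def _stream(ap, ml=None, force=None, valid=None):
    ap = np.asarray(ap, dtype=float)
    ml = np.zeros_like(ap) if ml is None else np.asarray(ml, dtype=float)
    force = np.full_like(ap, 500.0) if force is None else np.asarray(force, dtype=float)
    valid = np.ones_like(ap, dtype=bool) if valid is None else valid
    return InsoleStream(force, ap, ml, valid)


def _one_stance(n):
    return GaitEvents(np.array([0]), np.array([n]), 120.0)


# --------------------------------------------------------------------------
# CoP deviations
# --------------------------------------------------------------------------

def test_monotone_anterior_path_has_no_deviations():
    ap = np.cumsum(np.full(80, 1.0))
    out = cop_deviation_features(_stream(ap), _one_stance(80))
    assert out["pd_count"] == 0 and out["ml_dev_count"] == 0
    assert out["pd_length_mm"] == 0 and out["pd_duration_s"] == 0


def test_two_injected_posterior_pulses_counted_exactly():
    steps = np.full(80, 1.0)
    steps[20:23] = -1.0  # 3 frames at -1 mm/frame
    steps[50:53] = -1.0
    ap = np.cumsum(steps)
    out = cop_deviation_features(_stream(ap), _one_stance(80))
    assert out["pd_count"] == 2
    assert out["pd_length_mm"] == pytest.approx(3.0)
    assert out["pd_duration_s"] == pytest.approx(3 / 120.0)


def test_single_ml_step_above_dual_threshold_counts():
    ml = np.zeros(60)
    ml[30:] = 0.6  # one step of 0.6 mm/frame > 0.5
    ap = np.cumsum(np.full(60, 1.0))
    out = cop_deviation_features(_stream(ap, ml=ml), _one_stance(60))
    assert out["ml_dev_count"] == 1
    assert out["ml_dev_length_mm"] == pytest.approx(0.6)
    assert out["ml_dev_duration_s"] == pytest.approx(1 / 120.0)


def test_subthreshold_ml_steps_ignored():
    ml = np.cumsum(np.full(60, 0.4))  # all steps below 0.5 mm/frame
    ap = np.cumsum(np.full(60, 1.0))
    out = cop_deviation_features(_stream(ap, ml=ml), _one_stance(60))
    assert out["ml_dev_count"] == 0


def test_stance_with_too_few_valid_frames_skipped_with_warning():
    ap = np.cumsum(np.full(40, 1.0))
    valid = np.zeros(40, dtype=bool)
    valid[:2] = True
    with pytest.warns(UserWarning, match="valid CoP"):
        out = cop_deviation_features(_stream(ap, valid=valid), _one_stance(40))
    assert np.isnan(out["pd_count"])


# --------------------------------------------------------------------------
# CoP velocities
# --------------------------------------------------------------------------

def test_velocity_normalization_arithmetic():
    ap = np.cumsum(np.full(72, 1.0))  # 1 mm/frame over a 0.6 s stance
    raw = cop_velocity_features(_stream(ap), _one_stance(72), normalize_by_stance_time=False)
    norm = cop_velocity_features(_stream(ap), _one_stance(72), normalize_by_stance_time=True)
    assert raw["cop_vel_mean"] == pytest.approx(120.0)
    assert norm["cop_vel_mean"] == pytest.approx(200.0)


def test_stationary_cop_has_zero_velocities():
    out = cop_velocity_features(_stream(np.full(60, 40.0)), _one_stance(60))
    for key in ("cop_vel_min", "cop_vel_max", "cop_vel_mean", "cop_vel_median"):
        assert out[key] == 0.0


def test_velocity_median_definition():
    ap = np.concatenate([[0.0], np.cumsum([1.0, 2.0, 3.0])])
    out = cop_velocity_features(_stream(ap), _one_stance(4), normalize_by_stance_time=False)
    assert out["cop_vel_median"] == pytest.approx(2.0 * 120.0)
    assert out["cop_vel_min"] == pytest.approx(120.0)
    assert out["cop_vel_max"] == pytest.approx(360.0)


def test_velocity_order_invariant():
    rng = np.random.default_rng(3)
    ap = np.cumsum(rng.uniform(0.1, 2.0, 90))
    out = cop_velocity_features(_stream(ap), _one_stance(90))
    assert out["cop_vel_min"] <= out["cop_vel_median"] <= out["cop_vel_max"]


# --------------------------------------------------------------------------
# Ensemble CoV (Winter)
# --------------------------------------------------------------------------

def test_identical_stances_have_zero_cov():
    m = np.linspace(30.0, 210.0, 101)
    ap = np.concatenate([m, np.zeros(50), m])
    valid = np.ones(252, dtype=bool)
    valid[101:151] = False
    events = GaitEvents(np.array([0, 151]), np.array([101, 252]), 120.0)
    out = cop_cov_features(_stream(ap, valid=valid), events)
    assert out["cop_cov_ap_pct"] == pytest.approx(0.0, abs=1e-12)


def test_constant_offset_pair_matches_closed_form():
    m = np.linspace(30.0, 210.0, 101)
    c = 5.0
    ap = np.concatenate([m + c, np.zeros(50), m - c])
    valid = np.ones(252, dtype=bool)
    valid[101:151] = False
    events = GaitEvents(np.array([0, 151]), np.array([101, 252]), 120.0)
    out = cop_cov_features(_stream(ap, valid=valid), events)
    # sigma_i = c everywhere; mean |mu| = mean of m = 120
    assert out["cop_cov_ap_pct"] == pytest.approx(100.0 * c / np.mean(np.abs(m)))


def test_resampler_always_yields_101_points():
    assert len(resample_stance(np.arange(61.0))) == 101
    assert len(resample_stance(np.arange(73.0))) == 101


def test_single_stance_cov_is_missing():
    ap = np.cumsum(np.full(80, 1.0))
    out = cop_cov_features(_stream(ap), _one_stance(80))
    assert np.isnan(out["cop_cov_ap_pct"])


# --------------------------------------------------------------------------
# Temporal features
# --------------------------------------------------------------------------

def _periodic_events(offset=0):
    fs = np.array([120, 240, 360, 480]) + offset
    fo = fs + 72
    return GaitEvents(fs, fo, 120.0)


def test_periodic_gait_temporal_values():
    left = _periodic_events()
    right = GaitEvents(np.array([60, 180, 300, 420, 540]),
                       np.array([60, 180, 300, 420, 540]) + 72, 120.0)
    out = temporal_features(left, right)
    assert out["stride_time_s"] == pytest.approx(1.0)
    assert out["pct_stance"] == pytest.approx(60.0)
    assert out["cov_stride_pct"] == pytest.approx(0.0, abs=1e-9)
    assert out["stride_time_si_pct"] == pytest.approx(0.0)
    assert out["cadence_steps_per_min"] == pytest.approx(120.0)
    # stance 60% of stride -> both feet down 2*(60-50)% = 20% of the stride
    assert out["pct_double_support"] == pytest.approx(20.0)
    assert out["double_support_time_s"] == pytest.approx(0.2)


def test_symmetry_index_formula():
    left = GaitEvents(np.array([0, 132, 264]), np.array([66, 198, 330]), 120.0)   # 1.1 s strides
    right = GaitEvents(np.array([0, 108, 216]), np.array([54, 162, 270]), 120.0)  # 0.9 s strides
    out = temporal_features(left, right)
    assert out["stride_time_si_pct"] == pytest.approx(100.0 * 0.2 / 1.0)


def test_stride_cov_matches_two_pass_oracle():
    fs = np.array([0, 120, 252, 360])  # strides 1.0, 1.1, 0.9 s
    events = GaitEvents(fs, fs + 60, 120.0)
    out = temporal_features(events, None)
    strides = np.diff(fs) / 120.0
    mean = sum(strides) / len(strides)
    sd = (sum((s - mean) ** 2 for s in strides) / (len(strides) - 1)) ** 0.5
    assert out["cov_stride_pct"] == pytest.approx(100.0 * sd / mean)


def test_unilateral_events_flag_bilateral_features_missing():
    out = temporal_features(_periodic_events(), None)
    assert np.isfinite(out["stride_time_s"])
    assert np.isnan(out["stride_time_si_pct"])
    assert np.isnan(out["pct_double_support"])


def test_temporal_features_scale_under_time_dilation():
    left = _periodic_events()
    slow = GaitEvents(left.foot_strike_frames * 2, left.foot_off_frames * 2, 120.0)
    fast_out = temporal_features(left, None)
    slow_out = temporal_features(slow, None)
    assert slow_out["stride_time_s"] == pytest.approx(2 * fast_out["stride_time_s"])
    assert slow_out["pct_stance"] == pytest.approx(fast_out["pct_stance"])


# --------------------------------------------------------------------------
# Impulses
# --------------------------------------------------------------------------

def test_triangular_pulse_whole_stance_impulse():
    up = np.linspace(0.0, 800.0, 37)
    force = np.concatenate([up, up[::-1][1:]])  # 73 frames, 0.6 s, peak 800 N
    stream = _stream(np.cumsum(np.full(73, 1.0)), force=force)
    out = impulse_features(stream, _one_stance(73), mass_kg=80.0)
    assert out["i7_nspkg"] == pytest.approx(0.5 * 0.6 * 800.0 / 80.0)
    # single-peak curve: no double bump, I1-I6 missing for the trial
    assert np.isnan(out["i1_nspkg"])


def test_generator_m_curve_matches_analytic_integral(clean_trial):
    from gaitrisk.synthetic import FORCE_PEAK_BW, GRAVITY_M_S2, _m_curve

    insole = clean_trial.insole_left
    gt = clean_trial.ground_truth_events["left"]
    mass = clean_trial.mass_kg
    out = impulse_features(insole, gt, mass_kg=mass)
    stance_s = float(np.mean(gt.stance_times_s()))
    area, _ = quad(lambda tau: _m_curve(np.array([tau]))[0], 0.0, 1.0)
    analytic_i7 = FORCE_PEAK_BW * mass * GRAVITY_M_S2 * area * stance_s / mass
    assert out["i7_nspkg"] == pytest.approx(analytic_i7, rel=0.01)


def test_impulse_additivity_on_generator_stances(clean_trial):
    out = impulse_features(
        clean_trial.insole_left, clean_trial.ground_truth_events["left"],
        mass_kg=clean_trial.mass_kg,
    )
    assert out["i5_nspkg"] == pytest.approx(out["i1_nspkg"] + out["i2_nspkg"])
    assert out["i6_nspkg"] == pytest.approx(out["i3_nspkg"] + out["i4_nspkg"])
    # whole-stance integral equals the sum of independently integrated segments
    assert out["i7_nspkg"] == pytest.approx(out["i5_nspkg"] + out["i6_nspkg"], rel=1e-6)


def test_impulses_scale_inversely_with_mass(clean_trial):
    insole = clean_trial.insole_left
    gt = clean_trial.ground_truth_events["left"]
    a = impulse_features(insole, gt, mass_kg=60.0)
    b = impulse_features(insole, gt, mass_kg=120.0)
    assert a["i7_nspkg"] == pytest.approx(2.0 * b["i7_nspkg"])


# --------------------------------------------------------------------------
# Trial-level extraction
# --------------------------------------------------------------------------

def test_trial_emits_exactly_30_named_features(clean_trial):
    out = extract_insole_features(clean_trial)
    assert list(out) == INSOLE_FEATURE_NAMES
    assert len(out) == 30
    assert all(np.isfinite(v) for v in out.values())


def test_clean_trial_features_match_generator_parameters(clean_trial):
    out = extract_insole_features(clean_trial)
    assert out["stride_time_s"] == pytest.approx(1.2, abs=1 / 120.0)
    assert out["pct_stance"] == pytest.approx(62.0, abs=1.5)
    assert out["pd_count"] == 0.0
    assert out["ml_dev_count"] == 0.0
    assert out["stride_time_si_pct"] == pytest.approx(0.0, abs=0.5)
    assert out["cov_stride_pct"] == pytest.approx(0.0, abs=0.5)
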