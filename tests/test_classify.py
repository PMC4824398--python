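"""Sensor combinations, splits, model sweeps, metrics, and rank-sum
comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitrisk.classify import (
    CLINICAL_CODE,
    METRIC_NAMES,
    SENSOR_COMBINATIONS,
    ConfusionMatrix,
    FeatureMatrix,
    MetricSet,
    ModelReport,
    combination_columns,
    compute_metrics,
    confusion_from_rates,
    evaluate_combination,
    evaluate_model,
    rank_models,
    split_train_test,
    train_model,
)


def _matrix(X, y):
    idx = [f"s{i}" for i in range(len(X))]
    return FeatureMatrix(pd.DataFrame(X, index=idx), pd.Series(y, index=idx), "X", "ST")


# --------------------------------------------------------------------------
# Sensor combinations
# --------------------------------------------------------------------------

def test_there_are_31_sensor_combinations():
    assert len(SENSOR_COMBINATIONS) == 31
    assert len(set(SENSOR_COMBINATIONS)) == 31


@pytest.mark.parametrize(
    "combo,expected",
    [("I", 30), ("H", 29), ("P", 29), ("H-P", 58), ("LS-RS", 58), ("H-P-LS-RS", 116),
     ("I-P", 59), ("I-H-P", 88), ("I-H-P-LS-RS", 146), (CLINICAL_CODE, 7)],
)
def test_combination_column_counts(combo, expected):
    assert len(combination_columns(combo)) == expected


def test_every_combination_count_follows_30_29_rule():
    for combo in SENSOR_COMBINATIONS:
        parts = combo.split("-")
        expected = 30 * ("I" in parts) + 29 * sum(p != "I" for p in parts)
        assert len(combination_columns(combo)) == expected


def test_unknown_combination_rejected():
    with pytest.raises(ValueError):
        combination_columns("I-X")


# --------------------------------------------------------------------------
# Train/test split
# --------------------------------------------------------------------------

def test_split_24_76_cohort_gives_18_57_and_6_19():
    y = [True] * 24 + [False] * 76
    fm = _matrix(np.zeros((100, 3)), y)
    tr, te = split_train_test(fm, seed=0)
    assert (int(tr.y.sum()), int((~tr.y).sum())) == (18, 57)
    assert (int(te.y.sum()), int((~te.y).sum())) == (6, 19)


def test_split_small_even_cohort():
    fm = _matrix(np.zeros((8, 2)), [True] * 4 + [False] * 4)
    tr, te = split_train_test(fm, seed=1)
    assert (int(tr.y.sum()), int((~tr.y).sum())) == (3, 3)
    assert (int(te.y.sum()), int((~te.y).sum())) == (1, 1)


def test_split_deterministic_and_disjoint():
    y = [True] * 10 + [False] * 30
    fm = _matrix(np.arange(80).reshape(40, 2), y)
    tr1, te1 = split_train_test(fm, seed=5)
    tr2, te2 = split_train_test(fm, seed=5)
    assert list(tr1.X.index) == list(tr2.X.index)
    assert set(tr1.X.index).isdisjoint(te1.X.index)
    assert set(tr1.X.index) | set(te1.X.index) == set(fm.X.index)


def test_split_requires_two_members_per_class():
    fm = _matrix(np.zeros((5, 2)), [True] + [False] * 4)
    with pytest.raises(ValueError):
        split_train_test(fm, seed=0)


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------

def test_linear_svm_separates_linearly_separable_classes():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-3, 0.5, (40, 2)), rng.normal(3, 0.5, (40, 2))])
    y = [False] * 40 + [True] * 40
    fm = _matrix(X, y)
    model = train_model(fm, "SVM-1", seed=0)
    cm = evaluate_model(model, fm)  # training accuracy
    assert compute_metrics(cm).accuracy_pct == 100.0


def test_quadratic_svm_beats_linear_on_xor():
    acc = {1: [], 2: []}
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (200, 2))
        y = X[:, 0] * X[:, 1] > 0
        fm = _matrix(X, y)
        tr, te = split_train_test(fm, seed=seed)
        for deg in (1, 2):
            model = train_model(tr, f"SVM-{deg}", seed=seed)
            acc[deg].append(compute_metrics(evaluate_model(model, te)).accuracy_pct)
    assert np.mean(acc[2]) > np.mean(acc[1]) + 10.0


def test_linear_nb_approaches_analytic_bayes_rate():
    from scipy.stats import norm

    # two unit-variance Gaussians 1.5 apart: Bayes accuracy = Phi(0.75)
    bayes_pct = 100.0 * norm.cdf(0.75)
    rng = np.random.default_rng(3)
    n = 2000
    X = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(1.5, 1, n // 2)])[:, None]
    y = [False] * (n // 2) + [True] * (n // 2)
    fm = _matrix(X, y)
    tr, te = split_train_test(fm, seed=1)
    model = train_model(tr, "NB-L", seed=1)
    acc = compute_metrics(evaluate_model(model, te)).accuracy_pct
    assert abs(acc - bayes_pct) < 5.0


def test_single_class_training_set_rejected():
    fm = _matrix(np.zeros((10, 2)), [True] * 10)
    with pytest.raises(ValueError):
        train_model(fm, "SVM-1")


def test_nn_sweep_includes_neighbour_refinement():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(-1, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
    fm = _matrix(X, [False] * 30 + [True] * 30)
    reports = evaluate_combination(fm, seed=2)
    nn_nodes = sorted(int(r.model_spec.split("-")[1]) for r in reports if r.model_spec.startswith("NN"))
    base = [5, 10, 15, 20, 25]
    assert set(base) <= set(nn_nodes)
    extras = [n for n in nn_nodes if n not in base]
    assert 0 <= len(extras) <= 4
    if extras:  # refinement fills a contiguous gap next to a base node
        assert max(extras) - min(extras) == len(extras) - 1


# --------------------------------------------------------------------------
# Confusion-matrix reconstruction and metrics
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rates,expected",
    [((6, 19, 50.0, 94.7), (3, 1, 3, 18)),
     ((6, 19, 100.0, 73.7), (6, 5, 0, 14)),
     ((6, 19, 66.7, 89.5), (4, 2, 2, 17)),
     ((6, 19, 0.0, 100.0), (0, 0, 6, 19))],
)
def test_confusion_from_rates_reconstruction(rates, expected):
    cm = confusion_from_rates(*rates)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected


def test_confusion_from_rates_rejects_inconsistent_rates():
    with pytest.raises(ValueError):
        confusion_from_rates(6, 19, 40.0, 94.7)  # 40% of 6 = 2.4 fallers


@pytest.mark.parametrize(
    "counts,f1,mcc,extras",
    [((3, 1, 3, 18), 0.600, 0.521, {"accuracy_pct": 84.0, "ppv_pct": 75.0}),
     ((6, 5, 0, 14), 0.706, 0.634, {"npv_pct": 100.0}),
     ((4, 2, 2, 17), 0.667, 0.561, {"accuracy_pct": 84.0})],
)
def test_metric_arithmetic_on_reconstructed_matrices(counts, f1, mcc, extras):
    m = compute_metrics(ConfusionMatrix(*counts))
    assert round(m.f1, 3) == f1
    assert round(m.mcc, 3) == mcc
    for key, val in extras.items():
        assert getattr(m, key) == pytest.approx(val, abs=0.05)


def test_constant_negative_classifier_zero_denominator_convention():
    m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=24, tn=76))
    assert m.accuracy_pct == 76.0
    assert m.sensitivity_pct == 0.0 and m.specificity_pct == 100.0
    assert m.ppv_pct == 0.0 and m.npv_pct == 76.0
    assert m.f1 == 0.0 and m.mcc == 0.0


def test_perfect_classifier_scores_unity():
    m = compute_metrics(ConfusionMatrix(tp=6, fp=0, fn=0, tn=19))
    assert m.f1 == 1.0 and m.mcc == 1.0 and m.accuracy_pct == 100.0


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        compute_metrics(ConfusionMatrix(0, 0, 0, 0))


cm_strategy = st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0)


@given(cm_strategy)
def test_mcc_and_f1_bounds(counts):
    m = compute_metrics(ConfusionMatrix(*counts))
    assert -1.0 <= m.mcc <= 1.0
    assert 0.0 <= m.f1 <= 1.0


@given(cm_strategy)
def test_mcc_symmetric_under_class_swap(counts):
    tp, fp, fn, tn = counts
    a = compute_metrics(ConfusionMatrix(tp, fp, fn, tn)).mcc
    b = compute_metrics(ConfusionMatrix(tn, fn, fp, tp)).mcc  # swap labels+preds
    assert a == pytest.approx(b, abs=1e-12)


# --------------------------------------------------------------------------
# Rank-sum comparison
# --------------------------------------------------------------------------

def _report(name, values):
    return ModelReport("X", "ST", name, MetricSet(*values))


def _brute_force_rank_sum(table):
    """Independent oracle: per column, rank with mean-shared ties, sum."""
    table = np.asarray(table, dtype=float)
    sums = np.zeros(len(table))
    for j in range(table.shape[1]):
        col = table[:, j]
        for i, v in enumerate(col):
            better = np.sum(col > v)
            equal = np.sum(col == v)
            # ranks occupied by the tie group: better+1 .. better+equal
            sums[i] += better + (equal + 1) / 2.0
    return sums


def test_identical_reports_share_equal_summed_ranks():
    reports = [_report(f"M{i}", (80.0, 50.0, 90.0, 60.0, 85.0, 0.5, 0.4)) for i in range(4)]
    ranked = rank_models(reports)
    assert len({r.summed_rank for r in ranked}) == 1


def test_dominating_report_gets_summed_rank_seven():
    good = _report("good", (90.0, 80.0, 95.0, 85.0, 92.0, 0.8, 0.7))
    bad = _report("bad", (70.0, 40.0, 80.0, 50.0, 75.0, 0.4, 0.2))
    ranked = rank_models([bad, good])
    assert ranked[0].model_spec == "good"
    assert ranked[0].summed_rank == 7.0
    assert ranked[1].summed_rank == 14.0


@given(st.integers(0, 10_000))
def test_rank_models_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    table = np.round(rng.uniform(0, 100, size=(10, 7)), 1)
    reports = [_report(f"M{i}", tuple(row)) for i, row in enumerate(table)]
    ranked = rank_models(reports)
    expected = _brute_force_rank_sum(table)
    got = {r.model_spec: r.summed_rank for r in ranked}
    for i in range(10):
        assert got[f"M{i}"] == pytest.approx(expected[i])
    # output sorted ascending by summed rank
    assert all(a.summed_rank <= b.summed_rank for a, b in zip(ranked, ranked[1:]))


def test_ranking_invariant_to_input_order():
    rng = np.random.default_rng(9)
    table = rng.uniform(0, 100, size=(6, 7))
    reports = [_report(f"M{i}", tuple(row)) for i, row in enumerate(table)]
    a = [r.model_spec for r in rank_models(list(reports))]
    b = [r.model_spec for r in rank_models(list(reports[::-1]))]
    assert a == b


def test_report_with_missing_metric_excluded_with_warning():
    ok = [_report(f"M{i}", tuple(np.random.default_rng(i).uniform(0, 100, 7))) for i in range(3)]
    broken = _report("broken", (80.0, 50.0, 90.0, 60.0, 85.0, float("nan"), 0.4))
    with pytest.warns(UserWarning, match="missing metric"):
        ranked = rank_models(ok + [broken])
    assert all(r.model_spec != "broken" for r in ranked)


def test_summed_rank_equals_sum_of_per_metric_ranks():
    rng = np.random.default_rng(11)
    reports = [_report(f"M{i}", tuple(rng.uniform(0, 100, 7))) for i in range(5)]
    for r in rank_models(reports):
        assert r.summed_rank == pytest.approx(sum(r.per_metric_ranks[m] for m in METRIC_NAMES))
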