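"""Fall-risk classification: sensor combinations, model sweeps, metrics
and rank-sum model comparison.

Thirty-one sensor combinations (pressure insole I and/or accelerometers
H, P, LS, RS) plus the clinical-assessment set (CA) are each turned into
a participant x feature matrix. Three model families are swept per
matrix: a single-hidden-layer perceptron (node counts 5..25 plus a
neighbour refinement around the best), naive Bayes with pooled-variance
(linear) or per-class-variance (quadratic) Gaussians, and polynomial-
kernel SVMs of degree 1..7. Each trained model is scored on a stratified
75/25 hold-out with seven metrics (accuracy, sensitivity, specificity,
PPV, NPV, F1, MCC); models are compared by ranking every metric across
models (1 = best, ties share the mean rank) and summing the seven ranks
— lowest summed rank wins.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.impute import SimpleImputer
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    CLINICAL_FEATURE_NAMES,
    INSOLE_FEATURE_NAMES,
    site_columns,
)
from .types import ConfusionMatrix

_SITE_CODE = {"H": "head", "P": "pelvis", "LS": "left_shank", "RS": "right_shank"}
_ACCEL_CODES = ("H", "P", "LS", "RS")


def _sensor_combinations() -> list[str]:
    accel_subsets = []
    for r in range(1, 5):
        for combo in itertools.combinations(_ACCEL_CODES, r):
            accel_subsets.append("-".join(combo))
    # insole alone, accelerometer subsets, then insole + each subset
    return ["I"] + accel_subsets + [f"I-{s}" for s in accel_subsets]


#: The 31 sensor combinations, in canonical (size-then-position) order.
SENSOR_COMBINATIONS = _sensor_combinations()

#: Clinical-assessment feature set code.
CLINICAL_CODE = "CA"


def combination_columns(combination: str) -> list[str]:
    """Feature columns for a sensor-combination code (or ``CA``)."""
    if combination == CLINICAL_CODE:
        return list(CLINICAL_FEATURE_NAMES)
    cols: list[str] = []
    for part in combination.split("-"):
        if part == "I":
            cols.extend(INSOLE_FEATURE_NAMES)
        elif part in _SITE_CODE:
            cols.extend(site_columns(_SITE_CODE[part]))
        else:
            raise ValueError(f"unknown sensor code {part!r} in {combination!r}")
    return cols


def _combination_blocks(combination: str) -> list[list[str]]:
    if combination == CLINICAL_CODE:
        return [list(CLINICAL_FEATURE_NAMES)]
    out = []
    for part in combination.split("-"):
        if part == "I":
            out.append(list(INSOLE_FEATURE_NAMES))
        else:
            out.append(site_columns(_SITE_CODE[part]))
    return out


@dataclass
class FeatureMatrix:
    """Participant x feature matrix for one sensor combination."""

    X: pd.DataFrame
    y: pd.Series
    combination: str
    condition: str

    @property
    def n_rows(self) -> int:
        return len(self.X)


def build_feature_matrix(
    features: pd.DataFrame,
    labels: pd.Series,
    combination: str,
    condition: str,
) -> FeatureMatrix:
    """Assemble the matrix for one combination and walking condition.

    ``features`` is the cohort table indexed by (subject_id, condition).
    Participants for whom any required sensor block is entirely missing
    (sensor absent for the trial) are excluded with a warning; scattered
    missing values within a present sensor are retained and imputed at
    training time.
    """
    cols = combination_columns(combination)
    if combination == CLINICAL_CODE:
        sub = features.xs(condition, level="condition")[cols]
    else:
        sub = features.xs(condition, level="condition")[cols]
    keep = pd.Series(True, index=sub.index)
    for block in _combination_blocks(combination):
        block_missing = sub[block].isna().all(axis=1)
        keep &= ~block_missing
    dropped = sub.index[~keep].tolist()
    if dropped:
        warnings.warn(
            f"{combination}/{condition}: dropped {len(dropped)} participants "
            f"missing a required sensor: {dropped}",
            stacklevel=2,
        )
    sub = sub[keep]
    y = labels.reindex(sub.index).astype(bool)
    return FeatureMatrix(X=sub, y=y, combination=combination, condition=condition)


def split_train_test(
    matrix: FeatureMatrix, train_fraction: float = 0.75, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified participant split, deterministic given ``seed``.

    Per-class training counts are floor(train_fraction * n_class), so a
    24-faller / 76-non-faller cohort yields 18+57 training and 6+19 test
    participants.
    """
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for label in (True, False):
        members = matrix.y.index[matrix.y == label].to_numpy()
        if len(members) < 2:
            raise ValueError(f"class {label} has fewer than 2 members; cannot stratify")
        n_train = math.floor(train_fraction * len(members))
        order = rng.permutation(len(members))
        train_idx.extend(members[order[:n_train]])
        test_idx.extend(members[order[n_train:]])
    tr = FeatureMatrix(
        matrix.X.loc[train_idx], matrix.y.loc[train_idx], matrix.combination, matrix.condition
    )
    te = FeatureMatrix(
        matrix.X.loc[test_idx], matrix.y.loc[test_idx], matrix.combination, matrix.condition
    )
    return tr, te


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------

class PooledGaussianNB(BaseEstimator, ClassifierMixin):
    """Gaussian naive Bayes with a pooled (class-shared) diagonal covariance.

    The "linear" counterpart of per-class-covariance Gaussian NB: with a
    shared covariance the log-odds are linear in the features.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        self.theta_ = np.vstack([X[y_idx == k].mean(axis=0) for k in range(len(self.classes_))])
        within = np.zeros(p)
        for k in range(len(self.classes_)):
            Xk = X[y_idx == k]
            within += ((Xk - self.theta_[k]) ** 2).sum(axis=0)
        self.var_ = within / n + 1e-9 * max(float(X.var()), 1.0)
        self.class_prior_ = np.bincount(y_idx) / n
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            log_det = np.sum(np.log(2.0 * np.pi * self.var_))
            maha = ((X - self.theta_[k]) ** 2 / self.var_).sum(axis=1)
            jll[:, k] = np.log(self.class_prior_[k]) - 0.5 * (log_det + maha)
        return jll

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def parse_model_spec(spec: str) -> tuple[str, int | str]:
    """Parse labels like ``NN-9``, ``NB-L``, ``SVM-2``."""
    family, _, param = spec.partition("-")
    family = family.upper()
    if family == "NN":
        return "NN", int(param)
    if family == "NB":
        if param.upper() not in ("L", "Q"):
            raise ValueError(f"NB variant must be L or Q, got {spec!r}")
        return "NB", param.upper()
    if family == "SVM":
        return "SVM", int(param)
    raise ValueError(f"unknown model family in {spec!r}")


def make_model(spec: str, seed: int = 0, standardize: bool = True) -> Pipeline:
    """Build the imputation/standardisation/estimator pipeline for a spec."""
    family, param = parse_model_spec(spec)
    if family == "NN":
        est = MLPClassifier(
            hidden_layer_sizes=(int(param),),
            max_iter=600,
            random_state=seed,
        )
    elif family == "NB":
        est = PooledGaussianNB() if param == "L" else GaussianNB()
    else:
        est = SVC(kernel="poly", degree=int(param), gamma="scale", coef0=1.0, C=1.0)
    steps = [("impute", SimpleImputer(strategy="mean"))]
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", est))
    return Pipeline(steps)


def train_model(train: FeatureMatrix, spec: str, seed: int = 0, standardize: bool = True) -> Pipeline:
    """Fit one model spec on a training matrix (features z-scored on
    training statistics)."""
    if train.y.nunique() < 2:
        raise ValueError("training set contains a single class")
    model = make_model(spec, seed=seed, standardize=standardize)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny data
        model.fit(train.X.to_numpy(), train.y.to_numpy())
    return model


def evaluate_model(model: Pipeline, test: FeatureMatrix) -> ConfusionMatrix:
    pred = np.asarray(model.predict(test.X.to_numpy()), dtype=bool)
    truth = test.y.to_numpy()
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

METRIC_NAMES = (
    "accuracy_pct",
    "sensitivity_pct",
    "specificity_pct",
    "ppv_pct",
    "npv_pct",
    "f1",
    "mcc",
)


@dataclass
class MetricSet:
    """The seven evaluation metrics derived from one confusion matrix."""

    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _safe_div(num: float, den: float) -> float:
    """Zero-denominator convention: the metric is 0 (as for the constant
    all-non-faller baseline, which has F1 = 0 and MCC = 0)."""
    return num / den if den != 0 else 0.0


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, PPV, NPV (percent), F1 and MCC.

    F1 = 2*TP / (2*TP + FP + FN) — the harmonic mean of precision and
    sensitivity; MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return MetricSet(
        accuracy_pct=100.0 * (tp + tn) / cm.total,
        sensitivity_pct=100.0 * _safe_div(tp, tp + fn),
        specificity_pct=100.0 * _safe_div(tn, tn + fp),
        ppv_pct=100.0 * _safe_div(tp, tp + fp),
        npv_pct=100.0 * _safe_div(tn, tn + fn),
        f1=_safe_div(2.0 * tp, 2.0 * tp + fp + fn),
        mcc=_safe_div(tp * tn - fp * fn, mcc_den),
    )


def confusion_from_rates(
    n_pos: int, n_neg: int, sensitivity_pct: float, specificity_pct: float, tol: float = 0.25
) -> ConfusionMatrix:
    """Reconstruct the confusion matrix implied by printed sensitivity and
    specificity on a known test split.

    The implied TP and TN counts must land within ``tol`` of an integer
    (printed percentages are rounded, so the residual is tiny for real
    rows); otherwise the rates are inconsistent with the split.
    """
    implied_tp = sensitivity_pct * n_pos / 100.0
    implied_tn = specificity_pct * n_neg / 100.0
    tp, tn = round(implied_tp), round(implied_tn)
    if abs(implied_tp - tp) > tol or abs(implied_tn - tn) > tol:
        raise ValueError(
            f"rates imply non-integer counts (tp={implied_tp:.3f}, tn={implied_tn:.3f})"
        )
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


# --------------------------------------------------------------------------
# Model sweep and ranking
# --------------------------------------------------------------------------

@dataclass
class ModelReport:
    """One trained model's metrics, per-metric ranks and summed rank."""

    sensor_combination: str
    condition: str
    model_spec: str
    metrics: MetricSet
    per_metric_ranks: dict[str, float] = field(default_factory=dict)
    summed_rank: float = float("nan")

    @property
    def name(self) -> str:
        return f"{self.sensor_combination} {self.model_spec} ({self.condition})"


def rank_models(reports: list[ModelReport]) -> list[ModelReport]:
    """Rank models per metric (1 = best, ties share the mean rank) and
    order by summed rank (ascending), breaking ties by accuracy, MCC,
    then name.

    Reports with a missing metric are excluded with a warning. The
    result is invariant to the input order up to this tie-breaking.
    """
    usable = []
    for r in reports:
        vals = r.metrics.as_dict()
        if any(not np.isfinite(v) for v in vals.values()):
            warnings.warn(f"excluding {r.name}: missing metric", stacklevel=2)
            continue
        usable.append(r)
    if len(usable) < 2:
        raise ValueError("need at least 2 complete reports to rank")
    for metric in METRIC_NAMES:
        values = np.array([getattr(r.metrics, metric) for r in usable])
        ranks = rankdata(-values, method="average")  # higher is better for all seven
        for r, rank in zip(usable, ranks):
            r.per_metric_ranks[metric] = float(rank)
    for r in usable:
        r.summed_rank = float(sum(r.per_metric_ranks.values()))
    return sorted(
        usable,
        key=lambda r: (r.summed_rank, -r.metrics.accuracy_pct, -r.metrics.mcc, r.name),
    )


NN_BASE_NODES = (5, 10, 15, 20, 25)
NB_VARIANTS = ("NB-L", "NB-Q")
SVM_DEGREES = tuple(range(1, 8))


def _spec_seed(base_seed: int, combination: str, condition: str, spec: str) -> int:
    """Stable per-(combination, spec) seed below 2**31."""
    key = f"{base_seed}|{combination}|{condition}|{spec}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _score_key(report: ModelReport) -> tuple[float, float]:
    return (report.metrics.accuracy_pct, report.metrics.mcc)


def evaluate_combination(
    matrix: FeatureMatrix,
    seed: int = 0,
    standardize: bool = True,
    refine_nn: bool = True,
) -> list[ModelReport]:
    """Train and score the full model sweep for one feature matrix.

    The split is stratified 75/25 (fixed by ``seed``). The perceptron
    sweep evaluates 5..25 nodes in steps of 5; if the best node count
    has a better-performing neighbour, the intermediate node counts are
    also evaluated (e.g. best at 15 with 20 beating 10 adds 16..19).
    """
    train, test = split_train_test(matrix, seed=seed)

    def run(spec: str) -> ModelReport:
        s = _spec_seed(seed, matrix.combination, matrix.condition, spec)
        model = train_model(train, spec, seed=s, standardize=standardize)
        cm = evaluate_model(model, test)
        return ModelReport(
            sensor_combination=matrix.combination,
            condition=matrix.condition,
            model_spec=spec,
            metrics=compute_metrics(cm),
        )

    reports = [run(v) for v in NB_VARIANTS]
    reports += [run(f"SVM-{d}") for d in SVM_DEGREES]

    nn_reports = {n: run(f"NN-{n}") for n in NN_BASE_NODES}
    reports += list(nn_reports.values())
    if refine_nn:
        best = max(NN_BASE_NODES, key=lambda n: _score_key(nn_reports[n]))
        neighbours = [n for n in (best - 5, best + 5) if n in nn_reports]
        if neighbours:
            toward = max(neighbours, key=lambda n: _score_key(nn_reports[n]))
            lo, hi = sorted((best, toward))
            reports += [run(f"NN-{n}") for n in range(lo + 1, hi)]
    return reports


def run_ranking(
    features: pd.DataFrame,
    labels: pd.Series,
    condition: str,
    combinations: list[str] | None = None,
    seed: int = 0,
    include_clinical: bool = True,
    standardize: bool = True,
    refine_nn: bool = True,
) -> list[ModelReport]:
    """Full analysis for one walking condition: every sensor combination
    (plus the clinical set), the whole model sweep, ranked by summed rank."""
    combos = list(combinations) if combinations else list(SENSOR_COMBINATIONS)
    if include_clinical and CLINICAL_CODE not in combos:
        combos.append(CLINICAL_CODE)
    reports: list[ModelReport] = []
    for combo in combos:
        matrix = build_feature_matrix(features, labels, combo, condition)
        reports.extend(
            evaluate_combination(matrix, seed=seed, standardize=standardize, refine_nn=refine_nn)
        )
    return rank_models(reports)


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Tabulate ranked reports (columns mirror the result tables)."""
    rows = []
    for r in reports:
        m = r.metrics
        rows.append(
            {
                "sensors": r.sensor_combination,
                "condition": r.condition,
                "model_type": r.model_spec,
                "accuracy": m.accuracy_pct,
                "sensitivity": m.sensitivity_pct,
                "specificity": m.specificity_pct,
                "ppv": m.ppv_pct,
                "npv": m.npv_pct,
                "f1": m.f1,
                "mcc": m.mcc,
                "summed_rank": r.summed_rank,
            }
        )
    return pd.DataFrame(rows)
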