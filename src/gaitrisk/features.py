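"""Trial- and cohort-level feature extraction.

Produces one tidy table with a row per (subject, condition) and columns
for the 30 insole features, 29 accelerometer features per site (prefixed
``head__``, ``pelvis__``, ``left_shank__``, ``right_shank__``) and the 7
clinical features. Sensors absent from a trial leave their whole column
block NaN; the classifier stage drops such rows for combinations that
require the sensor.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .accel import ACCEL_FEATURE_NAMES, extract_accel_features
from .insole import INSOLE_FEATURE_NAMES, extract_insole_features
from .io import read_clinical, read_labels, read_masses, read_trial
from .synthetic import CohortSubject
from .types import ACCEL_SITES, CONDITIONS, ClinicalFeatures, SensorTrial

CLINICAL_FEATURE_NAMES = list(ClinicalFeatures.FIELDS)


def site_columns(site: str) -> list[str]:
    return [f"{site}__{name}" for name in ACCEL_FEATURE_NAMES]


#: All sensor-derived feature columns, canonical order (30 + 4*29 = 146).
SENSOR_FEATURE_COLUMNS = list(INSOLE_FEATURE_NAMES) + [
    col for site in ACCEL_SITES for col in site_columns(site)
]

ALL_FEATURE_COLUMNS = SENSOR_FEATURE_COLUMNS + CLINICAL_FEATURE_NAMES


def extract_trial_features(trial: SensorTrial, mass_kg: float | None = None) -> dict[str, float]:
    """All sensor features for one trial; absent sensors yield NaN blocks."""
    out: dict[str, float] = {}
    if trial.insole_left is not None or trial.insole_right is not None:
        out.update(extract_insole_features(trial, mass_kg=mass_kg))
    else:
        out.update({name: np.nan for name in INSOLE_FEATURE_NAMES})
    for site in ACCEL_SITES:
        if site in trial.accel:
            feats = extract_accel_features(trial.accel[site])
            out.update({f"{site}__{k}": v for k, v in feats.items()})
        else:
            out.update({col: np.nan for col in site_columns(site)})
    return out


def extract_cohort_features(cohort: list[CohortSubject]) -> pd.DataFrame:
    """Feature table for a generated cohort.

    Indexed by (subject_id, condition); sensor columns plus the 7
    clinical columns (repeated across conditions).
    """
    rows = []
    index = []
    for subject in cohort:
        clinical = subject.profile.clinical.as_dict()
        for condition, trial in sorted(subject.trials.items()):
            feats = extract_trial_features(trial, mass_kg=subject.profile.mass_kg)
            feats.update(clinical)
            rows.append(feats)
            index.append((subject.subject_id, condition))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["subject_id", "condition"]))
    return df[ALL_FEATURE_COLUMNS]


def extract_features_from_dir(
    directory: str | Path, conditions: tuple[str, ...] = CONDITIONS
) -> pd.DataFrame:
    """Feature table for an on-disk cohort directory (CSV trial files)."""
    directory = Path(directory)
    labels = read_labels(directory)
    clinical = read_clinical(directory)
    masses = read_masses(directory)
    rows = []
    index = []
    for subject_id in labels.index:
        for condition in conditions:
            trial = read_trial(directory, subject_id, condition, mass_kg=masses.get(subject_id))
            feats = extract_trial_features(trial, mass_kg=masses.get(subject_id))
            feats.update(clinical.loc[subject_id].to_dict())
            rows.append(feats)
            index.append((subject_id, condition))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["subject_id", "condition"]))
    return df[ALL_FEATURE_COLUMNS]
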