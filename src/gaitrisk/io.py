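"""Trial file formats, sensel-grid conversion and the filtering primitive.

Cohort directory layout::

    cohort.yaml                          generation config + subject profiles
    clinical.csv                         one row per subject, 7 clinical columns
    labels.csv                           subject_id, is_faller
    <id>_<cond>_insole_<side>.csv        frame,total_force_n,cop_ap_mm,cop_ml_mm,valid
    <id>_<cond>_accel_<site>.csv         frame,vertical,ap,ml

Missing accelerometer files are interpreted as absent sensors (emulating
power failure), not as errors.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

from .errors import IntegrityError, ParseError
from .synthetic import CohortSubject
from .types import (
    ACCEL_FS_HZ,
    ACCEL_SITES,
    INSOLE_FS_HZ,
    AccelStream,
    ClinicalFeatures,
    InsoleStream,
    SensorTrial,
)

INSOLE_COLUMNS = ["frame", "total_force_n", "cop_ap_mm", "cop_ml_mm", "valid"]
ACCEL_COLUMNS = ["frame", "vertical", "ap", "ml"]


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def lowpass_filter(
    series: np.ndarray, fs_hz: float, cutoff_hz: float = 12.5, order: int = 5
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    A 5th-order, 12.5 Hz low-pass Butterworth by default, applied
    forward-backward (``filtfilt``) so temporal events are not
    phase-shifted. Output length equals input length.
    """
    if cutoff_hz >= fs_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0 or fs_hz <= 0:
        raise ValueError("sampling rate and cutoff must be positive")
    b, a = sp_signal.butter(order, cutoff_hz, btype="low", fs=fs_hz)
    return sp_signal.filtfilt(b, a, np.asarray(series, dtype=float))


# --------------------------------------------------------------------------
# Sensel grid -> total force + CoP
# --------------------------------------------------------------------------

@dataclass
class SenselGridFrame:
    """One frame of a pressure-sensel grid (kPa) with uniform pitch (mm)."""

    pressures: np.ndarray
    sensel_pitch_mm: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pressures = np.atleast_2d(np.asarray(self.pressures, dtype=float))
        if self.pressures.size == 0:
            raise ValueError("grid must contain at least one sensel")
        if self.sensel_pitch_mm <= 0:
            raise ValueError("sensel pitch must be positive")


def grid_to_cop(
    frames: list[SenselGridFrame],
    sensel_area_mm2: float,
    contact_threshold_n: float = 0.0,
    fs_hz: float = INSOLE_FS_HZ,
) -> InsoleStream:
    """Reduce a sensel-grid pressure stream to total force + CoP.

    Total force is the sum of sensel pressures times sensel area
    (kPa x mm^2 = mN); the CoP is the pressure-weighted centroid of the
    sensel coordinates, with row index increasing anteriorly (AP) and
    column index increasing to the right (ML). Frames with total force at
    or below ``contact_threshold_n`` are flagged invalid (CoP undefined),
    never raised on.
    """
    if sensel_area_mm2 <= 0:
        raise ValueError("sensel area must be positive")
    n = len(frames)
    force = np.zeros(n)
    cop_ap = np.zeros(n)
    cop_ml = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i, fr in enumerate(frames):
        p = fr.pressures
        # kPa * mm^2 = 1e3 Pa * 1e-6 m^2 = 1e-3 N per unit
        total = float(p.sum()) * sensel_area_mm2 * 1e-3
        force[i] = total
        if total > contact_threshold_n and p.sum() > 0:
            rows, cols = np.indices(p.shape)
            w = p / p.sum()
            cop_ap[i] = float((rows * w).sum()) * fr.sensel_pitch_mm
            cop_ml[i] = float((cols * w).sum()) * fr.sensel_pitch_mm
            valid[i] = True
    return InsoleStream(force, cop_ap, cop_ml, valid, fs_hz=fs_hz)


# --------------------------------------------------------------------------
# CSV writing
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _insole_path(directory: Path, subject_id: str, condition: str, side: str) -> Path:
    return Path(directory) / f"{subject_id}_{condition}_insole_{side}.csv"


def _accel_path(directory: Path, subject_id: str, condition: str, site: str) -> Path:
    return Path(directory) / f"{subject_id}_{condition}_accel_{site}.csv"


def write_trial(directory: str | Path, trial: SensorTrial) -> None:
    """Write one trial's insole and accelerometer CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for side, stream in (("left", trial.insole_left), ("right", trial.insole_right)):
        if stream is None:
            continue
        path = _insole_path(directory, trial.subject_id, trial.condition, side)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(INSOLE_COLUMNS)
            for i in range(len(stream)):
                w.writerow(
                    [
                        i,
                        _fmt(stream.total_force_n[i]),
                        _fmt(stream.cop_ap_mm[i]),
                        _fmt(stream.cop_ml_mm[i]),
                        int(stream.valid[i]),
                    ]
                )
    for site, stream in trial.accel.items():
        path = _accel_path(directory, trial.subject_id, trial.condition, site)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(ACCEL_COLUMNS)
            for i in range(len(stream)):
                w.writerow(
                    [i, _fmt(stream.vertical[i]), _fmt(stream.ap[i]), _fmt(stream.ml[i])]
                )


def write_cohort(
    directory: str | Path, cohort: list[CohortSubject], config: dict | None = None
) -> None:
    """Write a full cohort directory: trials, cohort.yaml, clinical and labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profiles = []
    clinical_rows = []
    label_rows = []
    for subject in cohort:
        prof = dataclasses.asdict(subject.profile)
        prof["clinical"] = subject.profile.clinical.as_dict()
        prof["conditions"] = sorted(subject.trials)
        profiles.append(prof)
        clinical_rows.append(
            {"subject_id": subject.subject_id, **subject.profile.clinical.as_dict()}
        )
        label_rows.append(
            {"subject_id": subject.subject_id, "is_faller": int(subject.is_faller)}
        )
        for trial in subject.trials.values():
            write_trial(directory, trial)
    doc = {"config": config or {}, "subjects": profiles}
    with open(directory / "cohort.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    pd.DataFrame(clinical_rows).to_csv(directory / "clinical.csv", index=False)
    pd.DataFrame(label_rows).to_csv(directory / "labels.csv", index=False)


# --------------------------------------------------------------------------
# CSV reading
# --------------------------------------------------------------------------

def _read_numeric_csv(path: Path, columns: list[str]) -> dict[str, np.ndarray]:
    """Read a trial CSV with strict shape checking and line-numbered errors."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [c.strip() for c in header] != columns:
            raise ParseError(f"{path}: line 1: expected header {','.join(columns)}")
        data: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            try:
                data.append([float(v) for v in row])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    arr = np.asarray(data, dtype=float).reshape(-1, len(columns))
    return {name: arr[:, j] for j, name in enumerate(columns)}


def read_trial(
    directory: str | Path,
    subject_id: str,
    condition: str,
    mass_kg: float | None = None,
) -> SensorTrial:
    """Load one trial from a cohort directory.

    Absent accelerometer (or insole) files yield absent entries rather
    than errors; inconsistent stream lengths raise
    :class:`~gaitrisk.errors.IntegrityError`.
    """
    directory = Path(directory)
    insoles: dict[str, InsoleStream | None] = {}
    for side in ("left", "right"):
        path = _insole_path(directory, subject_id, condition, side)
        if not path.exists():
            insoles[side] = None
            continue
        cols = _read_numeric_csv(path, INSOLE_COLUMNS)
        insoles[side] = InsoleStream(
            total_force_n=cols["total_force_n"],
            cop_ap_mm=cols["cop_ap_mm"],
            cop_ml_mm=cols["cop_ml_mm"],
            valid=cols["valid"].astype(bool),
            fs_hz=INSOLE_FS_HZ,
        )
    lengths = {side: len(s) for side, s in insoles.items() if s is not None}
    if len(set(lengths.values())) > 1:
        raise IntegrityError(
            f"{subject_id} {condition}: left/right insole lengths differ: {lengths}"
        )

    accel: dict[str, AccelStream] = {}
    acc_lengths: set[int] = set()
    for site in ACCEL_SITES:
        path = _accel_path(directory, subject_id, condition, site)
        if not path.exists():
            continue
        cols = _read_numeric_csv(path, ACCEL_COLUMNS)
        accel[site] = AccelStream(cols["vertical"], cols["ap"], cols["ml"], fs_hz=ACCEL_FS_HZ)
        acc_lengths.add(len(accel[site]))
    if len(acc_lengths) > 1:
        raise IntegrityError(
            f"{subject_id} {condition}: accelerometer stream lengths differ"
        )

    return SensorTrial(
        subject_id=subject_id,
        condition=condition,
        insole_left=insoles["left"],
        insole_right=insoles["right"],
        accel=accel,
        mass_kg=mass_kg,
    )


def read_labels(directory: str | Path) -> pd.Series:
    """Faller labels indexed by subject_id (boolean)."""
    df = pd.read_csv(Path(directory) / "labels.csv")
    return df.set_index("subject_id")["is_faller"].astype(bool)


def read_clinical(directory: str | Path) -> pd.DataFrame:
    """Clinical feature table indexed by subject_id (7 columns)."""
    df = pd.read_csv(Path(directory) / "clinical.csv")
    return df.set_index("subject_id")[list(ClinicalFeatures.FIELDS)]


def read_cohort_config(directory: str | Path) -> dict:
    with open(Path(directory) / "cohort.yaml") as fh:
        return yaml.safe_load(fh)


def read_masses(directory: str | Path) -> dict[str, float]:
    """Subject body masses recorded in cohort.yaml."""
    doc = read_cohort_config(directory)
    return {s["subject_id"]: float(s["mass_kg"]) for s in doc.get("subjects", [])}
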