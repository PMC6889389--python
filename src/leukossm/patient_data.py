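"""Patient time-series data model and CSV I/O.

A patient record is an irregular multivariate time series collected during
maintenance therapy: daily oral 6-MP doses, leukocyte counts and CRP
measurements from (bi)weekly visits, and a slowly varying body-surface-area
(BSA) series used to normalise doses.

CSV schema (one file per patient, RFC-4180, missing cells empty)::

    time,dose,leukocyte,crp,bsa
    0.0,25.0,5.4,1.2,1.05
    1.0,25.0,,,
    7.0,25.0,4.9,0.8,

``time`` is days from the start of maintenance therapy.  A row contributes a
dose event if ``dose`` is non-empty, an observation if ``leukocyte`` or
``crp`` is non-empty, and a BSA knot if ``bsa`` is non-empty.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CSV_COLUMNS = ["time", "dose", "leukocyte", "crp", "bsa"]


class ValidationError(ValueError):
    """A patient record violates a structural invariant."""


@dataclass
class PatientRecord:
    """One patient's longitudinal treatment data.

    Times are in days; doses in mg; leukocyte counts in 1e9 cells/L; CRP in
    mg/L; BSA in m^2.  Missing leukocyte/CRP measurements are NaN.
    """

    patient_id: str
    dose_times: np.ndarray
    doses: np.ndarray
    obs_times: np.ndarray
    leukocyte: np.ndarray
    crp: np.ndarray
    bsa_times: np.ndarray
    bsa: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dose_times", "doses", "obs_times", "leukocyte", "crp",
                     "bsa_times", "bsa"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        for name in ("dose_times", "obs_times", "bsa_times"):
            t = getattr(self, name)
            if t.size and np.any(np.diff(t) < 0):
                raise ValidationError(f"{name} must be non-decreasing")
        if self.doses.size != self.dose_times.size:
            raise ValidationError("doses and dose_times length mismatch")
        if self.leukocyte.size != self.obs_times.size or self.crp.size != self.obs_times.size:
            raise ValidationError("observation columns must match obs_times length")
        if self.bsa.size != self.bsa_times.size:
            raise ValidationError("bsa and bsa_times length mismatch")
        if np.any(self.doses < 0):
            raise ValidationError("doses must be non-negative")
        with np.errstate(invalid="ignore"):
            if np.any(self.leukocyte[~np.isnan(self.leukocyte)] <= 0):
                raise ValidationError("leukocyte counts must be positive where present")
            if np.any(self.crp[~np.isnan(self.crp)] < 0):
                raise ValidationError("CRP must be non-negative where present")
        if self.bsa.size == 0 or np.any(self.bsa <= 0):
            raise ValidationError("bsa must be present and positive")
        both_missing = np.isnan(self.leukocyte) & np.isnan(self.crp)
        if np.any(both_missing):
            raise ValidationError("every observation row needs leukocyte or CRP")
        if self.span <= 0:
            raise ValidationError("treatment span must be positive")

    @property
    def start_time(self) -> float:
        return min(x.min() for x in (self.dose_times, self.obs_times, self.bsa_times)
                   if x.size)

    @property
    def end_time(self) -> float:
        return max(x.max() for x in (self.dose_times, self.obs_times, self.bsa_times)
                   if x.size)

    @property
    def span(self) -> float:
        return self.end_time - self.start_time

    def leukocyte_mask(self) -> np.ndarray:
        return ~np.isnan(self.leukocyte)

    def truncate_observations(self, t_max: float) -> "PatientRecord":
        """Keep observations at times <= ``t_max``; doses and BSA are kept in
        full (the dose schedule is an input, not a prediction target)."""
        keep = self.obs_times <= t_max
        return replace(self, obs_times=self.obs_times[keep],
                       leukocyte=self.leukocyte[keep], crp=self.crp[keep])


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m^2 from the Mosteller formula
    sqrt(height_cm * weight_kg / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def bsa_at(record: PatientRecord, t) -> float | np.ndarray:
    """BSA at time ``t`` by piecewise-linear interpolation of the recorded
    series, clamped at the endpoints."""
    return np.interp(t, record.bsa_times, record.bsa)


def dose_input(record: PatientRecord, t: float, t_dur: float = 1.0) -> float:
    """BSA-normalised drug input d(t) in mg/m^2.

    Returns the last dose administered during the window (t - t_dur, t],
    divided by the interpolated BSA at ``t``; zero if no dose falls in the
    window.  ``t_dur`` is in days (default 1 day = 24 h).
    """
    if t_dur <= 0:
        raise ValueError("t_dur must be positive")
    idx = np.searchsorted(record.dose_times, t, side="right") - 1
    if idx < 0:
        return 0.0
    t_dose = record.dose_times[idx]
    if t_dose <= t - t_dur:
        return 0.0
    return float(record.doses[idx]) / float(bsa_at(record, t))


def make_dose_fn(record: PatientRecord, t_dur: float = 1.0):
    """Close over a record, returning the callable d: time -> mg/m^2.

    Equivalent to ``dose_input(record, t, t_dur)`` but implemented with
    scalar bisection because it sits in the innermost filtering loop.
    """
    from bisect import bisect_right

    dose_times = record.dose_times.tolist()
    doses = record.doses.tolist()
    bsa_t = record.bsa_times.tolist()
    bsa_v = record.bsa.tolist()
    n_bsa = len(bsa_t)

    def d(t: float) -> float:
        i = bisect_right(dose_times, t) - 1
        if i < 0 or dose_times[i] <= t - t_dur:
            return 0.0
        j = bisect_right(bsa_t, t) - 1
        if j < 0:
            b = bsa_v[0]
        elif j >= n_bsa - 1:
            b = bsa_v[-1]
        else:
            t0, t1 = bsa_t[j], bsa_t[j + 1]
            b = bsa_v[j] + (bsa_v[j + 1] - bsa_v[j]) * (t - t0) / (t1 - t0)
        return doses[i] / b

    return d


def read_patient_csv(path, patient_id: str | None = None) -> PatientRecord:
    """Read one patient CSV file into a validated :class:`PatientRecord`.

    Missing cells become NaN markers, never zeros.  Raises
    :class:`ValidationError` on invariant violations and ``ValueError`` on
    malformed files.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["time"].isna().any():
        row = int(df.index[df["time"].isna()][0])
        raise ValueError(f"{path}: empty 'time' cell at data row {row}")
    if patient_id is None:
        patient_id = str(getattr(path, "stem", None) or str(path).rsplit("/", 1)[-1]
                         .removesuffix(".csv"))
    t = df["time"].to_numpy(float)
    dose_rows = df["dose"].notna().to_numpy()
    obs_rows = (df["leukocyte"].notna() | df["crp"].notna()).to_numpy()
    bsa_rows = df["bsa"].notna().to_numpy()
    return PatientRecord(
        patient_id=patient_id,
        dose_times=t[dose_rows], doses=df["dose"].to_numpy(float)[dose_rows],
        obs_times=t[obs_rows],
        leukocyte=df["leukocyte"].to_numpy(float)[obs_rows],
        crp=df["crp"].to_numpy(float)[obs_rows],
        bsa_times=t[bsa_rows], bsa=df["bsa"].to_numpy(float)[bsa_rows],
    )


def write_patient_csv(record: PatientRecord, path) -> None:
    """Write a record in the patient CSV schema (round-trips with
    :func:`read_patient_csv` up to formatting)."""
    times = np.unique(np.concatenate([record.dose_times, record.obs_times,
                                      record.bsa_times]))
    df = pd.DataFrame({"time": times})
    for col in CSV_COLUMNS[1:]:
        df[col] = np.nan
    pos = {tt: i for i, tt in enumerate(times)}
    for tt, d in zip(record.dose_times, record.doses):
        df.loc[pos[tt], "dose"] = d
    for tt, l, c in zip(record.obs_times, record.leukocyte, record.crp):
        df.loc[pos[tt], "leukocyte"] = l
        df.loc[pos[tt], "crp"] = c
    for tt, b in zip(record.bsa_times, record.bsa):
        df.loc[pos[tt], "bsa"] = b
    df.to_csv(path, index=False)


def read_cohort(directory) -> list[PatientRecord]:
    """Read every ``*.csv`` file in a directory as one patient each."""
    from pathlib import Path

    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no patient CSV files in {directory}")
    return [read_patient_csv(p) for p in paths]


def bsa_series_from_growth(table: pd.DataFrame, start_age_days: float,
                           start_height_cm: float, start_weight_kg: float,
                           times: np.ndarray) -> np.ndarray:
    """Optional helper: BSA series from a user-supplied median growth table.

    ``table`` must have columns ``age_days``, ``height_cm``, ``weight_kg``
    (e.g. sex-averaged median curves).  The curves are shifted additively so
    that they pass through the patient's recorded start values, then
    interpolated at ``start_age_days + times`` and converted with the
    Mosteller formula.  No growth table is bundled with the package.
    """
    for col in ("age_days", "height_cm", "weight_kg"):
        if col not in table.columns:
            raise ValueError(f"growth table missing column {col!r}")
    ages = start_age_days + np.asarray(times, float)
    h0 = np.interp(start_age_days, table["age_days"], table["height_cm"])
    w0 = np.interp(start_age_days, table["age_days"], table["weight_kg"])
    h = np.interp(ages, table["age_days"], table["height_cm"]) + (start_height_cm - h0)
    w = np.interp(ages, table["age_days"], table["weight_kg"]) + (start_weight_kg - w0)
    return np.sqrt(h * w / 3600.0)
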