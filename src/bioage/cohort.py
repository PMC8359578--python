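"""Cohort and ECG-parameter table I/O, eligibility filtering, and clinical covariates.

The cohort is exchanged as delimited text with one row per patient.  The
demographic columns are fixed by :data:`REQUIRED_COLUMNS`; every remaining
column is interpreted as an ECG measurement and validated against the
packaged catalogue.  Eligibility mirrors a cardiology registry design:
structural heart disease, age outside 20-90 years, indeterminate QRS axis
(R axis > 180 degrees), paced beats, and atrial/ventricular tachyarrhythmia
are excluded; follow-up is truncated at three years so registration-year
imbalance cannot distort event rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import Catalogue, load_catalogue

logger = logging.getLogger(__name__)

#: Follow-up cap in days: 3 years of 365.25 days.
FOLLOWUP_CAP_DAYS = 3 * 365.25

REQUIRED_COLUMNS = ("patient_id", "sex", "ca_years", "followup_days", "status", "death_cause")
OPTIONAL_COLUMNS = ("scr_mg_dl", "height_m", "weight_kg")
FLAG_COLUMNS = (
    "structural_heart_disease",
    "pacing",
    "tachyarrhythmia",
    "indeterminate_axis",
)

#: Eligibility criteria in attribution order (first match wins).
EXCLUSION_ORDER = (
    "structural_heart_disease",
    "age_out_of_range",
    "indeterminate_axis",
    "pacing",
    "tachyarrhythmia",
)


@dataclass
class CohortTable:
    """Per-patient demographics, follow-up and outcome labels.

    ``frame`` is indexed by ``patient_id`` and carries the columns of
    :data:`REQUIRED_COLUMNS` (minus the id), the optional covariates and
    the binary exclusion-flag columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient_id values: {dupes}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ca_years(self) -> pd.Series:
        return self.frame["ca_years"]

    @property
    def sex(self) -> pd.Series:
        return self.frame["sex"]

    @property
    def is_dead(self) -> pd.Series:
        return self.frame["status"] == "all_cause_death"

    @property
    def is_cv_death(self) -> pd.Series:
        return self.frame["death_cause"] == "cardiovascular"

    def validate(self) -> None:
        f = self.frame
        bad_sex = set(f["sex"].unique()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        bad_status = set(f["status"].unique()) - {"alive", "all_cause_death"}
        if bad_status:
            raise ValueError(f"unknown status values: {sorted(bad_status)}")
        bad_cause = set(f["death_cause"].unique()) - {"cardiovascular", "non_cardiovascular", "none"}
        if bad_cause:
            raise ValueError(f"unknown death_cause values: {sorted(bad_cause)}")
        alive = f["status"] == "alive"
        if (alive & (f["death_cause"] != "none")).any() or (~alive & (f["death_cause"] == "none")).any():
            raise ValueError("death_cause must be 'none' iff status is 'alive'")
        if (f["followup_days"] < 0).any():
            raise ValueError("negative followup_days")


@dataclass
class ParameterMatrix:
    """Patients x ECG parameters, rows aligned with a :class:`CohortTable`."""

    frame: pd.DataFrame  # indexed by patient_id, numeric columns
    column_meta: pd.DataFrame = field(default=None)  # parameter/lead per column

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def drop_constant_columns(self) -> "ParameterMatrix":
        keep = self.frame.columns[self.frame.nunique() > 1]
        dropped = sorted(set(self.frame.columns) - set(keep))
        if dropped:
            logger.warning("dropping constant columns: %s", dropped)
        meta = None
        if self.column_meta is not None:
            meta = self.column_meta.loc[self.column_meta["column"].isin(keep)].reset_index(drop=True)
        return ParameterMatrix(self.frame[keep], meta)


@dataclass(frozen=True)
class StandardizationModel:
    """Per-column mean and SD (ddof=1) learned on the modelling cohort."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"non-positive standard deviation for columns: {bad}")

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.mean.index) - set(frame.columns)
        if missing:
            raise KeyError(f"missing columns: {sorted(missing)}")
        cols = list(self.mean.index)
        return (frame[cols] - self.mean) / self.sd


# ---------------------------------------------------------------------------
# I/O


def read_parameter_table(
    path, catalogue: Catalogue | None = None, sep: str | None = None
) -> tuple[CohortTable, ParameterMatrix]:
    """Read a delimited per-patient table into cohort and parameter tables.

    Unknown ECG columns (not in the catalogue's used set) are dropped with a
    warning.  Missing values are allowed only in the optional covariates.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"required column missing: {col!r}")
    if raw["patient_id"].duplicated().any():
        dupes = raw.loc[raw["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dupes}")
    raw = raw.set_index("patient_id")

    demo_cols = [c for c in raw.columns if c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS + FLAG_COLUMNS]
    ecg_cols = [c for c in raw.columns if c not in demo_cols]
    known = set(catalogue.used_columns)
    unknown = [c for c in ecg_cols if c not in known]
    if unknown:
        warnings.warn(f"dropping {len(unknown)} columns not in the catalogue: {unknown}")
        logger.warning("unknown ECG columns dropped: %s", unknown)
        ecg_cols = [c for c in ecg_cols if c in known]

    cohort_frame = raw[demo_cols].copy()
    for flag in FLAG_COLUMNS:
        if flag in cohort_frame.columns:
            cohort_frame[flag] = cohort_frame[flag].fillna(0).astype(int).astype(bool)
        else:
            cohort_frame[flag] = False
    cohort_frame["death_cause"] = cohort_frame["death_cause"].fillna("none")
    for col in ("ca_years", "followup_days"):
        cohort_frame[col] = pd.to_numeric(cohort_frame[col], errors="raise")

    params = raw[ecg_cols].copy()
    for col in ecg_cols:
        try:
            params[col] = pd.to_numeric(params[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = params[pd.to_numeric(params[col], errors="coerce").isna() & params[col].notna()]
            rows = bad.index.tolist()
            raise ValueError(f"non-numeric value in ECG column {col!r}, rows {rows}") from exc
    if params.isna().any().any():
        bad_cols = params.columns[params.isna().any()].tolist()
        raise ValueError(f"missing values in ECG columns: {bad_cols}")

    meta = catalogue.table.loc[catalogue.table["column"].isin(ecg_cols), ["parameter", "lead", "column"]]
    cohort = CohortTable(cohort_frame)
    cohort.validate()
    return cohort, ParameterMatrix(params, meta.reset_index(drop=True))


def write_parameter_table(cohort: CohortTable, params: ParameterMatrix, path, sep: str | None = None) -> None:
    """Write cohort + parameters as one delimited table (inverse of read)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    merged = cohort.frame.join(params.frame, how="left")
    out = merged.reset_index().rename(columns={"index": "patient_id"})
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Eligibility and follow-up


def apply_exclusions(
    cohort: CohortTable, params: ParameterMatrix
) -> tuple[CohortTable, ParameterMatrix, dict[str, int]]:
    """Apply the eligibility criteria; attribute each removal to the first
    matching criterion, in the fixed :data:`EXCLUSION_ORDER`."""
    f = cohort.frame
    criteria = {
        "structural_heart_disease": f["structural_heart_disease"].to_numpy(bool),
        "age_out_of_range": ((f["ca_years"] < 20) | (f["ca_years"] > 90)).to_numpy(),
        "indeterminate_axis": f["indeterminate_axis"].to_numpy(bool),
        "pacing": f["pacing"].to_numpy(bool),
        "tachyarrhythmia": f["tachyarrhythmia"].to_numpy(bool),
    }
    report = {name: 0 for name in EXCLUSION_ORDER}
    excluded = np.zeros(len(f), dtype=bool)
    for name in EXCLUSION_ORDER:
        hit = criteria[name] & ~excluded
        report[name] = int(hit.sum())
        excluded |= criteria[name]
    keep = f.index[~excluded]
    out_cohort = CohortTable(f.loc[keep].copy())
    out_params = ParameterMatrix(params.frame.loc[keep].copy(), params.column_meta)
    return out_cohort, out_params, report


def truncate_followup(cohort: CohortTable, cap_days: float = FOLLOWUP_CAP_DAYS) -> CohortTable:
    """Cap follow-up at ``cap_days``; deaths beyond the cap are censored
    (status reset to alive) because outcomes are evaluated within the window."""
    if cap_days <= 0:
        raise ValueError("cap_days must be positive")
    f = cohort.frame.copy()
    if (f["followup_days"] < 0).any():
        raise ValueError("negative followup_days")
    over = f["followup_days"] > cap_days
    f.loc[over, "followup_days"] = cap_days
    f.loc[over, "status"] = "alive"
    f.loc[over, "death_cause"] = "none"
    return CohortTable(f)


# ---------------------------------------------------------------------------
# Clinical covariates


def egfr_mdrd_ja(scr_mg_dl: float, age_years: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the Japanese-coefficient MDRD
    equation: 194 * SCr^-1.004 * Age^-0.287, times 0.739 for women."""
    scr = np.asarray(scr_mg_dl, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    value = 194.0 * scr ** -1.004 * age ** -0.287
    sex_arr = np.asarray(sex)
    if sex_arr.shape == ():
        if str(sex) not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        factor = 0.739 if sex == "female" else 1.0
    else:
        factor = np.where(sex_arr == "female", 0.739, 1.0)
    result = value * factor
    return float(result) if np.ndim(result) == 0 else result


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, kg/m^2."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    result = w / h**2
    return float(result) if np.ndim(result) == 0 else result
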