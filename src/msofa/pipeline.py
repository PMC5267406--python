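"""Cohort pipeline: read long-format ICU observations, apply eligibility,
select worst-in-window values, impute single gaps, and score each patient
at admission (T0) and 48 hours (T48).

Input schema
------------
Two comma-separated UTF-8 files with header rows.

``observations.csv`` — one row per patient per timestamp:
    patient_id, timestamp_h, spo2, pao2, oxygen_device, oxygen_flow, fio2,
    map, gcs, platelets, bilirubin, creatinine, urine_output,
    dopamine, dobutamine, norepinephrine
Units: timestamp_h hours since ICU admission; spo2 percent; pao2 mmHg;
oxygen_device one of room_air/nasal_cannula/face_mask/ventilator;
oxygen_flow L/min; fio2 fraction; map mmHg; gcs 3–15; platelets 10^3/mm^3;
bilirubin and creatinine mg/dL; urine_output mL/day; vasopressor doses
µg/kg/min (blank or 0 = not administered).

``patients.csv`` — one row per patient:
    patient_id, age, sex, admission_source, admission_type,
    mechanically_ventilated, vasopressor_used, low_risk_monitoring,
    icu_los_days, outcome
``outcome`` is survived/died/none; boolean columns accept 0/1 or
true/false.

Scoring windows are T0 = [0, 24) h and T48 = [24, 48] h from admission;
within each window the worst value of each parameter is used (minimum for
the oxygenation ratio, platelets, MAP, GCS and urine output; maximum for
bilirubin, creatinine and vasopressor doses).  A single missing value in a
parameter's time-ordered series, with a measurement on each side, is
replaced by the mean of its two neighbours; longer runs and edge gaps stay
missing.  An organ left unscorable after imputation scores 0 by default
and raises a per-patient completeness flag; in strict mode the patient is
excluded instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    IncompleteObservationError,
    OrganSubscores,
    OxygenDelivery,
    OxygenDevice,
    RespiratoryMode,
    VasopressorDose,
    VasopressorDrug,
    cardiovascular_subscore,
    cns_subscore,
    coagulation_subscore,
    estimate_fio2,
    liver_subscore,
    oxygenation_ratio,
    renal_subscore,
    respiratory_subscore,
)

logger = logging.getLogger(__name__)

T0_WINDOW: tuple[float, float] = (0.0, 24.0)
T48_WINDOW: tuple[float, float] = (24.0, 48.0)


class Outcome(str, Enum):
    SURVIVED = "survived"
    DIED = "died"
    NONE = "none"


class ExclusionReason(str, Enum):
    LOW_RISK_MONITORING = "low_risk_monitoring"
    DIED_OR_DISCHARGED_LT_24H = "died_or_discharged_lt_24h"
    NO_OUTCOME = "no_outcome"
    AGE_LE_12 = "age_le_12"


class SchemaError(ValueError):
    """Input file violates the documented schema; message lists offenders."""


@dataclass(frozen=True)
class ClinicalObservation:
    """One timestamped measurement set for one patient."""

    patient_id: str
    timestamp: float  # hours since ICU admission
    spo2: Optional[float] = None
    pao2: Optional[float] = None
    oxygen: Optional[OxygenDelivery] = None
    map: Optional[float] = None
    gcs: Optional[int] = None
    platelets: Optional[float] = None
    bilirubin: Optional[float] = None
    creatinine: Optional[float] = None
    urine_output: Optional[float] = None
    vasopressors: tuple[VasopressorDose, ...] = ()

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0 h, got {self.timestamp}")


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, eligibility fields, outcome and observation series."""

    patient_id: str
    age: float
    sex: str
    admission_source: str
    admission_type: str
    mechanically_ventilated: bool
    vasopressor_used: bool
    icu_los: float  # days
    outcome: Outcome
    low_risk_monitoring: bool = False
    observations: tuple[ClinicalObservation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", Outcome(self.outcome))
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.icu_los < 0:
            raise ValueError(f"icu_los must be >= 0, got {self.icu_los}")
        obs = tuple(sorted(self.observations, key=lambda o: o.timestamp))
        object.__setattr__(self, "observations", obs)


@dataclass(frozen=True)
class EligibilityReport:
    screened: int
    enrolled: int
    excluded: tuple[tuple[str, ExclusionReason], ...]
    analyzed: int

    def reason_counts(self) -> dict[str, int]:
        counts = {reason.value: 0 for reason in ExclusionReason}
        for _, reason in self.excluded:
            counts[reason.value] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [("screened", self.screened), ("enrolled", self.enrolled)]
        rows += [(f"excluded_{k}", v) for k, v in self.reason_counts().items()]
        rows.append(("analyzed", self.analyzed))
        return pd.DataFrame(rows, columns=["item", "count"])


@dataclass(frozen=True)
class ScoreSummary:
    """Per-patient T0/T48 subscores and the derived score family.

    The derived quantities are computed from the two totals, so the
    identities delta = at48 - initial, total_sum = 2 * mean_score and
    highest = max(initial, at48) hold by construction.
    """

    patient_id: str
    t0_subscores: OrganSubscores
    t48_subscores: OrganSubscores
    missing_t0: tuple[str, ...] = ()
    missing_t48: tuple[str, ...] = ()

    @property
    def t0_total(self) -> int:
        return self.t0_subscores.total

    @property
    def t48_total(self) -> int:
        return self.t48_subscores.total

    @property
    def initial(self) -> int:
        return self.t0_total

    @property
    def at48(self) -> int:
        return self.t48_total

    @property
    def mean_score(self) -> float:
        return (self.t0_total + self.t48_total) / 2.0

    @property
    def highest(self) -> int:
        return max(self.t0_total, self.t48_total)

    @property
    def delta(self) -> int:
        return self.t48_total - self.t0_total

    @property
    def total_sum(self) -> int:
        return self.t0_total + self.t48_total

    @property
    def complete(self) -> bool:
        return not self.missing_t0 and not self.missing_t48


class UnscorablePatientError(ValueError):
    """A scoring window has no usable observations for this patient."""


# ---------------------------------------------------------------------------
# Reading & validation

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False,
             "yes": True, "no": False}

#: column -> (required, lower bound, upper bound); bounds are physiologic
#: validity limits, inclusive.
OBSERVATION_SCHEMA: dict[str, tuple[bool, float, float]] = {
    "timestamp_h": (True, 0.0, 10_000.0),
    "spo2": (False, 0.0, 100.0),
    "pao2": (False, 0.0, 700.0),
    "oxygen_flow": (False, 0.0, 80.0),
    "fio2": (False, 0.21, 1.0),
    "map": (False, 10.0, 250.0),
    "gcs": (False, 3.0, 15.0),
    "platelets": (False, 0.0, 3000.0),
    "bilirubin": (False, 0.0, 80.0),
    "creatinine": (False, 0.0, 40.0),
    "urine_output": (False, 0.0, 20_000.0),
    "dopamine": (False, 0.0, 100.0),
    "dobutamine": (False, 0.0, 100.0),
    "norepinephrine": (False, 0.0, 10.0),
}

PATIENT_COLUMNS = (
    "patient_id", "age", "sex", "admission_source", "admission_type",
    "mechanically_ventilated", "vasopressor_used", "low_risk_monitoring",
    "icu_los_days", "outcome",
)

ADMISSION_SOURCES = (
    "emergency_room", "operating_room", "pacu", "obstetric_theatre",
    "medical_ward", "surgical_ward", "obstetric_gynecology_ward",
    "other_hospital",
)


def _parse_bool(value, column: str, row: int, errors: list[str]) -> bool:
    key = str(value).strip().lower()
    if key in _BOOL_MAP:
        return _BOOL_MAP[key]
    errors.append(f"row {row}: column {column!r} has non-boolean value {value!r}")
    return False


def _obs_from_row(row: pd.Series, line: int, errors: list[str]) -> Optional[ClinicalObservation]:
    def opt(col: str) -> Optional[float]:
        if col not in row or pd.isna(row[col]):
            return None
        value = row[col]
        if not isinstance(value, (int, float, np.integer, np.floating)):
            errors.append(f"row {line}: column {col!r} is non-numeric: {value!r}")
            return None
        _, lo, hi = OBSERVATION_SCHEMA[col]
        if not (lo <= value <= hi):
            errors.append(f"row {line}: column {col!r} value {value} outside [{lo}, {hi}]")
            return None
        return float(value)

    oxygen: Optional[OxygenDelivery] = None
    if "oxygen_device" in row and not pd.isna(row["oxygen_device"]) and str(row["oxygen_device"]).strip():
        device = str(row["oxygen_device"]).strip().lower()
        try:
            oxygen = OxygenDelivery(OxygenDevice(device), flow=opt("oxygen_flow"), fio2=opt("fio2"))
        except ValueError as exc:
            errors.append(f"row {line}: invalid oxygen delivery: {exc}")

    vaso: list[VasopressorDose] = []
    for drug in VasopressorDrug:
        dose = opt(drug.value)
        if dose is not None and dose > 0:
            vaso.append(VasopressorDose(drug, dose))

    timestamp = opt("timestamp_h")
    if timestamp is None:
        errors.append(f"row {line}: missing or invalid timestamp_h")
        return None
    gcs_value = opt("gcs")
    if gcs_value is not None and gcs_value != int(gcs_value):
        errors.append(f"row {line}: gcs must be an integer, got {gcs_value}")
        gcs_value = None
    try:
        return ClinicalObservation(
            patient_id=str(row["patient_id"]),
            timestamp=timestamp,
            spo2=opt("spo2"),
            pao2=opt("pao2"),
            oxygen=oxygen,
            map=opt("map"),
            gcs=int(gcs_value) if gcs_value is not None else None,
            platelets=opt("platelets"),
            bilirubin=opt("bilirubin"),
            creatinine=opt("creatinine"),
            urine_output=opt("urine_output"),
            vasopressors=tuple(vaso),
        )
    except ValueError as exc:
        errors.append(f"row {line}: {exc}")
        return None


def read_observations(
    observations_path,
    patients_path,
    schema: Optional[dict[str, tuple[bool, float, float]]] = None,
) -> list[PatientRecord]:
    """Read and validate the two-file cohort schema into PatientRecords.

    Malformed rows are reported with their (1-based, header-inclusive)
    line numbers; any violation raises :class:`SchemaError` listing every
    offender found.  An empty observations file yields an empty cohort
    with a logged warning.
    """
    schema = dict(OBSERVATION_SCHEMA if schema is None else schema)
    errors: list[str] = []

    try:
        obs_df = pd.read_csv(observations_path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        obs_df = pd.DataFrame(columns=["patient_id", "timestamp_h"])
    try:
        pat_df = pd.read_csv(patients_path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        pat_df = pd.DataFrame(columns=list(PATIENT_COLUMNS))

    if obs_df.empty and pat_df.empty:
        logger.warning("empty cohort: %s has no observation rows", observations_path)
        return []

    known_obs = {"patient_id", "oxygen_device", *schema}
    unknown = set(obs_df.columns) - known_obs
    if unknown:
        errors.append(f"unknown observation columns: {sorted(unknown)}")
    missing_cols = {"patient_id", "timestamp_h"} - set(obs_df.columns)
    if missing_cols:
        raise SchemaError(f"observations file lacks required columns: {sorted(missing_cols)}")
    missing_pat = set(PATIENT_COLUMNS) - set(pat_df.columns)
    if missing_pat:
        raise SchemaError(f"patients file lacks required columns: {sorted(missing_pat)}")

    dup = obs_df.duplicated(subset=["patient_id", "timestamp_h"], keep=False)
    if dup.any():
        offenders = obs_df.loc[dup, ["patient_id", "timestamp_h"]].drop_duplicates()
        pairs = [f"({r.patient_id}, {r.timestamp_h})" for r in offenders.itertuples()]
        errors.append(f"duplicate (patient_id, timestamp_h) pairs: {', '.join(pairs)}")

    # coerce numeric columns, flagging non-numeric cells with line numbers
    for col in schema:
        if col not in obs_df.columns:
            continue
        coerced = pd.to_numeric(obs_df[col], errors="coerce")
        bad = coerced.isna() & obs_df[col].notna()
        for idx in obs_df.index[bad]:
            errors.append(f"row {idx + 2}: column {col!r} is non-numeric: {obs_df.at[idx, col]!r}")
        obs_df[col] = coerced

    observations: dict[str, list[ClinicalObservation]] = {}
    for idx, row in obs_df.iterrows():
        obs = _obs_from_row(row, idx + 2, errors)  # +2: header line + 1-based
        if obs is not None:
            observations.setdefault(obs.patient_id, []).append(obs)

    records: list[PatientRecord] = []
    for idx, row in pat_df.iterrows():
        line = idx + 2
        try:
            record = PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                admission_source=str(row["admission_source"]).strip().lower(),
                admission_type=str(row["admission_type"]).strip().lower(),
                mechanically_ventilated=_parse_bool(row["mechanically_ventilated"], "mechanically_ventilated", line, errors),
                vasopressor_used=_parse_bool(row["vasopressor_used"], "vasopressor_used", line, errors),
                low_risk_monitoring=_parse_bool(row["low_risk_monitoring"], "low_risk_monitoring", line, errors),
                icu_los=float(row["icu_los_days"]),
                outcome=Outcome(str(row["outcome"]).strip().lower()),
                observations=tuple(observations.get(str(row["patient_id"]), ())),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"patients row {line}: {exc}")
            continue
        records.append(record)

    orphan = set(observations) - {r.patient_id for r in records}
    if orphan:
        errors.append(f"observations for unknown patient_ids: {sorted(orphan)}")

    if errors:
        raise SchemaError("input validation failed:\n  " + "\n  ".join(errors))
    if not records:
        logger.warning("empty cohort read from %s", patients_path)
    return records


# ---------------------------------------------------------------------------
# Eligibility

def apply_eligibility(records: Sequence[PatientRecord]) -> tuple[list[PatientRecord], EligibilityReport]:
    """Apply the enrolment rules: adults (>12 years) staying >24 h with a
    known outcome, excluding low-risk-monitoring admissions.

    Each excluded patient carries exactly one primary reason, resolved in
    the order age, low-risk monitoring, early death/discharge, no outcome.
    """
    included: list[PatientRecord] = []
    excluded: list[tuple[str, ExclusionReason]] = []
    for record in records:
        if record.age <= 12:
            excluded.append((record.patient_id, ExclusionReason.AGE_LE_12))
        elif record.low_risk_monitoring:
            excluded.append((record.patient_id, ExclusionReason.LOW_RISK_MONITORING))
        elif record.icu_los <= 1.0:
            excluded.append((record.patient_id, ExclusionReason.DIED_OR_DISCHARGED_LT_24H))
        elif record.outcome is Outcome.NONE:
            excluded.append((record.patient_id, ExclusionReason.NO_OUTCOME))
        else:
            included.append(record)
    report = EligibilityReport(
        screened=len(records),
        enrolled=len(records),
        excluded=tuple(excluded),
        analyzed=len(included),
    )
    return included, report


# ---------------------------------------------------------------------------
# Worst-in-window selection and single-gap imputation

#: direction of "worst" per parameter: min = lower is worse, max = higher is worse
WORST_DIRECTION: dict[str, str] = {
    "oxygenation_ratio": "min",
    "spo2": "min",
    "pao2": "min",
    "platelets": "min",
    "map": "min",
    "gcs": "min",
    "urine_output": "min",
    "bilirubin": "max",
    "creatinine": "max",
    "fio2": "max",
    "dopamine": "max",
    "dobutamine": "max",
    "norepinephrine": "max",
}


def _parameter_value(obs: ClinicalObservation, parameter: str,
                     mode: RespiratoryMode = RespiratoryMode.SPO2) -> Optional[float]:
    if parameter == "oxygenation_ratio":
        if obs.oxygen is None:
            return None
        try:
            fio2 = estimate_fio2(obs.oxygen)
            return oxygenation_ratio(obs.spo2, obs.pao2, fio2, mode)
        except (IncompleteObservationError, ValueError):
            return None
    if parameter == "fio2":
        if obs.oxygen is None:
            return None
        try:
            return estimate_fio2(obs.oxygen)
        except IncompleteObservationError:
            return None
    if parameter in ("dopamine", "dobutamine", "norepinephrine"):
        doses = [v.dose for v in obs.vasopressors if v.drug is VasopressorDrug(parameter)]
        return max(doses) if doses else None
    if not hasattr(obs, parameter):
        raise ValueError(f"unknown parameter {parameter!r}")
    value = getattr(obs, parameter)
    return float(value) if value is not None else None


def worst_in_window(
    observations: Sequence[ClinicalObservation],
    window: tuple[float, float],
    parameter: str,
    mode: RespiratoryMode = RespiratoryMode.SPO2,
    closed_right: bool = False,
) -> Optional[float]:
    """Worst value of ``parameter`` among observations inside ``window``.

    The window is [start, end) by default (``closed_right=True`` includes
    the right edge, used for the T48 window so an observation at exactly
    48 h counts).  Returns None when no in-window observation carries the
    parameter.
    """
    if parameter not in WORST_DIRECTION:
        raise ValueError(f"unknown parameter {parameter!r}")
    start, end = window
    values = []
    for obs in observations:
        inside = start <= obs.timestamp < end or (closed_right and obs.timestamp == end)
        if not inside:
            continue
        value = _parameter_value(obs, parameter, mode)
        if value is not None:
            values.append(value)
    if not values:
        return None
    return min(values) if WORST_DIRECTION[parameter] == "min" else max(values)


def impute_single_gap(series: Sequence[Optional[float]]) -> list[Optional[float]]:
    """Fill isolated missing values in a time-ordered series.

    A missing entry with a present value immediately before and after
    becomes the arithmetic mean of those two neighbours.  Leading and
    trailing gaps and runs of two or more stay missing.  Present values
    are never altered, and the operation is idempotent.
    """
    values = list(series)
    filled = list(values)
    for i, v in enumerate(values):
        if v is not None:
            continue
        if 0 < i < len(values) - 1 and values[i - 1] is not None and values[i + 1] is not None:
            filled[i] = (values[i - 1] + values[i + 1]) / 2.0
    return filled


# ---------------------------------------------------------------------------
# Per-patient scoring

_IMPUTABLE = ("spo2", "pao2", "fio2", "map", "gcs", "platelets",
              "bilirubin", "creatinine", "urine_output")


def _imputed_observations(record: PatientRecord) -> list[ClinicalObservation]:
    """Apply single-gap imputation per parameter across the observation series."""
    obs = list(record.observations)
    series = {p: impute_single_gap([_parameter_value(o, p) for o in obs]) for p in _IMPUTABLE}
    out = []
    for i, o in enumerate(obs):
        oxygen = o.oxygen
        if series["fio2"][i] is not None and (oxygen is None or _parameter_value(o, "fio2") is None):
            # an imputed FiO2 stands in for an unknown delivery state
            fio2 = min(max(series["fio2"][i], 0.21), 1.0)
            oxygen = OxygenDelivery(OxygenDevice.VENTILATOR, fio2=fio2)
        gcs = series["gcs"][i]
        out.append(replace(
            o,
            spo2=series["spo2"][i],
            pao2=series["pao2"][i],
            oxygen=oxygen,
            map=series["map"][i],
            gcs=int(round(gcs)) if gcs is not None else None,
            platelets=series["platelets"][i],
            bilirubin=series["bilirubin"][i],
            creatinine=series["creatinine"][i],
            urine_output=series["urine_output"][i],
        ))
    return out


def _score_window(
    observations: Sequence[ClinicalObservation],
    window: tuple[float, float],
    mode: RespiratoryMode,
    closed_right: bool,
) -> tuple[OrganSubscores, tuple[str, ...]]:
    def worst(parameter: str) -> Optional[float]:
        return worst_in_window(observations, window, parameter, mode, closed_right)

    start, end = window
    in_window = [o for o in observations
                 if start <= o.timestamp < end or (closed_right and o.timestamp == end)]
    if not in_window:
        raise UnscorablePatientError(
            f"no observations in window [{start}, {end}{']' if closed_right else ')'} h")

    missing: list[str] = []

    ratio = worst("oxygenation_ratio")
    if ratio is None:
        missing.append("respiratory")
        respiratory = 0
    else:
        respiratory = respiratory_subscore(ratio, mode)

    platelets = worst("platelets")
    if platelets is None:
        missing.append("coagulation")
        coagulation = 0
    else:
        coagulation = coagulation_subscore(platelets)

    bilirubin = worst("bilirubin")
    if bilirubin is None:
        missing.append("liver")
        liver = 0
    else:
        liver = liver_subscore(bilirubin)

    map_w = worst("map")
    vaso = [VasopressorDose(VasopressorDrug(drug), dose)
            for drug in ("dopamine", "dobutamine", "norepinephrine")
            if (dose := worst(drug)) is not None]
    if map_w is None and not vaso:
        missing.append("cardiovascular")
        cardiovascular = 0
    else:
        cardiovascular = cardiovascular_subscore(map_w, vaso)

    gcs = worst("gcs")
    if gcs is None:
        missing.append("cns")
        cns = 0
    else:
        cns = cns_subscore(gcs)

    creatinine = worst("creatinine")
    urine = worst("urine_output")
    if creatinine is None and urine is None:
        missing.append("renal")
        renal = 0
    else:
        renal = renal_subscore(creatinine, urine)

    subscores = OrganSubscores(respiratory, coagulation, liver, cardiovascular,
                               cns, renal, respiratory_mode=mode)
    return subscores, tuple(missing)


def score_timepoints(
    record: PatientRecord,
    mode: RespiratoryMode | str = RespiratoryMode.SPO2,
    strict_missing: bool = False,
) -> ScoreSummary:
    """Score one eligible patient at T0 and T48 and derive the score family.

    Raises :class:`UnscorablePatientError` when either window has no
    observations, or — in strict mode — when any organ component remains
    unscorable after imputation.
    """
    mode = RespiratoryMode(mode)
    observations = _imputed_observations(record)
    t0_sub, miss0 = _score_window(observations, T0_WINDOW, mode, closed_right=False)
    t48_sub, miss48 = _score_window(observations, T48_WINDOW, mode, closed_right=True)
    if strict_missing and (miss0 or miss48):
        raise UnscorablePatientError(
            f"unscorable components after imputation: T0 {list(miss0)}, T48 {list(miss48)}")
    return ScoreSummary(record.patient_id, t0_sub, t48_sub, miss0, miss48)


def score_cohort(
    records: Sequence[PatientRecord],
    mode: RespiratoryMode | str = RespiratoryMode.SPO2,
    strict_missing: bool = False,
) -> tuple[list[ScoreSummary], list[tuple[str, str]]]:
    """Score every record; returns (summaries, skipped (patient_id, reason))."""
    summaries: list[ScoreSummary] = []
    skipped: list[tuple[str, str]] = []
    for record in records:
        try:
            summaries.append(score_timepoints(record, mode, strict_missing))
        except UnscorablePatientError as exc:
            logger.warning("patient %s unscorable: %s", record.patient_id, exc)
            skipped.append((record.patient_id, str(exc)))
    return summaries, skipped


def scores_to_frame(
    summaries: Sequence[ScoreSummary],
    records: Optional[Sequence[PatientRecord]] = None,
) -> pd.DataFrame:
    """Per-patient score table: subscores at both timepoints, the derived
    family, and completeness flags; outcome/demographics joined when the
    records are supplied."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"patient_id": s.patient_id}
        for tp, sub in (("t0", s.t0_subscores), ("t48", s.t48_subscores)):
            for organ, points in sub.as_dict().items():
                row[f"{tp}_{organ}"] = points
        row.update(
            t0_total=s.t0_total, t48_total=s.t48_total,
            initial=s.initial, at48=s.at48, mean_score=s.mean_score,
            highest=s.highest, delta=s.delta, total_sum=s.total_sum,
            complete=s.complete,
            missing_t0=";".join(s.missing_t0),
            missing_t48=";".join(s.missing_t48),
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if records is not None and not frame.empty:
        meta = pd.DataFrame([
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "mechanically_ventilated": r.mechanically_ventilated,
                "vasopressor_used": r.vasopressor_used,
                "icu_los_days": r.icu_los,
                "outcome": r.outcome.value,
            }
            for r in records
        ])
        frame = frame.merge(meta, on="patient_id", how="left")
    return frame
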