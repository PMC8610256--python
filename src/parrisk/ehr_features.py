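"""Cohort filters and extraction of the 12 score predictors from EHR records.

The predictor set comprises two administrative flags (length of stay > 4
days, admission in the previous six months), eight ICD-10-coded
comorbidities, in-stay opioid dispensing (ATC ``N02A`` and sub-levels), and
hyperkalaemia (serum potassium > 5.5 mmol/L in the last seven in-stay days,
with last-observation-carried-forward from earlier in the stay).

Patients with no potassium measurement at all are treated as normokalaemic
(values assumed not missing at random) and flagged ``potassium_missing``;
patients with no dispensing record at all cannot be scored for opioids and
are excluded from the base cohort, re-entering only through the published
sensitivity variants.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "PatientAdmission",
    "PredictorVector",
    "ComorbidityMap",
    "Dispensing",
    "LabResult",
    "DataError",
    "DispensingMissingError",
    "PREDICTOR_NAMES",
    "COMORBIDITY_PREDICTORS",
    "EXCLUSION_REASONS",
    "apply_inclusion",
    "apply_exclusion",
    "extract_los_flag",
    "extract_prior_admission_flag",
    "extract_comorbidity_flags",
    "extract_opioid_flag",
    "extract_hyperkalaemia_flag",
    "extract_predictors",
    "extract_predictor_table",
    "sensitivity_variants",
    "load_comorbidity_map",
    "bundled_comorbidity_map",
    "load_cohort",
]

# ---------------------------------------------------------------------------
# Cohort and predictor constants
# ---------------------------------------------------------------------------

MIN_AGE_YEARS = 65
MIN_STAY_HOURS = 48          # inclusive: exactly 48 h is retained
LOS_FLAG_DAYS = 4.0          # strict: LOS must exceed 96 h to flag
PRIOR_WINDOW_DAYS = 183      # "previous six months", window-start inclusive
POTASSIUM_WINDOW_DAYS = 7
HYPERKALAEMIA_MMOL_L = 5.5   # strict: flag requires K+ > 5.5
OPIOID_ATC_PREFIX = "N02A"

COMORBIDITY_PREDICTORS = (
    "anaemia", "hypertension", "heart_failure", "acute_mi", "chronic_ihd",
    "diabetes_organ", "cancer", "metastatic_ca",
)
PREDICTOR_NAMES = (
    "los_gt4", "prior_adm_6m", *COMORBIDITY_PREDICTORS, "opioids",
    "hyperkalaemia",
)

#: Fixed evaluation order for the exclusion tally; each record is counted
#: once, at the first matching reason.
EXCLUSION_REASONS = ("death", "transfer", "non_swiss", "dispensing_missing")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}")


class DataError(ValueError):
    """An input record violates a hard data contract."""


class DispensingMissingError(DataError):
    """Opioid extraction requested for a patient with no dispensing data.

    Such patients must be excluded from the base cohort or routed to a
    sensitivity variant with the opioid flag forced.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dispensing:
    atc_code: str
    dispense_ts: pd.Timestamp


@dataclass(frozen=True)
class LabResult:
    analyte: str
    value: float        # mmol/L for potassium
    draw_ts: pd.Timestamp


@dataclass
class PatientAdmission:
    """One index hospitalisation with its nested clinical records."""

    patient_id: str
    age: float
    sex: str
    admission_ts: pd.Timestamp
    discharge_ts: pd.Timestamp
    residency: str                  # "Swiss" | "non-Swiss"
    disposition: str                # "home" | "death" | "transfer"
    diagnoses: list[str] = field(default_factory=list)
    dispensings: list[Dispensing] = field(default_factory=list)
    dispensing_available: bool = True
    labs: list[LabResult] = field(default_factory=list)
    prior_admissions: list[pd.Timestamp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.discharge_ts < self.admission_ts:
            raise DataError(
                f"{self.patient_id}: discharge precedes admission"
            )

    @property
    def los_hours(self) -> float:
        return (self.discharge_ts - self.admission_ts) / pd.Timedelta(hours=1)


@dataclass
class PredictorVector:
    """The 12 binary predictor flags plus missingness indicators."""

    patient_id: str
    los_gt4: bool = False
    prior_adm_6m: bool = False
    anaemia: bool = False
    hypertension: bool = False
    heart_failure: bool = False
    acute_mi: bool = False
    chronic_ihd: bool = False
    diabetes_organ: bool = False
    cancer: bool = False
    metastatic_ca: bool = False
    opioids: bool = False
    hyperkalaemia: bool = False
    potassium_missing: bool = False
    dispensing_missing: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in PREDICTOR_NAMES}


@dataclass(frozen=True)
class ComorbidityMap:
    """Mapping from comorbidity predictor name to ICD-10 code prefixes."""

    prefixes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [p for p in COMORBIDITY_PREDICTORS if p not in self.prefixes]
        if missing:
            raise DataError(f"comorbidity map lacks predictors: {missing}")
        empty = [k for k, v in self.prefixes.items() if not v]
        if empty:
            raise DataError(f"comorbidity map has empty prefix lists: {empty}")


def load_comorbidity_map(path: str | Path) -> ComorbidityMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ComorbidityMap(
        {k: tuple(str(p).upper() for p in v) for k, v in raw.items()}
    )


def bundled_comorbidity_map() -> ComorbidityMap:
    """Bundled synthetic stand-in map (standard ICD-10 ranges).

    The validation study used the code lists of the score's development
    publication, whose supplement cannot be redistributed; the packaged file
    ``comorbidity_map_synthetic.yaml`` substitutes standard Charlson-style
    ICD-10 ranges for the same eight conditions.
    """
    return load_comorbidity_map(
        Path(__file__).parent / "data" / "comorbidity_map_synthetic.yaml"
    )


# ---------------------------------------------------------------------------
# Inclusion / exclusion
# ---------------------------------------------------------------------------


def apply_inclusion(admissions: list[PatientAdmission]) -> list[PatientAdmission]:
    """Keep admissions of patients aged >= 65 hospitalised >= 48 hours."""
    return [
        a for a in admissions
        if a.age >= MIN_AGE_YEARS and a.los_hours >= MIN_STAY_HOURS
    ]


def apply_exclusion(
    admissions: list[PatientAdmission],
) -> tuple[list[PatientAdmission], dict[str, int]]:
    """Drop death-before-discharge, transfers, non-Swiss residents and
    patients with no dispensing information.

    Returns the retained admissions and a tally of exclusions in the fixed
    order ``death, transfer, non_swiss, dispensing_missing``; a record is
    counted once, at the first reason that matches.
    """
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    retained: list[PatientAdmission] = []
    for a in admissions:
        if a.disposition == "death":
            tally["death"] += 1
        elif a.disposition == "transfer":
            tally["transfer"] += 1
        elif a.residency != "Swiss":
            tally["non_swiss"] += 1
        elif not a.dispensing_available:
            tally["dispensing_missing"] += 1
        else:
            retained.append(a)
    return retained, tally


# ---------------------------------------------------------------------------
# Per-predictor extraction
# ---------------------------------------------------------------------------


def extract_los_flag(a: PatientAdmission) -> bool:
    """Length of stay strictly greater than four days (96 h)."""
    return a.los_hours > LOS_FLAG_DAYS * 24.0


def extract_prior_admission_flag(a: PatientAdmission) -> bool:
    """Any prior discharge within the 183 days before the index admission.

    The window is ``[admission - 183 d, admission)``: the start is inclusive,
    the index admission instant itself is not.
    """
    window_start = a.admission_ts - pd.Timedelta(days=PRIOR_WINDOW_DAYS)
    for prior in a.prior_admissions:
        if prior >= a.admission_ts:
            raise DataError(
                f"{a.patient_id}: prior discharge {prior} is not before the "
                f"index admission {a.admission_ts}"
            )
        if prior >= window_start:
            return True
    return False


def normalise_icd10(code: str) -> str | None:
    """Uppercase and strip dots; return None (with a warning) if malformed."""
    cleaned = code.strip().upper().replace(".", "")
    if not _ICD10_RE.match(cleaned):
        warnings.warn(f"skipping malformed ICD-10 code {code!r}", stacklevel=3)
        return None
    return cleaned


def extract_comorbidity_flags(
    a: PatientAdmission, cmap: ComorbidityMap
) -> dict[str, bool]:
    """Prefix-match the admission's diagnoses against the comorbidity map."""
    codes = [c for c in (normalise_icd10(d) for d in a.diagnoses) if c]
    return {
        name: any(code.startswith(pfx) for code in codes
                  for pfx in cmap.prefixes[name])
        for name in COMORBIDITY_PREDICTORS
    }


def extract_opioid_flag(a: PatientAdmission) -> bool:
    """Any ATC N02A (or sub-level) dispensing during the stay, inclusive ends."""
    if not a.dispensing_available:
        raise DispensingMissingError(
            f"{a.patient_id}: dispensing records missing; exclude the patient "
            "or use a sensitivity variant with the opioid flag forced"
        )
    return any(
        d.atc_code.strip().upper().startswith(OPIOID_ATC_PREFIX)
        and a.admission_ts <= d.dispense_ts <= a.discharge_ts
        for d in a.dispensings
    )


def extract_hyperkalaemia_flag(a: PatientAdmission) -> tuple[bool, bool]:
    """Hyperkalaemia over the last seven in-stay days, with carry-forward.

    Potassium draws within ``[discharge - 7 d, discharge]`` are considered;
    if none exist, the most recent earlier in-stay value is carried forward.
    The flag is true iff any considered value exceeds 5.5 mmol/L (strict).
    A patient with no potassium value at all is assumed normokalaemic:
    returns ``(False, True)``.
    """
    window_start = a.discharge_ts - pd.Timedelta(days=POTASSIUM_WINDOW_DAYS)
    potassium = [
        lab for lab in a.labs
        if lab.analyte == "potassium" and lab.draw_ts <= a.discharge_ts
    ]
    for lab in potassium:
        if lab.value <= 0:
            raise DataError(
                f"{a.patient_id}: non-positive potassium {lab.value} mmol/L"
            )
    in_window = [lab for lab in potassium if lab.draw_ts >= window_start]
    if not in_window:
        earlier = [lab for lab in potassium if lab.draw_ts < window_start]
        if earlier:
            in_window = [max(earlier, key=lambda lab: lab.draw_ts)]
    if not in_window:
        return False, True
    return any(lab.value > HYPERKALAEMIA_MMOL_L for lab in in_window), False


def extract_predictors(
    a: PatientAdmission,
    cmap: ComorbidityMap,
    *,
    allow_missing_dispensing: bool = False,
) -> PredictorVector:
    """Assemble the full predictor vector for one admission.

    With ``allow_missing_dispensing`` the opioid flag of a dispensing-missing
    patient is provisionally False and ``dispensing_missing`` is set, for use
    by the sensitivity variants; otherwise such a patient raises
    :class:`DispensingMissingError`.
    """
    hyper, k_missing = extract_hyperkalaemia_flag(a)
    if a.dispensing_available:
        opioids, disp_missing = extract_opioid_flag(a), False
    elif allow_missing_dispensing:
        opioids, disp_missing = False, True
    else:
        raise DispensingMissingError(
            f"{a.patient_id}: dispensing records missing"
        )
    return PredictorVector(
        patient_id=a.patient_id,
        los_gt4=extract_los_flag(a),
        prior_adm_6m=extract_prior_admission_flag(a),
        opioids=opioids,
        hyperkalaemia=hyper,
        potassium_missing=k_missing,
        dispensing_missing=disp_missing,
        **extract_comorbidity_flags(a, cmap),
    )


def extract_predictor_table(
    admissions: list[PatientAdmission],
    cmap: ComorbidityMap,
    *,
    allow_missing_dispensing: bool = False,
) -> pd.DataFrame:
    """Predictor flags for a cohort, one row per patient, indexed by id."""
    rows = [
        extract_predictors(
            a, cmap, allow_missing_dispensing=allow_missing_dispensing
        )
        for a in admissions
    ]
    df = pd.DataFrame(
        [
            {"patient_id": pv.patient_id, **pv.as_dict(),
             "potassium_missing": pv.potassium_missing,
             "dispensing_missing": pv.dispensing_missing}
            for pv in rows
        ]
    )
    return df.set_index("patient_id")


# ---------------------------------------------------------------------------
# Sensitivity variants
# ---------------------------------------------------------------------------


def sensitivity_variants(
    predictors: pd.DataFrame,
    excluded_dispensing_missing: list[PatientAdmission],
    cmap: ComorbidityMap,
) -> dict[str, pd.DataFrame]:
    """The three published missing-data sensitivity cohorts.

    ``hyperkalaemia_to_1`` flips the hyperkalaemia flag to True for every
    potassium-missing patient of the base cohort.  ``opioids_to_0`` /
    ``opioids_to_1`` re-admit the dispensing-missing patients with the opioid
    flag forced to False / True respectively.  All other flags are untouched.
    """
    variant_a = predictors.copy()
    variant_a.loc[variant_a["potassium_missing"], "hyperkalaemia"] = True

    readmitted = extract_predictor_table(
        excluded_dispensing_missing, cmap, allow_missing_dispensing=True
    ) if excluded_dispensing_missing else predictors.iloc[0:0].copy()

    variants = {"hyperkalaemia_to_1": variant_a}
    for label, forced in (("opioids_to_0", False), ("opioids_to_1", True)):
        extra = readmitted.copy()
        extra["opioids"] = forced
        variants[label] = pd.concat([predictors, extra])
    return variants


# ---------------------------------------------------------------------------
# CSV loading
# ---------------------------------------------------------------------------


def load_cohort(directory: str | Path) -> list[PatientAdmission]:
    """Build admission objects from the five input CSV tables.

    Expects ``admissions.csv``, ``diagnoses.csv``, ``dispensings.csv``,
    ``labs.csv`` and ``prior_admissions.csv`` with ISO-8601 timestamps; the
    last four tables may be absent (treated as empty).
    """
    directory = Path(directory)
    adm = pd.read_csv(directory / "admissions.csv")

    def _grouped(name: str, parse_ts: list[str]) -> dict:
        path = directory / name
        if not path.exists():
            return {}
        df = pd.read_csv(path)
        for col in parse_ts:
            df[col] = pd.to_datetime(df[col])
        return {pid: g for pid, g in df.groupby("patient_id")}

    diag = _grouped("diagnoses.csv", [])
    disp = _grouped("dispensings.csv", ["dispense_ts"])
    labs = _grouped("labs.csv", ["draw_ts"])
    prior = _grouped("prior_admissions.csv", ["prior_discharge_ts"])

    out: list[PatientAdmission] = []
    for row in adm.itertuples(index=False):
        pid = row.patient_id
        d = disp.get(pid)
        lb = labs.get(pid)
        out.append(
            PatientAdmission(
                patient_id=str(pid),
                age=float(row.age),
                sex=str(row.sex),
                admission_ts=pd.Timestamp(row.admission_ts),
                discharge_ts=pd.Timestamp(row.discharge_ts),
                residency=str(row.residency),
                disposition=str(row.disposition),
                diagnoses=(
                    list(diag[pid]["icd10_code"]) if pid in diag else []
                ),
                dispensings=[
                    Dispensing(r.atc_code, r.dispense_ts)
                    for r in d.itertuples(index=False)
                ] if d is not None else [],
                dispensing_available=bool(row.dispensing_available),
                labs=[
                    LabResult(r.analyte, float(r.value), r.draw_ts)
                    for r in lb.itertuples(index=False)
                ] if lb is not None else [],
                prior_admissions=(
                    list(prior[pid]["prior_discharge_ts"])
                    if pid in prior else []
                ),
            )
        )
    return out
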