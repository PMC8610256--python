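"""Synthetic EHR cohort generator.

Emits the five raw input tables the extraction stage consumes (admissions,
ICD-10 diagnoses, ATC-coded dispensings, potassium labs, prior-admission
dates), an outcome table, and a ground-truth table recording the flags,
event probabilities and exclusion reasons each record was generated from.

The generator emulates the validation cohort's statistical structure: the
twelve predictor flags are drawn independently at the published marginal
prevalences, the 30-day potentially-avoidable-readmission (PAR) outcome
follows a logistic model whose slopes default to the published unadjusted
log odds ratios and whose intercept is calibrated so the marginal event
rate matches the published 5.7%, potassium results are missing for 7.2% of
patients and dispensing records for 1.5%.  Additional records violating the
inclusion and exclusion rules are appended at configurable rates so the
cohort filters have real work to do.

Flags are materialised as concrete records: a matching ICD-10 code per
comorbidity, an in-stay N02A dispensing for opioid users (plus decoy
non-opioid dispensings and pre-admission opioid dispensings that must *not*
flag), a potassium value above 5.5 mmol/L in the final week for
hyperkalaemic patients (sometimes only before the window, exercising the
carry-forward rule), and admission arithmetic consistent with the
length-of-stay and prior-admission flags.  Output is byte-reproducible for
a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .ehr_features import (
    COMORBIDITY_PREDICTORS,
    PREDICTOR_NAMES,
    ComorbidityMap,
    bundled_comorbidity_map,
)

__all__ = [
    "CohortConfig",
    "DEFAULT_PREVALENCE",
    "DEFAULT_LOG_ODDS_RATIOS",
    "calibrate_intercept",
    "expected_event_rate",
    "draw_flags",
    "generate_cohort",
    "write_cohort",
    "TABLE_NAMES",
]

#: Marginal predictor prevalences of the validation cohort (n = 5,985).
DEFAULT_PREVALENCE: dict[str, float] = {
    "los_gt4": 0.738,
    "prior_adm_6m": 0.227,
    "anaemia": 0.206,
    "hypertension": 0.696,
    "heart_failure": 0.227,
    "acute_mi": 0.046,
    "chronic_ihd": 0.253,
    "diabetes_organ": 0.078,
    "cancer": 0.105,
    "metastatic_ca": 0.068,
    "opioids": 0.265,
    "hyperkalaemia": 0.003,
}

#: Published unadjusted odds ratios, logged — a convenience default for the
#: outcome model, not a claim about the true joint model.
DEFAULT_LOG_ODDS_RATIOS: dict[str, float] = {
    "los_gt4": float(np.log(1.37)),
    "prior_adm_6m": float(np.log(1.59)),
    "anaemia": float(np.log(1.68)),
    "hypertension": float(np.log(1.15)),
    "heart_failure": float(np.log(1.56)),
    "acute_mi": float(np.log(1.03)),
    "chronic_ihd": float(np.log(1.10)),
    "diabetes_organ": float(np.log(1.38)),
    "cancer": float(np.log(1.32)),
    "metastatic_ca": float(np.log(1.46)),
    "opioids": float(np.log(1.62)),
    "hyperkalaemia": float(np.log(2.38)),
}

TABLE_NAMES = (
    "admissions", "diagnoses", "dispensings", "labs", "prior_admissions",
    "outcomes", "ground_truth",
)

_BASE_DATE = pd.Timestamp("2016-12-01")
_STUDY_DAYS = 700  # admissions spread over Dec 2016 - Nov 2018

_OPIOID_ATCS = ("N02AA01", "N02AA05", "N02AB03", "N02AX02")
_DECOY_ATCS = ("A02BC02", "C07AB02", "N02BE01", "B01AC06")
_NOISE_ICD10 = ("Z511", "J189", "N390", "M169", "R51")


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_patients: int = 5985
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    log_odds_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS_RATIOS))
    target_par_rate: float = 0.057
    intercept: float | None = None          # calibrated when None
    missing_potassium_rate: float = 0.072
    missing_dispensing_rate: float = 0.015
    death_rate: float = 0.05
    transfer_rate: float = 0.10
    non_swiss_rate: float = 0.03
    ineligible_rate: float = 0.05           # under-65 or <48 h stays
    predictor_correlation: float = 0.0      # exchangeable latent correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in PREDICTOR_NAMES:
            if name not in self.prevalence:
                raise ValueError(f"prevalence missing for predictor {name!r}")
            if not 0.0 <= self.prevalence[name] <= 1.0:
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        rates = (self.missing_potassium_rate, self.missing_dispensing_rate,
                 self.death_rate, self.transfer_rate, self.non_swiss_rate,
                 self.ineligible_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if not -1.0 / (len(PREDICTOR_NAMES) - 1) < self.predictor_correlation < 1.0:
            raise ValueError("predictor_correlation outside the valid range")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.log_odds_ratios[p] for p in PREDICTOR_NAMES])

    @property
    def prevalence_vector(self) -> np.ndarray:
        return np.array([self.prevalence[p] for p in PREDICTOR_NAMES])


# ---------------------------------------------------------------------------
# Outcome-model calibration
# ---------------------------------------------------------------------------


def expected_event_rate(cfg: CohortConfig, intercept: float) -> float:
    """Exact marginal event probability under independent predictors.

    Enumerates all 2^12 flag combinations with their product probabilities;
    with a non-zero predictor correlation this is an independence
    approximation (the correlation hook only perturbs the joint draw).
    """
    prev = cfg.prevalence_vector
    beta = cfg.beta
    combos = np.array(list(itertools.product((0, 1), repeat=len(prev))), float)
    weights = np.prod(np.where(combos == 1, prev, 1.0 - prev), axis=1)
    return float(weights @ expit(intercept + combos @ beta))


def calibrate_intercept(cfg: CohortConfig, target_rate: float) -> float:
    """Intercept at which the marginal event rate equals ``target_rate``.

    Solved by root bracketing on the analytic expectation; the returned
    intercept reproduces the target to within 1e-4 in rate.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly in (0, 1)")
    if np.allclose(cfg.beta, 0.0):
        return float(logit(target_rate))
    alpha = brentq(
        lambda a: expected_event_rate(cfg, a) - target_rate, -30.0, 10.0,
        xtol=1e-6,
    )
    return float(alpha)


# ---------------------------------------------------------------------------
# Flag and outcome draws (fast path, no record materialisation)
# ---------------------------------------------------------------------------


def draw_flags(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw an (n, 12) boolean flag matrix at the configured prevalences.

    With ``predictor_correlation`` > 0 the flags are thresholded from an
    exchangeable-correlation Gaussian copula, preserving the marginals.
    """
    prev = cfg.prevalence_vector
    if cfg.predictor_correlation == 0.0:
        return rng.random((n, len(prev))) < prev
    rho = cfg.predictor_correlation
    k = len(prev)
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, k))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique
    return z < norm.ppf(prev)


# ---------------------------------------------------------------------------
# Full cohort generation
# ---------------------------------------------------------------------------


def _materialise_code(prefix: str, rng: np.random.Generator) -> str:
    """A concrete ICD-10 code beginning with the given prefix."""
    code = prefix
    while len(code) < 3:
        code += str(rng.integers(0, 10))
    if len(code) == 3:
        code += str(rng.integers(0, 10))
    return code


def generate_cohort(
    cfg: CohortConfig,
    comorbidity_map: ComorbidityMap | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate the raw tables plus ground truth for one synthetic cohort.

    Returns a dict of DataFrames keyed by :data:`TABLE_NAMES`.  The first
    ``cfg.n_patients`` patients survive inclusion and exclusion; appended
    records violate one rule each (first matching reason recorded in the
    ground truth) at the configured rates.
    """
    cmap = comorbidity_map or bundled_comorbidity_map()
    for name in COMORBIDITY_PREDICTORS:
        if name not in cmap.prefixes:
            raise ValueError(f"comorbidity map lacks predictor {name!r}")
    rng = np.random.default_rng(cfg.seed)

    n_clean = cfg.n_patients
    extras = {
        "death": int(round(cfg.death_rate * n_clean)),
        "transfer": int(round(cfg.transfer_rate * n_clean)),
        "non_swiss": int(round(cfg.non_swiss_rate * n_clean)),
        "dispensing_missing": int(round(cfg.missing_dispensing_rate * n_clean)),
        "not_included": int(round(cfg.ineligible_rate * n_clean)),
    }
    n_total = n_clean + sum(extras.values())

    reasons = np.array([""] * n_clean
                       + [r for r, k in extras.items() for _ in range(k)],
                       dtype=object)

    flags = draw_flags(cfg, rng, n_total)
    names = list(PREDICTOR_NAMES)
    idx = {p: j for j, p in enumerate(names)}

    # potassium missingness forces the hyperkalaemia flag off (values are
    # assumed not missing at random, i.e. normal)
    k_missing = rng.random(n_total) < cfg.missing_potassium_rate
    flags[k_missing, idx["hyperkalaemia"]] = False

    # ineligible extras get short stays; keep the LOS flag truthful
    ineligible = reasons == "not_included"
    short_stay = ineligible & (rng.random(n_total) < 0.5)
    young = ineligible & ~short_stay
    flags[short_stay, idx["los_gt4"]] = False

    alpha = cfg.intercept
    if alpha is None:
        alpha = calibrate_intercept(cfg, cfg.target_par_rate)
    true_prob = expit(alpha + flags.astype(float) @ cfg.beta)
    y = rng.binomial(1, true_prob)

    # --- admissions ---------------------------------------------------------
    patient_ids = np.array([f"P{i:06d}" for i in range(1, n_total + 1)])
    adm_minutes = rng.integers(0, _STUDY_DAYS * 24 * 60, n_total)
    los_hours = np.where(
        flags[:, idx["los_gt4"]],
        97 + np.floor(rng.exponential(115.0, n_total)),
        rng.integers(48, 97, n_total).astype(float),
    )
    los_hours = np.minimum(los_hours, 24.0 * 90)
    los_hours[short_stay] = rng.integers(24, 48, int(short_stay.sum())).astype(float)

    age = np.maximum(65, np.round(rng.normal(79.7, 7.7, n_total))).astype(int)
    age[young] = rng.integers(40, 65, int(young.sum()))
    sex = np.where(rng.random(n_total) < 0.469, "M", "F")

    residency = np.where(reasons == "non_swiss", "non-Swiss", "Swiss")
    disposition = np.full(n_total, "home", dtype=object)
    disposition[reasons == "death"] = "death"
    disposition[reasons == "transfer"] = "transfer"
    disp_missing = reasons == "dispensing_missing"

    admission_ts = _BASE_DATE + pd.to_timedelta(adm_minutes, unit="m")
    discharge_ts = admission_ts + pd.to_timedelta(los_hours, unit="h")

    admissions = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": age,
            "sex": sex,
            "admission_ts": admission_ts,
            "discharge_ts": discharge_ts,
            "residency": residency,
            "disposition": disposition,
            "dispensing_available": ~disp_missing,
        }
    )

    # --- nested record tables ----------------------------------------------
    diag_rows: list[tuple[str, str]] = []
    disp_rows: list[tuple[str, str, pd.Timestamp]] = []
    lab_rows: list[tuple[str, str, float, pd.Timestamp]] = []
    prior_rows: list[tuple[str, pd.Timestamp]] = []

    for i in range(n_total):
        pid = patient_ids[i]
        adm, dis = admission_ts[i], discharge_ts[i]
        stay_h = los_hours[i]

        for name in COMORBIDITY_PREDICTORS:
            if flags[i, idx[name]]:
                prefix = cmap.prefixes[name][
                    rng.integers(0, len(cmap.prefixes[name]))
                ]
                diag_rows.append((pid, _materialise_code(prefix, rng)))
        if rng.random() < 0.5:
            diag_rows.append(
                (pid, _NOISE_ICD10[rng.integers(0, len(_NOISE_ICD10))])
            )

        if not disp_missing[i]:
            if flags[i, idx["opioids"]]:
                ts = adm + pd.Timedelta(hours=float(rng.uniform(0, stay_h)))
                disp_rows.append(
                    (pid, _OPIOID_ATCS[rng.integers(0, len(_OPIOID_ATCS))],
                     ts.floor("min"))
                )
            elif rng.random() < 0.05:
                # pre-admission opioid: must not flag
                ts = adm - pd.Timedelta(days=float(rng.uniform(1, 30)))
                disp_rows.append((pid, "N02AA01", ts.floor("min")))
            if rng.random() < 0.6:
                ts = adm + pd.Timedelta(hours=float(rng.uniform(0, stay_h)))
                disp_rows.append(
                    (pid, _DECOY_ATCS[rng.integers(0, len(_DECOY_ATCS))],
                     ts.floor("min"))
                )

        if not k_missing[i]:
            stay_days = stay_h / 24.0
            if flags[i, idx["hyperkalaemia"]]:
                high = float(rng.uniform(5.6, 6.8))
                if stay_days > 9 and rng.random() < 0.2:
                    # high value only before the 7-day window: the flag must
                    # come from the carry-forward rule, so no later draws
                    back = float(rng.uniform(7.5, min(stay_days, 30.0)))
                    ts = dis - pd.Timedelta(days=back)
                    lab_rows.append((pid, "potassium", round(high, 2),
                                     ts.floor("min")))
                else:
                    back = float(rng.uniform(0.0, min(7.0, stay_days)))
                    ts = dis - pd.Timedelta(days=back)
                    lab_rows.append((pid, "potassium", round(high, 2),
                                     ts.floor("min")))
            else:
                for _ in range(int(rng.integers(1, 3))):
                    back = float(rng.uniform(0.0, stay_days))
                    ts = dis - pd.Timedelta(days=back)
                    lab_rows.append(
                        (pid, "potassium", round(float(rng.uniform(3.4, 5.0)), 2),
                         ts.floor("min"))
                    )

        if flags[i, idx["prior_adm_6m"]]:
            back = float(rng.uniform(1.0, 183.0))
            prior_rows.append((pid, (adm - pd.Timedelta(days=back)).floor("min")))
        elif rng.random() < 0.3:
            # stale prior admission outside the six-month window
            back = float(rng.uniform(200.0, 400.0))
            prior_rows.append((pid, (adm - pd.Timedelta(days=back)).floor("min")))

    diagnoses = pd.DataFrame(diag_rows, columns=["patient_id", "icd10_code"])
    dispensings = pd.DataFrame(
        disp_rows, columns=["patient_id", "atc_code", "dispense_ts"]
    )
    labs = pd.DataFrame(
        lab_rows, columns=["patient_id", "analyte", "value", "draw_ts"]
    )
    labs.insert(3, "unit", "mmol/L")
    priors = pd.DataFrame(prior_rows, columns=["patient_id", "prior_discharge_ts"])

    outcomes = pd.DataFrame({"patient_id": patient_ids, "par": y})

    ground_truth = pd.DataFrame(flags, columns=names)
    ground_truth.insert(0, "patient_id", patient_ids)
    ground_truth["potassium_missing"] = k_missing
    ground_truth["dispensing_missing"] = disp_missing
    ground_truth["true_prob"] = np.round(true_prob, 6)
    ground_truth["par"] = y
    ground_truth["exclusion_reason"] = reasons

    return {
        "admissions": admissions,
        "diagnoses": diagnoses,
        "dispensings": dispensings,
        "labs": labs,
        "prior_admissions": priors,
        "outcomes": outcomes,
        "ground_truth": ground_truth,
    }


def write_cohort(tables: dict[str, pd.DataFrame], directory: str | Path) -> None:
    """Write the generated tables as CSV with ISO-8601 timestamps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(directory / f"{name}.csv", index=False)
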