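"""Synthetic registry/claims cohort with known ground truth.

Generates a linked questionnaire + dispensing-claims dataset emulating a
national inflammatory-arthritis registry joined to subsidised-prescription
claims: ~3,400 participants followed for up to 11 years, questionnaires
6-monthly for the first two years of participation then annually,
per-medication exposure episodes with class-specific refill intervals
(monthly oral csDMARDs through 6-monthly infusions), four-level and
checkbox status questions, and a parameterised reporting-error process
whose covariate effects (planted odds ratios) are exactly the quantities
the discordance-predictor stage estimates.

The generator also emits ground truth (exposure episodes, true statuses,
perturbation flags) and a brute-force truth labeller used as the oracle
for the classification pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit, logit

from .classify import (
    CHECKED,
    CURRENT,
    DONT_KNOW,
    NEVER,
    STOPPED,
    UNCHECKED,
    MedicationDefinition,
)

#: Questionnaire-level covariates used by the predictor stage.
COVARIATE_COLUMNS = (
    "age",
    "female",
    "tertiary_education",
    "married",
    "current_smoker",
    "disease_duration",
    "ses_percentile",
    "depressed_anxious",
    "pain",
    "self_rated_health",
    "haq_score",
    "online_modality",
)

_EPOCH = date(1970, 1, 1)


def _day(d: date) -> int:
    return (d - _EPOCH).days


def _from_day(days: np.ndarray) -> pd.Series:
    return pd.Series(pd.to_datetime(days, unit="D", origin="unix")).dt.normalize()


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class ReportErrorModel(BaseModel):
    """Logistic reporting-error process at the questionnaire x medication
    level.

    A true-positive-status report is flipped to a negative with
    probability expit(logit(base_fn) + x'beta) and a true-negative-status
    report to "current"/checked with probability
    expit(logit(base_fp) + x'beta); ``effects`` maps covariate column
    names to log odds ratios (the planted effects).  Four-level questions
    are additionally answered "don't know" with ``dont_know_prob``,
    independent of the error process.
    """

    base_fp: float = Field(default=0.02, ge=0.0, le=1.0)
    base_fn: float = Field(default=0.05, ge=0.0, le=1.0)
    effects: dict[str, float] = Field(default_factory=dict)
    dont_know_prob: float = Field(default=0.01, ge=0.0, le=1.0)
    stop_date_prob: float = Field(default=0.8, ge=0.0, le=1.0)

    @field_validator("effects")
    @classmethod
    def _known_covariates(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariate(s) in error model: {sorted(unknown)}")
        return v


class CohortConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    Defaults follow the emulated registry: 3,400 participants,
    questionnaires January 2012 - June 2023 (6-monthly for two years,
    then annual), claims available from one year before the first
    questionnaire.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_participants: int = Field(default=3400, gt=0)
    study_start: date = date(2012, 1, 1)
    study_end: date = date(2023, 6, 30)
    claims_lead_days: int = Field(default=365, ge=0)
    dropout_mean_years: float = Field(default=8.0, gt=0.0)
    medication_catalogue: list[MedicationDefinition] = Field(default_factory=lambda: default_catalogue())
    prevalence: dict[str, float] = Field(default_factory=dict)
    claims_capture: dict[str, float] = Field(default_factory=dict)
    refill_jitter: float = Field(default=0.25, ge=0.0, lt=1.0)
    error_model: ReportErrorModel = Field(default_factory=ReportErrorModel)
    covariate_missing_prob: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for med_id, p in {**self.prevalence, **self.claims_capture}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {med_id!r} outside [0, 1]: {p}")
        return self

    def medication(self, med_id: str) -> MedicationDefinition:
        for m in self.medication_catalogue:
            if m.medication_id == med_id:
                return m
        raise KeyError(med_id)


# default usage prevalence and claims-capture probability per catalogue
# medication; OTC-available medicines have low capture (private and
# over-the-counter supply invisible to subsidised claims)
_DEFAULTS: dict[str, tuple[float, float]] = {
    "methotrexate_oral": (0.45, 1.0),
    "methotrexate_inj": (0.06, 1.0),
    "hydroxychloroquine": (0.18, 1.0),
    "sulfasalazine": (0.12, 1.0),
    "etanercept": (0.22, 1.0),
    "infliximab": (0.04, 1.0),
    "rituximab": (0.03, 0.85),
    "tofacitinib": (0.05, 1.0),
    "prednisolone": (0.30, 0.90),
    "oxycodone": (0.08, 0.90),
    "celecoxib": (0.10, 0.95),
    "paracetamol": (0.35, 0.35),
}

# claims codes emitted for each default medication: (ATC level-5, item code)
_EMIT_CODES: dict[str, tuple[str, str]] = {
    "methotrexate_oral": ("L04AX03", "162201"),
    "methotrexate_inj": ("L04AX03", "107563"),
    "hydroxychloroquine": ("P01BA02", "201101"),
    "sulfasalazine": ("A07EC01", "201102"),
    "etanercept": ("L04AB01", "201103"),
    "infliximab": ("L04AB02", "201104"),
    "rituximab": ("L01XC02", "201105"),
    "tofacitinib": ("L04AA29", "201106"),
    "prednisolone": ("H02AB06", "201107"),
    "oxycodone": ("N02AA05", "201108"),
    "celecoxib": ("M01AH01", "201109"),
    "paracetamol": ("N02BE01", "201110"),
}


def default_catalogue() -> list[MedicationDefinition]:
    """Twelve-medication catalogue spanning the five questionnaire
    classes, with dosing-realistic refill intervals.  Oral and injectable
    methotrexate share an ATC code and are discriminated by item code;
    tofacitinib carries a mid-study subsidy listing date."""

    def med(mid, name, cls, q, mode, codes, refill, presc=True, lfrom=None, lto=None):
        return MedicationDefinition(
            medication_id=mid, display_name=name, med_class=cls,
            prescription_only=presc, question_type=q, match_mode=mode,
            codes=frozenset(codes), listed_from=lfrom, listed_to=lto,
            refill_interval_days=refill,
        )

    return [
        med("methotrexate_oral", "Methotrexate (oral)", "csDMARD", "four_level",
            "item_code", {"162201"}, 30),
        med("methotrexate_inj", "Methotrexate (injection)", "csDMARD", "four_level",
            "item_code", {"107563"}, 30),
        med("hydroxychloroquine", "Hydroxychloroquine", "csDMARD", "four_level",
            "atc7", {"P01BA02"}, 60),
        med("sulfasalazine", "Sulfasalazine", "csDMARD", "four_level",
            "atc7", {"A07EC01"}, 45),
        med("etanercept", "Etanercept", "btsDMARD", "four_level",
            "atc7", {"L04AB01"}, 30),
        med("infliximab", "Infliximab", "btsDMARD", "four_level",
            "atc7", {"L04AB02"}, 56),
        med("rituximab", "Rituximab", "btsDMARD", "four_level",
            "atc7", {"L01XC02"}, 182),
        med("tofacitinib", "Tofacitinib citrate", "btsDMARD", "four_level",
            "atc7", {"L04AA29"}, 30, lfrom=date(2015, 10, 1)),
        med("prednisolone", "Prednisolone/prednisone", "glucocorticoid", "four_level",
            "atc7", {"H02AB06"}, 60),
        med("oxycodone", "Oxycodone", "opioid_analgesic", "checkbox",
            "atc7", {"N02AA05"}, 45),
        med("celecoxib", "Celecoxib", "nonopioid_analgesic", "checkbox",
            "atc7", {"M01AH01"}, 45),
        med("paracetamol", "Paracetamol", "nonopioid_analgesic", "checkbox",
            "atc7", {"N02BE01"}, 60, presc=False),
    ]


@dataclass
class GroundTruth:
    """True exposure and report-level truth for a synthetic cohort.

    ``episodes``: participant_id, medication_id, episode_start,
    episode_end.  ``labels``: report_id, true_status, perturbed (the
    emitted status differs from the true one due to the error process),
    dont_know (overridden to "don't know").
    """

    episodes: pd.DataFrame
    labels: pd.DataFrame


@dataclass
class SyntheticCohort:
    """Generated questionnaire, covariate and claims tables plus truth."""

    questionnaires: pd.DataFrame
    covariates: pd.DataFrame
    claims: pd.DataFrame
    medications: dict[str, MedicationDefinition]
    truth: GroundTruth
    config: CohortConfig

    def table_hash(self) -> str:
        """SHA-256 over the emitted CSV text of all three tables
        (determinism check: identical seed => identical hash)."""
        h = hashlib.sha256()
        for df in (self.questionnaires, self.covariates, self.claims):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _questionnaire_offsets(followup_days: int) -> np.ndarray:
    """Offsets (days since enrolment): 6-monthly to two years, then annual."""
    first = np.arange(0, min(followup_days, 728) + 1, 182)
    if followup_days < 910:
        return first
    annual = np.arange(1093, followup_days + 1, 365)
    return np.concatenate([first, annual])


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a linked questionnaire + claims cohort.

    Identical configuration (including seed) yields byte-identical
    tables.  Returns a :class:`SyntheticCohort`.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)
    try:
        config = CohortConfig.model_validate(config)
    except Exception as exc:  # pydantic ValidationError -> domain error
        raise ConfigurationError(str(exc)) from exc

    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    start_day = _day(config.study_start)
    end_day = _day(config.study_end)
    claims_start_day = start_day - config.claims_lead_days

    # --- participants ------------------------------------------------------
    pid = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    enrol = rng.integers(start_day, end_day + 1, size=n)
    followup = np.minimum(
        end_day - enrol,
        np.round(rng.exponential(config.dropout_mean_years * 365.25, size=n)).astype(np.int64),
    )
    age0 = np.clip(rng.normal(55.1, 14.4, size=n), 18.0, 95.0)
    female = rng.random(n) < 0.671
    tertiary = rng.random(n) < 0.50
    married = rng.random(n) < 0.65
    smoker = rng.random(n) < 0.12
    duration0 = np.clip(rng.normal(15.9, 11.2, size=n), 0.0, None)
    ses = rng.uniform(1.0, 100.0, size=n)
    frailty = rng.normal(0.0, 1.0, size=n)

    # --- questionnaire schedule -------------------------------------------
    q_pid_idx, q_day = [], []
    for i in range(n):
        offs = _questionnaire_offsets(int(followup[i]))
        q_pid_idx.append(np.full(offs.size, i))
        q_day.append(enrol[i] + offs)
    q_pid_idx = np.concatenate(q_pid_idx)
    q_day = np.concatenate(q_day).astype(np.int64)
    nq = q_day.size

    # --- per-questionnaire covariates (HAQ / VAS / pain share one latent
    # health factor; everything else independent) ---------------------------
    g = 0.7 * frailty[q_pid_idx] + 0.7 * rng.normal(0.0, 1.0, size=nq)
    elapsed = (q_day - enrol[q_pid_idx]) / 365.25
    cov = pd.DataFrame({
        "participant_id": pid[q_pid_idx],
        "questionnaire_date": _from_day(q_day).values,
        "age": np.round(age0[q_pid_idx] + elapsed, 1),
        "female": female[q_pid_idx].astype(int),
        "tertiary_education": tertiary[q_pid_idx].astype(int),
        "married": married[q_pid_idx].astype(int),
        "current_smoker": smoker[q_pid_idx].astype(int),
        "disease_duration": np.round(duration0[q_pid_idx] + elapsed, 1),
        "ses_percentile": np.round(ses[q_pid_idx], 1),
        "depressed_anxious": (rng.random(nq) < expit(-1.0 + 0.8 * g)).astype(int),
        "pain": (rng.random(nq) < expit(0.8 + 1.2 * g)).astype(int),
        "self_rated_health": np.round(np.clip(70.0 - 12.0 * g + rng.normal(0.0, 8.0, size=nq), 0.0, 100.0), 0),
        "haq_score": np.round(np.clip(0.9 + 0.55 * g + rng.normal(0.0, 0.25, size=nq), 0.0, 3.0), 2),
        "online_modality": (rng.random(nq) < 0.69).astype(int),
    })

    # error-model linear predictor shared across medications
    lp = np.zeros(nq)
    for name, beta in config.error_model.effects.items():
        lp += beta * cov[name].to_numpy(dtype=float)

    # --- per-medication exposure, claims and reports -----------------------
    meds = {m.medication_id: m for m in config.medication_catalogue}
    q_frames, claim_frames, episode_frames, label_frames = [], [], [], []
    report_id0 = 0
    for med in config.medication_catalogue:
        prev = config.prevalence.get(med.medication_id, _DEFAULTS.get(med.medication_id, (0.10, 1.0))[0])
        capture = config.claims_capture.get(med.medication_id, _DEFAULTS.get(med.medication_id, (0.10, 1.0))[1])
        atc_emit, item_emit = _EMIT_CODES.get(med.medication_id, (sorted(med.codes)[0], "999999")) \
            if med.match_mode == "atc7" else _EMIT_CODES.get(med.medication_id, ("Z99ZZ99", sorted(med.codes)[0]))

        user = rng.random(n) < prev
        ep_start = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
        ep_end = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
        idx = np.flatnonzero(user)
        if idx.size:
            s = rng.integers(start_day - 730, np.maximum(enrol[idx] + followup[idx], start_day - 729))
            dur = 90 + np.round(rng.exponential(1095.0, size=idx.size)).astype(np.int64)
            ep_start[idx] = s
            ep_end[idx] = s + dur
            episode_frames.append(pd.DataFrame({
                "participant_id": pid[idx],
                "medication_id": med.medication_id,
                "episode_start": _from_day(ep_start[idx]).values,
                "episode_end": _from_day(ep_end[idx]).values,
            }))

            # dispensings: one supply per refill interval, jittered, within
            # the episode and the claims extraction period
            supply_stop = np.minimum(ep_end[idx], end_day)
            kmax = np.maximum(((supply_stop - ep_start[idx]) //
                               max(1, int(med.refill_interval_days * (1 - config.refill_jitter)))) + 1, 1)
            reps = kmax.astype(np.int64)
            total = int(reps.sum())
            gaps = med.refill_interval_days * rng.uniform(1 - config.refill_jitter, 1 + config.refill_jitter, size=total)
            seg = np.repeat(np.arange(idx.size), reps)
            csum = np.cumsum(gaps)
            seg_first = np.concatenate([[0], np.cumsum(reps)[:-1]])
            csum = csum - np.repeat(csum[seg_first] - gaps[seg_first], reps)  # restart cumsum per user
            days = ep_start[idx][seg] + np.round(csum - gaps[seg_first][seg]).astype(np.int64)
            keep = (days <= supply_stop[seg]) & (days >= claims_start_day) & (days <= end_day)
            keep &= rng.random(total) < capture
            if keep.any():
                claim_frames.append(pd.DataFrame({
                    "participant_id": pid[idx][seg[keep]],
                    "supply_date": _from_day(days[keep]).values,
                    "atc_code": atc_emit,
                    "item_code": item_emit,
                }))

        # --- true status at each questionnaire ----------------------------
        s_all, e_all = ep_start[q_pid_idx], ep_end[q_pid_idx]
        true_status = np.where(
            q_day < s_all, NEVER, np.where(q_day <= e_all, CURRENT, STOPPED)
        )
        is_pos = true_status == CURRENT

        # --- reporting errors ----------------------------------------------
        base = np.where(is_pos, config.error_model.base_fn, config.error_model.base_fp)
        with np.errstate(divide="ignore"):
            p_err = np.where(base <= 0.0, 0.0, np.where(base >= 1.0, 1.0, expit(logit(np.clip(base, 1e-12, 1 - 1e-12)) + lp)))
        err = rng.random(nq) < p_err
        emitted = true_status.copy()
        emitted[err & is_pos] = STOPPED  # under-report: claims continue => discordant
        emitted[err & ~is_pos] = CURRENT  # over-report

        # stop dates: reported for a fraction of genuine "stopped" reports,
        # dated at or shortly after the true episode end; erroneous
        # "stopped" reports carry no stop date
        stop_date = np.full(nq, np.datetime64("NaT"), dtype="datetime64[ns]")
        genuine_stop = (emitted == STOPPED) & ~err
        emit_stop = genuine_stop & (rng.random(nq) < config.error_model.stop_date_prob)
        if emit_stop.any():
            lag = rng.integers(0, 6, size=int(emit_stop.sum()))
            stop_date[emit_stop] = _from_day(e_all[emit_stop] + lag).values

        # four-level "don't know" overrides; checkbox semantics
        dont_know = np.zeros(nq, dtype=bool)
        if med.question_type == "four_level":
            dont_know = rng.random(nq) < config.error_model.dont_know_prob
            emitted = np.where(dont_know, DONT_KNOW, emitted)
            stop_date[dont_know] = np.datetime64("NaT")
        else:
            emitted = np.where(np.isin(emitted, [CURRENT]), CHECKED, UNCHECKED)
            stop_date[:] = np.datetime64("NaT")

        rids = np.arange(report_id0, report_id0 + nq, dtype=np.int64)
        report_id0 += nq
        q_frames.append(pd.DataFrame({
            "report_id": rids,
            "participant_id": pid[q_pid_idx],
            "questionnaire_date": _from_day(q_day).values,
            "modality": np.where(cov["online_modality"].to_numpy(dtype=bool), "online", "paper"),
            "medication_id": med.medication_id,
            "status": emitted,
            "stop_date": stop_date,
        }))
        label_frames.append(pd.DataFrame({
            "report_id": rids,
            "medication_id": med.medication_id,
            "true_status": np.where(
                (med.question_type == "checkbox") & np.ones(nq, dtype=bool),
                np.where(is_pos, CHECKED, UNCHECKED),
                true_status,
            ),
            "perturbed": err & ~dont_know,
            "dont_know": dont_know,
        }))

    questionnaires = pd.concat(q_frames, ignore_index=True)
    for c in ("free_text_1", "free_text_2", "free_text_3", "free_text_4", "free_text_5"):
        questionnaires[c] = ""
    claims = (
        pd.concat(claim_frames, ignore_index=True)
        .sort_values(["participant_id", "supply_date", "atc_code", "item_code"], kind="stable")
        .reset_index(drop=True)
        if claim_frames else
        pd.DataFrame(columns=["participant_id", "supply_date", "atc_code", "item_code"])
    )

    # covariate missingness: a random covariate blanked on a fraction of
    # questionnaires (drives the complete-case reduction downstream)
    if config.covariate_missing_prob > 0:
        hit = rng.random(nq) < config.covariate_missing_prob
        which = rng.integers(0, len(COVARIATE_COLUMNS), size=nq)
        cov = cov.copy()
        for j, name in enumerate(COVARIATE_COLUMNS):
            m = hit & (which == j)
            if m.any():
                cov[name] = cov[name].astype(float)
                cov.loc[m, name] = np.nan

    truth = GroundTruth(
        episodes=(pd.concat(episode_frames, ignore_index=True) if episode_frames
                  else pd.DataFrame(columns=["participant_id", "medication_id", "episode_start", "episode_end"])),
        labels=pd.concat(label_frames, ignore_index=True),
    )
    return SyntheticCohort(
        questionnaires=questionnaires,
        covariates=cov,
        claims=claims,
        medications=meds,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Brute-force truth labeller (classification oracle)
# ---------------------------------------------------------------------------

def emit_truth_labels(
    cohort: SyntheticCohort,
    window_days: int,
    *,
    never_with_dispensing: str = "fn",
) -> pd.Series:
    """Validity label per report by naive scan of all dispensings.

    Independent of the vectorised pipeline: for each report, every claims
    row of the participant is checked for a code match and window
    containment with plain date comparisons, then the classification
    rules are applied literally.  Returns a Series indexed by report_id.
    Unknown report ids raise KeyError via normal indexing downstream.
    """
    claims_by_pid: dict[str, list[tuple[date, str, str]]] = {}
    for row in cohort.claims.itertuples(index=False):
        claims_by_pid.setdefault(row.participant_id, []).append(
            (row.supply_date.date(), row.atc_code, row.item_code)
        )
    out = {}
    for row in cohort.questionnaires.itertuples(index=False):
        med = cohort.medications[row.medication_id]
        qd = row.questionnaire_date.date()
        lo = qd - timedelta(days=window_days)
        matches = []
        for (sd, atc, item) in claims_by_pid.get(row.participant_id, []):
            code = atc if med.match_mode == "atc7" else item
            if code in med.codes and lo <= sd <= qd:
                matches.append(sd)
        status = row.status
        if med.listed_from is not None and qd < med.listed_from:
            label = "excluded"
        elif med.listed_to is not None and qd > med.listed_to:
            label = "excluded"
        elif status == DONT_KNOW:
            label = "excluded"
        elif status in (CURRENT, CHECKED):
            label = "TP" if matches else "FP"
        elif not matches:
            label = "TN"
        elif status == STOPPED:
            if pd.isna(row.stop_date):
                label = "FN"
            else:
                sd0 = row.stop_date.date()
                label = "TN" if all(m <= sd0 for m in matches) else "FN"
        else:  # never / unchecked with a dispensing in window
            label = "FN" if never_with_dispensing == "fn" else "excluded"
        out[row.report_id] = label
    return pd.Series(out, name=f"truth_{window_days}d")


# ---------------------------------------------------------------------------
# Direct predictor-frame simulator (null / planted-effect experiments)
# ---------------------------------------------------------------------------

def simulate_predictor_frame(
    n: int,
    effects: Mapping[str, float] | None = None,
    base_rate: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a questionnaire-level predictor frame directly.

    Covariates are drawn from the same marginal model as the cohort
    generator; the discordance outcome is Bernoulli with
    logit P = logit(base_rate) + x'beta.  With ``effects`` empty this is
    an all-null simulation for false-discovery-rate experiments.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame({
        "age": np.clip(rng.normal(55.1, 14.4, size=n), 18.0, 95.0),
        "female": (rng.random(n) < 0.671).astype(int),
        "tertiary_education": (rng.random(n) < 0.50).astype(int),
        "married": (rng.random(n) < 0.65).astype(int),
        "current_smoker": (rng.random(n) < 0.12).astype(int),
        "disease_duration": np.clip(rng.normal(15.9, 11.2, size=n), 0.0, None),
        "ses_percentile": rng.uniform(1.0, 100.0, size=n),
        "depressed_anxious": (rng.random(n) < expit(-1.0 + 0.8 * g)).astype(int),
        "pain": (rng.random(n) < expit(0.8 + 1.2 * g)).astype(int),
        "self_rated_health": np.clip(70.0 - 12.0 * g + rng.normal(0.0, 8.0, size=n), 0.0, 100.0),
        "haq_score": np.clip(0.9 + 0.55 * g + rng.normal(0.0, 0.25, size=n), 0.0, 3.0),
        "online_modality": (rng.random(n) < 0.69).astype(int),
    })
    lp = np.full(n, logit(base_rate))
    for name, beta in (effects or {}).items():
        lp += beta * (df[name].to_numpy(dtype=float) - df[name].mean())
    df["discordant"] = (rng.random(n) < expit(lp)).astype(int)
    return df
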