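"""CSV schemas, run configuration, logging and pipeline orchestration.

The pipeline reads four CSV inputs — questionnaires, claims, a
medication definition map and an optional free-text recode table — and
writes the agreement outputs (one row per medication at its optimal
window, plus a long-format all-windows table) and the predictor outputs
(multivariable and univariate-screen tables).  All dates are ISO-8601,
encodings UTF-8, missing values empty fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import agreement, classify, predictors as predictors_mod
from .classify import (
    ATC7_PATTERN,
    STANDARD_WINDOWS,
    MedicationDefinition,
    ValidationError,
    canonical_status,
)
from .synthetic import COVARIATE_COLUMNS

QUESTIONNAIRE_COLUMNS = [
    "participant_id", "questionnaire_date", "modality", "medication_id",
    "status", "stop_date",
    "free_text_1", "free_text_2", "free_text_3", "free_text_4", "free_text_5",
]
CLAIMS_COLUMNS = ["participant_id", "supply_date", "atc_code", "item_code"]
MEDICATIONS_COLUMNS = [
    "medication_id", "display_name", "med_class", "prescription_only",
    "question_type", "match_mode", "codes", "listed_from", "listed_to",
    "refill_interval_days",
]
RECODES_COLUMNS = ["token", "medication_id", "target_status"]


class SchemaError(ValueError):
    """Input file violates the schema; carries per-row messages."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        preview = "; ".join(problems[:5])
        more = f" (+{len(problems) - 5} more)" if len(problems) > 5 else ""
        super().__init__(f"{path}: {len(problems)} invalid row(s): {preview}{more}")


class RunConfig(BaseModel):
    """One reproducible pipeline run."""

    questionnaires: Path
    claims: Path
    medications: Path
    recodes: Path | None = None
    covariates: Path | None = None
    output_dir: Path = Path("medagree_output")
    windows: list[int] = Field(default_factory=lambda: [30, 90, 182, 365])
    rounding_digits: int = Field(default=2, ge=0)
    never_with_dispensing: str = "fn"
    univariate_entry_threshold: float = 0.05
    bh_alpha: float = 0.05
    bh_scope: str = "per_medication"
    seed: int = 0

    @field_validator("windows")
    @classmethod
    def _windows_ok(cls, v: list[int]) -> list[int]:
        if len(set(v)) != len(v) or any(w <= 0 for w in v):
            raise ValueError("windows must be positive and unique")
        return v

    @field_validator("univariate_entry_threshold", "bh_alpha")
    @classmethod
    def _thresholds_ok(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)

    def lookback_windows(self) -> list[classify.LookbackWindow]:
        return [
            classify.WINDOW_BY_DAYS.get(d, classify.LookbackWindow(f"{d}d", d))
            for d in sorted(self.windows)
        ]


@dataclass
class RunLog:
    """Plain-text + JSON-lines run log with row accounting."""

    path: Path | None = None
    events: list[dict] = field(default_factory=list)

    def record(self, event: str, **payload) -> None:
        entry = {"event": event, **payload}
        self.events.append(entry)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry, default=str) + "\n")

    def counts(self) -> dict:
        return {e["event"]: e for e in self.events}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing column(s): {missing}"])


def _parse_dates(df: pd.DataFrame, col: str, problems: list[str], required: bool) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    raw = df[col].astype(str).str.strip()
    bad = parsed.isna() & (raw.ne("") & raw.ne("nan") if not required else True)
    for i in df.index[bad]:
        problems.append(f"line {i + 2}: malformed {col} {df[col][i]!r}")
    return parsed


def read_medications(path) -> dict[str, MedicationDefinition]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, MEDICATIONS_COLUMNS, path)
    problems: list[str] = []
    out: dict[str, MedicationDefinition] = {}
    for i, row in df.iterrows():
        try:
            codes = frozenset(c.strip() for c in str(row["codes"]).split(";") if c.strip())
            out[row["medication_id"]] = MedicationDefinition(
                medication_id=row["medication_id"],
                display_name=row["display_name"],
                med_class=row["med_class"],
                prescription_only=str(row["prescription_only"]).strip().lower() in ("true", "yes", "1"),
                question_type=str(row["question_type"]).strip(),
                match_mode=str(row["match_mode"]).strip(),
                codes=codes,
                listed_from=_opt_date(row.get("listed_from")),
                listed_to=_opt_date(row.get("listed_to")),
                refill_interval_days=int(float(row["refill_interval_days"] or 30)),
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {i + 2}: {exc}")
    if problems:
        raise SchemaError(path, problems)
    return out


def _opt_date(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() in ("", "nan", "NaT"):
        return None
    return pd.Timestamp(value).date()


def read_questionnaires(path, medications: dict[str, MedicationDefinition]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, QUESTIONNAIRE_COLUMNS[:6], path)
    problems: list[str] = []
    df["questionnaire_date"] = _parse_dates(df, "questionnaire_date", problems, required=True)
    if "stop_date" in df.columns:
        df["stop_date"] = _parse_dates(df, "stop_date", problems, required=False)
    statuses = []
    for i, row in df.iterrows():
        med = medications.get(row["medication_id"])
        if med is None:
            problems.append(f"line {i + 2}: unknown medication_id {row['medication_id']!r}")
            statuses.append(None)
            continue
        raw = str(row["status"]).strip()
        if raw == "":
            statuses.append(None)  # missing status -> excluded downstream
            continue
        try:
            status = canonical_status(raw)
            if status not in med.allowed_statuses:
                raise ValidationError(
                    f"status {status!r} invalid for {med.question_type} question {med.medication_id!r}")
            statuses.append(status)
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {i + 2}: {exc}")
            statuses.append(None)
    if problems:
        raise SchemaError(path, problems)
    df["status"] = statuses
    return df


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, CLAIMS_COLUMNS, path)
    problems: list[str] = []
    df["supply_date"] = _parse_dates(df, "supply_date", problems, required=True)
    bad_atc = ~df["atc_code"].astype(str).str.match(ATC7_PATTERN)
    for i in df.index[bad_atc]:
        problems.append(f"line {i + 2}: malformed ATC code {df['atc_code'][i]!r}")
    if problems:
        raise SchemaError(path, problems)
    return df


def read_recodes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, RECODES_COLUMNS, path)
    return df


def read_inputs(config: RunConfig):
    """Load and validate all configured input tables."""
    medications = read_medications(config.medications)
    questionnaires = read_questionnaires(config.questionnaires, medications)
    claims = read_claims(config.claims)
    recodes = read_recodes(config.recodes) if config.recodes else None
    covariates = pd.read_csv(config.covariates, parse_dates=["questionnaire_date"]) \
        if config.covariates else None
    return questionnaires, claims, medications, recodes, covariates


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def run_validation(config: RunConfig, log: RunLog | None = None):
    """Classification + agreement stage.

    Writes ``agreement_optimal.csv`` (one row per medication at its
    optimal window) and ``agreement_all_windows.csv`` to the output
    directory and returns the in-memory results.
    """
    log = log or RunLog()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if log.path is None:
        log.path = out_dir / "run_log.jsonl"
    log.record("config", **json.loads(config.model_dump_json()))

    questionnaires, claims, medications, recodes, _ = read_inputs(config)
    log.record("loaded", questionnaires=len(questionnaires), claims=len(claims),
               medications=len(medications))

    if recodes is not None:
        questionnaires, recode_log = classify.apply_recode_table(questionnaires, recodes, medications)
        log.record("recodes_applied", total=recode_log.total, per_medication=recode_log.counts)

    study_start = questionnaires["questionnaire_date"].min()
    study_end = questionnaires["questionnaire_date"].max()
    dropped = [m for m in medications.values()
               if (m.listed_from is not None and pd.Timestamp(m.listed_from) > study_end)
               or (m.listed_to is not None and pd.Timestamp(m.listed_to) < study_start)]
    for med in dropped:
        log.record("medication_dropped", medication_id=med.medication_id,
                   reason="no listing overlap with study period")
    analysed = {k: v for k, v in medications.items() if v not in dropped}
    questionnaires = questionnaires[questionnaires["medication_id"].isin(analysed)]

    windows = config.lookback_windows()
    classified = classify.classify_reports(
        questionnaires, claims, analysed, windows,
        never_with_dispensing=config.never_with_dispensing,
    )
    reasons = classified.loc[classified["excluded_reason"] != "", "excluded_reason"]
    log.record("classified", reports=len(classified),
               excluded_pre_window=reasons.value_counts().to_dict())

    results = agreement.agreement_by_medication(classified, windows)
    long_frame = agreement.results_frame(results, analysed)
    optimal_frame = agreement.results_frame(results, analysed, optimal_only=True)
    nd = config.rounding_digits
    for frame in (long_frame, optimal_frame):
        for col in frame.columns:
            if frame[col].dtype == float:
                frame[col] = frame[col].map(lambda x: agreement.round_half_up(x, nd))
    long_frame.to_csv(out_dir / "agreement_all_windows.csv", index=False)
    optimal_frame.to_csv(out_dir / "agreement_optimal.csv", index=False)
    log.record("agreement_written", medications=len(results))
    return classified, results, log


def run_predictors(config: RunConfig, classified=None, results=None, covariates=None, log: RunLog | None = None):
    """Discordance-predictor stage (requires the validation stage's
    optimal windows).  Writes ``predictors_multivariable.csv`` and
    ``predictors_univariate.csv``."""
    log = log or RunLog()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if classified is None or results is None:
        classified, results, log = run_validation(config, log)
    if covariates is None:
        if config.covariates is None:
            raise ValidationError("predictor stage needs a covariates table")
        covariates = pd.read_csv(config.covariates, parse_dates=["questionnaire_date"])

    medications = read_medications(config.medications)
    frames: dict[str, pd.DataFrame] = {}
    for med_id, per_window in results.items():
        med = medications.get(med_id)
        if med is not None and not med.prescription_only:
            log.record("predictor_skip", medication_id=med_id, reason="not prescription-only")
            continue
        optimal = [w for w, r in per_window.items() if r.is_optimal_window]
        if not optimal:
            log.record("predictor_skip", medication_id=med_id, reason="no defined kappa")
            continue
        col = f"validity_{optimal[0].label}"
        sub = classified[classified["medication_id"] == med_id]
        frames[med_id] = predictors_mod.build_predictor_frame(sub, covariates, col)
        log.record("predictor_frame", medication_id=med_id, rows=len(frames[med_id]),
                   discordant=int(frames[med_id]["discordant"].sum()))

    reports = predictors_mod.run_predictor_stage(
        frames,
        entry_threshold=config.univariate_entry_threshold,
        alpha=config.bh_alpha,
        bh_scope=config.bh_scope,
    )
    for rep in reports:
        if not rep.eligible:
            log.record("predictor_excluded", medication_id=rep.medication_id,
                       reason=rep.exclusion_reason)
        elif not rep.multivariable:
            log.record("predictor_no_selection", medication_id=rep.medication_id,
                       note="no significant univariate predictors")
    multi = predictors_mod.predictor_results_frame(reports, "multivariable")
    uni = predictors_mod.predictor_results_frame(reports, "univariate")
    multi.to_csv(out_dir / "predictors_multivariable.csv", index=False)
    uni.to_csv(out_dir / "predictors_univariate.csv", index=False)
    log.record("predictors_written", medications=len(reports))
    return reports, log


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort to the pipeline's input CSV schemas."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q = cohort.questionnaires.copy()
    q["questionnaire_date"] = q["questionnaire_date"].dt.strftime("%Y-%m-%d")
    q["stop_date"] = pd.to_datetime(q["stop_date"]).dt.strftime("%Y-%m-%d").fillna("")
    paths = {}
    paths["questionnaires"] = out_dir / "questionnaires.csv"
    q[["participant_id", "questionnaire_date", "modality", "medication_id", "status",
       "stop_date", "free_text_1", "free_text_2", "free_text_3", "free_text_4",
       "free_text_5"]].to_csv(paths["questionnaires"], index=False)
    c = cohort.claims.copy()
    c["supply_date"] = pd.to_datetime(c["supply_date"]).dt.strftime("%Y-%m-%d")
    paths["claims"] = out_dir / "claims.csv"
    c.to_csv(paths["claims"], index=False)
    m_rows = []
    for m in cohort.medications.values():
        m_rows.append({
            "medication_id": m.medication_id, "display_name": m.display_name,
            "med_class": m.med_class, "prescription_only": m.prescription_only,
            "question_type": m.question_type, "match_mode": m.match_mode,
            "codes": ";".join(sorted(m.codes)),
            "listed_from": m.listed_from or "", "listed_to": m.listed_to or "",
            "refill_interval_days": m.refill_interval_days,
        })
    paths["medications"] = out_dir / "medications.csv"
    pd.DataFrame(m_rows).to_csv(paths["medications"], index=False)
    cov = cohort.covariates.copy()
    cov["questionnaire_date"] = pd.to_datetime(cov["questionnaire_date"]).dt.strftime("%Y-%m-%d")
    paths["covariates"] = out_dir / "covariates.csv"
    cov.to_csv(paths["covariates"], index=False)
    return paths
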