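"""Exposure classification: match medication self-reports to dispensing claims.

Each questionnaire self-report of a medication is compared against the
participant's prescription-dispensing claims inside a look-back window
ending on the questionnaire date, and assigned a validity class
(TP / TN / FP / FN / excluded).  Matching is by 7-character WHO ATC
level-5 code, or by dispensing item code where the questionnaire item is
finer-grained than its ATC grouping (e.g. oral vs injectable
methotrexate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Statuses and validity classes
# ---------------------------------------------------------------------------

# four-level (radio/dropdown) statuses
NEVER = "never"
CURRENT = "current"
STOPPED = "stopped"
DONT_KNOW = "dont_know"
# checkbox statuses
CHECKED = "checked"
UNCHECKED = "unchecked"

FOUR_LEVEL_STATUSES = frozenset({NEVER, CURRENT, STOPPED, DONT_KNOW})
CHECKBOX_STATUSES = frozenset({CHECKED, UNCHECKED})
POSITIVE_STATUSES = frozenset({CURRENT, CHECKED})
NEGATIVE_STATUSES = frozenset({NEVER, STOPPED, UNCHECKED})

TP, TN, FP, FN, EXCLUDED = "TP", "TN", "FP", "FN", "excluded"
VALIDITY_CLASSES = (TP, TN, FP, FN, EXCLUDED)

ATC7_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

_CANONICAL_STATUS = {
    "never": NEVER, "never taken": NEVER,
    "current": CURRENT, "currently taking": CURRENT,
    "stopped": STOPPED, "stopped taking": STOPPED,
    "dont_know": DONT_KNOW, "don't know": DONT_KNOW, "dont know": DONT_KNOW,
    "checked": CHECKED, "unchecked": UNCHECKED,
}


def canonical_status(raw: str) -> str:
    """Normalise a raw status string; raises ValueError for unknown values."""
    key = str(raw).strip().lower()
    try:
        return _CANONICAL_STATUS[key]
    except KeyError:
        raise ValueError(f"unknown medication status {raw!r}") from None


class ValidationError(ValueError):
    """A record violates the schema or a status/question-type constraint."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LookbackWindow:
    """A claims look-back window preceding the questionnaire date."""

    label: str
    days: int

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValidationError(f"window length must be positive, got {self.days}")


#: The four standard windows: 1, 3, 6 and 12 months.
WINDOW_1MO = LookbackWindow("1mo", 30)
WINDOW_3MO = LookbackWindow("3mo", 90)
WINDOW_6MO = LookbackWindow("6mo", 182)
WINDOW_12MO = LookbackWindow("12mo", 365)
STANDARD_WINDOWS: tuple[LookbackWindow, ...] = (
    WINDOW_1MO, WINDOW_3MO, WINDOW_6MO, WINDOW_12MO,
)
WINDOW_BY_DAYS = {w.days: w for w in STANDARD_WINDOWS}
WINDOW_BY_LABEL = {w.label: w for w in STANDARD_WINDOWS}


@dataclass(frozen=True)
class SelfReportRecord:
    """One questionnaire's status for one medication."""

    participant_id: str
    questionnaire_date: date
    medication_id: str
    status: str
    stop_date: date | None = None
    modality: str = "online"

    def __post_init__(self) -> None:
        if self.stop_date is not None and self.status != STOPPED:
            raise ValidationError(
                f"stop_date only allowed with status 'stopped', got {self.status!r}"
            )


@dataclass(frozen=True)
class DispensingRecord:
    """One claims row: a single subsidised supply of a medication."""

    participant_id: str
    supply_date: date
    atc_code: str
    item_code: str

    def __post_init__(self) -> None:
        if not ATC7_PATTERN.match(self.atc_code):
            raise ValidationError(f"malformed ATC level-5 code {self.atc_code!r}")


@dataclass(frozen=True)
class MedicationDefinition:
    """Catalogue entry mapping one questionnaire item to claims codes."""

    medication_id: str
    display_name: str
    med_class: str  # csDMARD | btsDMARD | opioid_analgesic | nonopioid_analgesic | glucocorticoid
    prescription_only: bool
    question_type: str  # four_level | checkbox
    match_mode: str  # atc7 | item_code
    codes: frozenset[str]
    listed_from: date | None = None
    listed_to: date | None = None
    refill_interval_days: int = 30  # synthetic use only

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValidationError(f"{self.medication_id}: codes must be nonempty")
        if self.question_type not in ("four_level", "checkbox"):
            raise ValidationError(f"bad question_type {self.question_type!r}")
        if self.match_mode not in ("atc7", "item_code"):
            raise ValidationError(f"bad match_mode {self.match_mode!r}")
        if self.refill_interval_days < 1:
            raise ValidationError("refill_interval_days must be >= 1")

    @property
    def allowed_statuses(self) -> frozenset[str]:
        return FOUR_LEVEL_STATUSES if self.question_type == "four_level" else CHECKBOX_STATUSES


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_dispensings(
    report: SelfReportRecord,
    claims: Iterable[DispensingRecord],
    med: MedicationDefinition,
    window: LookbackWindow,
) -> list[date]:
    """Supply dates for ``med`` within the look-back window of a report.

    A supply matches when its code (ATC or item code per the medication's
    match mode) belongs to the medication's code set and its date d
    satisfies  questionnaire_date - window.days <= d <= questionnaire_date
    (both boundaries inclusive; a same-day supply counts).
    """
    lo = report.questionnaire_date - pd.Timedelta(days=window.days)
    lo = lo.date() if hasattr(lo, "date") else lo
    hi = report.questionnaire_date
    out = []
    for c in claims:
        if c.participant_id != report.participant_id:
            continue
        code = c.atc_code if med.match_mode == "atc7" else c.item_code
        if code in med.codes and lo <= c.supply_date <= hi:
            out.append(c.supply_date)
    out.sort()
    return out


def classify_self_report(
    report: SelfReportRecord,
    matches: Sequence[date],
    *,
    never_with_dispensing: str = "fn",
) -> str:
    """Assign a validity class to one self-report given its matched supplies.

    Rules (current-use validation against claims):

    * positive report (current / checked) -> TP with >=1 match, FP otherwise;
    * "don't know" -> excluded from agreement analysis;
    * negative report (never / stopped / unchecked) with no match -> TN;
    * "stopped" with matches and a reported stop date -> TN when every
      matched supply is on or before the stop date, FN when any supply
      post-dates it;
    * "stopped" with matches but no stop date -> FN (the stop-date carve-out
      applies only when a stop date was reported);
    * "never"/"unchecked" with a match -> FN by default; set
      ``never_with_dispensing="excluded"`` to drop such reports instead.
    """
    if never_with_dispensing not in ("fn", "excluded"):
        raise ValidationError(f"bad never_with_dispensing policy {never_with_dispensing!r}")
    status = report.status
    has_match = len(matches) > 0
    if status == DONT_KNOW:
        return EXCLUDED
    if status in POSITIVE_STATUSES:
        return TP if has_match else FP
    if status in NEGATIVE_STATUSES:
        if not has_match:
            return TN
        if status == STOPPED:
            if report.stop_date is None:
                return FN
            return TN if all(d <= report.stop_date for d in matches) else FN
        # never / unchecked with a dispensing in window
        return FN if never_with_dispensing == "fn" else EXCLUDED
    raise ValidationError(f"unknown status {status!r}")


# ---------------------------------------------------------------------------
# Vectorised cohort classification
# ---------------------------------------------------------------------------

_EPOCH = np.datetime64("1970-01-01")


def _day_numbers(dates: pd.Series) -> np.ndarray:
    return ((pd.to_datetime(dates).values - _EPOCH) / np.timedelta64(1, "D")).astype(np.int64)


def classify_reports(
    questionnaires: pd.DataFrame,
    claims: pd.DataFrame,
    medications: Mapping[str, MedicationDefinition],
    windows: Sequence[LookbackWindow] = STANDARD_WINDOWS,
    *,
    never_with_dispensing: str = "fn",
) -> pd.DataFrame:
    """Classify every self-report row at every look-back window.

    ``questionnaires`` is long-format (one row per questionnaire x
    medication) with columns participant_id, questionnaire_date,
    medication_id, status, stop_date.  Returns a copy with one
    ``validity_<label>`` column per window and an ``excluded_reason``
    column (missing-status and listing-period exclusions apply uniformly
    across windows).

    Implements the same rules as :func:`classify_self_report`, vectorised
    with sorted-array bisection per medication.
    """
    if never_with_dispensing not in ("fn", "excluded"):
        raise ValidationError(f"bad never_with_dispensing policy {never_with_dispensing!r}")
    q = questionnaires.copy()
    q["questionnaire_date"] = pd.to_datetime(q["questionnaire_date"])
    if "stop_date" in q.columns:
        q["stop_date"] = pd.to_datetime(q["stop_date"])
    else:
        q["stop_date"] = pd.NaT
    claims = claims.copy()
    claims["supply_date"] = pd.to_datetime(claims["supply_date"])

    # participant encoding shared by reports and claims
    pids = pd.Index(pd.unique(pd.concat([q["participant_id"], claims["participant_id"]])))
    q_pid = pids.get_indexer(q["participant_id"]).astype(np.int64)
    c_pid = pids.get_indexer(claims["participant_id"]).astype(np.int64)
    q_day = _day_numbers(q["questionnaire_date"])
    c_day = _day_numbers(claims["supply_date"])
    stop_day = np.where(
        q["stop_date"].notna(), _day_numbers(q["stop_date"].fillna(pd.Timestamp(0))), np.int64(-(10**9))
    )
    # composite sort key: participant block, then day
    span = max(int(c_day.max(initial=0)), int(q_day.max(initial=0))) + 2
    base = max(-int(c_day.min(initial=0)), -int(q_day.min(initial=0)), 0) + 1
    stride = np.int64(span + base + 2)

    status = q["status"].astype(str)
    missing = q["status"].isna() | (status == "") | (status == "nan")
    excluded_reason = np.where(missing, "missing_status", "").astype(object)

    for w in windows:
        q[f"validity_{w.label}"] = ""

    for med_id, med in medications.items():
        sel = (q["medication_id"] == med_id).to_numpy()
        if not sel.any():
            continue
        code_col = "atc_code" if med.match_mode == "atc7" else "item_code"
        cmask = claims[code_col].isin(med.codes).to_numpy()
        keys = (c_pid[cmask] * stride + c_day[cmask] + base)
        keys.sort()

        s = status[sel]
        qd = q_day[sel]
        sd = stop_day[sel]
        pk = q_pid[sel] * stride + base
        hi = np.searchsorted(keys, pk + qd, side="right")
        m_missing = missing.to_numpy()[sel]

        # listing-period exclusions
        listed = np.ones(sel.sum(), dtype=bool)
        if med.listed_from is not None:
            listed &= qd >= (np.datetime64(med.listed_from) - _EPOCH) / np.timedelta64(1, "D")
        if med.listed_to is not None:
            listed &= qd <= (np.datetime64(med.listed_to) - _EPOCH) / np.timedelta64(1, "D")
        reason = excluded_reason[sel]
        reason = np.where(~listed & (reason == ""), "outside_listing_period", reason)
        excluded_reason[sel] = reason

        is_pos = s.isin(POSITIVE_STATUSES).to_numpy()
        is_neg = s.isin(NEGATIVE_STATUSES).to_numpy()
        is_stop = (s == STOPPED).to_numpy()
        is_dk = (s == DONT_KNOW).to_numpy()
        has_stop_date = sd > -(10**8)

        for w in windows:
            lo = np.searchsorted(keys, pk + qd - w.days, side="left")
            nmatch = hi - lo
            has_match = nmatch > 0
            # supplies in window strictly after the reported stop date
            after_stop = hi - np.maximum(lo, np.searchsorted(keys, pk + sd, side="right"))
            never_label = FN if never_with_dispensing == "fn" else EXCLUDED
            label = np.select(
                [
                    m_missing | ~listed,
                    is_dk,
                    is_pos & has_match,
                    is_pos,
                    is_neg & ~has_match,
                    is_stop & has_stop_date & (after_stop == 0),
                    is_stop,
                    is_neg,  # never/unchecked with a match
                ],
                [EXCLUDED, EXCLUDED, TP, FP, TN, TN, FN, never_label],
                default=EXCLUDED,
            )
            q.loc[sel, f"validity_{w.label}"] = label

    q["excluded_reason"] = excluded_reason
    return q


# ---------------------------------------------------------------------------
# Free-text recodes and listing filter
# ---------------------------------------------------------------------------

FREE_TEXT_COLUMNS = tuple(f"free_text_{i}" for i in range(1, 6))


def _normalise_token(tok: str) -> str:
    return re.sub(r"\s+", " ", str(tok).strip().lower())


@dataclass
class RecodeLog:
    """Audit of free-text overrides applied per medication."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, medication_id: str, n: int = 1) -> None:
        self.counts[medication_id] = self.counts.get(medication_id, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def apply_recode_table(
    reports: pd.DataFrame,
    recodes: pd.DataFrame,
    medications: Mapping[str, MedicationDefinition],
) -> tuple[pd.DataFrame, RecodeLog]:
    """Override negative structured statuses named in free-text fields.

    ``recodes`` maps a normalised free-text token to (medication_id,
    target_status).  Where a questionnaire's free text names a medication
    whose structured status is negative or absent, the status is overridden
    to the target positive status.  Reports already positive are left
    unchanged; overrides are counted per medication.
    """
    log = RecodeLog()
    if recodes is None or len(recodes) == 0:
        return reports.copy(), log
    bad = set(recodes["medication_id"]) - set(medications)
    if bad:
        raise ValidationError(f"recode table references unknown medication(s): {sorted(bad)}")
    token_map: dict[str, tuple[str, str]] = {}
    for row in recodes.itertuples(index=False):
        token_map[_normalise_token(row.token)] = (row.medication_id, canonical_status(row.target_status))

    out = reports.copy()
    text_cols = [c for c in FREE_TEXT_COLUMNS if c in out.columns]
    if not text_cols:
        return out, log

    # free text is per questionnaire; gather named medications per (pid, date)
    per_q = out.drop_duplicates(["participant_id", "questionnaire_date"])[
        ["participant_id", "questionnaire_date", *text_cols]
    ]
    hits: dict[tuple, dict[str, str]] = {}
    for row in per_q.itertuples(index=False):
        named = {}
        for c in text_cols:
            tok = getattr(row, c)
            if pd.isna(tok) or str(tok).strip() == "":
                continue
            hit = token_map.get(_normalise_token(tok))
            if hit is not None:
                named[hit[0]] = hit[1]
        if named:
            hits[(row.participant_id, row.questionnaire_date)] = named

    if not hits:
        return out, log
    key = list(zip(out["participant_id"], out["questionnaire_date"]))
    for i, (k, med_id) in enumerate(zip(key, out["medication_id"])):
        named = hits.get(k)
        if not named or med_id not in named:
            continue
        cur = out.iat[i, out.columns.get_loc("status")]
        if pd.isna(cur) or canonical_status(cur) in NEGATIVE_STATUSES or cur == "":
            out.iat[i, out.columns.get_loc("status")] = named[med_id]
            log.add(med_id)
    return out, log


def filter_by_listing(
    reports: pd.DataFrame,
    med: MedicationDefinition,
    study_start: date | None = None,
    study_end: date | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Apply subsidy-listing-period rules for one medication.

    Returns ``(reports, dropped)``.  Reports dated outside the listing
    period get ``excluded_reason="outside_listing_period"`` (they cannot
    become false positives).  When the listing period has no overlap with
    the study period at all, the medication is dropped from the analysis
    set entirely and ``dropped`` is True.
    """
    sub = reports[reports["medication_id"] == med.medication_id].copy()
    if study_start is not None and med.listed_from is not None and med.listed_from > study_end:
        return sub.iloc[0:0], True
    if study_end is not None and med.listed_to is not None and med.listed_to < study_start:
        return sub.iloc[0:0], True
    qd = pd.to_datetime(sub["questionnaire_date"])
    ok = pd.Series(True, index=sub.index)
    if med.listed_from is not None:
        ok &= qd >= pd.Timestamp(med.listed_from)
    if med.listed_to is not None:
        ok &= qd <= pd.Timestamp(med.listed_to)
    if "excluded_reason" not in sub.columns:
        sub["excluded_reason"] = ""
    sub.loc[~ok & (sub["excluded_reason"] == ""), "excluded_reason"] = "outside_listing_period"
    return sub, False
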