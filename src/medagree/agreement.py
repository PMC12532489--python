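"""Agreement metrics for self-report vs dispensing claims.

Builds per-medication 2x2 contingency tables per look-back window and
computes unadjusted Cohen's kappa, sensitivity, PPV and NPV with 95%
confidence intervals; selects the optimal look-back window (highest
kappa, ties broken by sensitivity then by shortest window); and bands
kappa on the conventional poor/fair/moderate/substantial/high scale.

Kappa CIs use the large-sample asymptotic standard error
``sqrt(p_o (1 - p_o) / (n (1 - p_e)^2))`` truncated to [-1, 1];
proportion CIs are exact Clopper-Pearson intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    EXCLUDED,
    FN,
    FP,
    STANDARD_WINDOWS,
    TN,
    TP,
    LookbackWindow,
)

Z975 = float(stats.norm.ppf(0.975))

KAPPA_BANDS = (  # upper bound (inclusive) -> band; >0.80 is "high"
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "high"),
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as in published tables."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class EmptyTableError(ValueError):
    """Raised when a contingency table has no classifiable reports."""


@dataclass(frozen=True)
class ContingencyTable:
    """TP/TN/FP/FN/excluded tallies for one medication at one window."""

    tp: int
    tn: int
    fp: int
    fn: int
    excluded: int = 0
    medication_id: str = ""
    window: LookbackWindow | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def total(self) -> int:
        return self.n + self.excluded


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI; ``defined`` is False when the
    denominator is empty (the estimate is then NaN, never 0)."""

    value: float
    ci_lo: float
    ci_hi: float
    defined: bool = True


@dataclass
class AgreementResult:
    """All agreement metrics for one medication at one window."""

    medication_id: str
    window: LookbackWindow
    table: ContingencyTable
    kappa: MetricEstimate
    sensitivity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    band: str | None
    is_optimal_window: bool = False


def build_contingency(
    validity: Sequence[str] | pd.Series,
    medication_id: str = "",
    window: LookbackWindow | None = None,
) -> ContingencyTable:
    """Tally validity classes into a contingency table.

    Raises :class:`EmptyTableError` when no reports are supplied.
    """
    v = pd.Series(list(validity))
    if len(v) == 0:
        raise EmptyTableError(f"no reports to tally for {medication_id!r}")
    counts = v.value_counts()
    return ContingencyTable(
        tp=int(counts.get(TP, 0)),
        tn=int(counts.get(TN, 0)),
        fp=int(counts.get(FP, 0)),
        fn=int(counts.get(FN, 0)),
        excluded=int(counts.get(EXCLUDED, 0)),
        medication_id=medication_id,
        window=window,
    )


def cohens_kappa(table: ContingencyTable) -> MetricEstimate:
    """Unadjusted Cohen's kappa with an asymptotic 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with
    p_o = (tp + tn) / n and
    p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n^2.

    When both raters are constant and agree perfectly (p_o = p_e = 1)
    kappa is 1 by convention.  A degenerate table where one rater is
    constant but agreement is imperfect has no meaningful chance
    correction and is flagged undefined.
    """
    n = table.n
    if n == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    tp, tn, fp, fn = table.tp, table.tn, table.fp, table.fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe == 1.0:
        if po == 1.0:
            return MetricEstimate(1.0, 1.0, 1.0)
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    margins = (tp + fp, tp + fn, fn + tn, fp + tn)
    if 0 in margins and po < 1.0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return MetricEstimate(kappa, max(-1.0, kappa - Z975 * se), min(1.0, kappa + Z975 * se))


def _clopper_pearson(x: int, n: int) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    lo = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))
    return MetricEstimate(x / n, lo, hi)


def diagnostic_metrics(
    table: ContingencyTable,
) -> tuple[MetricEstimate, MetricEstimate, MetricEstimate]:
    """Sensitivity tp/(tp+fn), PPV tp/(tp+fp) and NPV tn/(tn+fn) with
    exact (Clopper-Pearson) 95% CIs.  A zero denominator yields an
    undefined estimate, never 0."""
    sens = _clopper_pearson(table.tp, table.tp + table.fn)
    ppv = _clopper_pearson(table.tp, table.tp + table.fp)
    npv = _clopper_pearson(table.tn, table.tn + table.fn)
    return sens, ppv, npv


def classify_kappa_band(kappa: float) -> str:
    """Band a kappa: <=0.20 poor; 0.21-0.40 fair; 0.41-0.60 moderate;
    0.61-0.80 substantial; >0.80 high."""
    if not (-1.0 - 1e-12 <= kappa <= 1.0 + 1e-12):
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    for hi, band in KAPPA_BANDS:
        if kappa <= hi + 1e-15:
            return band
    return "high"


def compute_agreement(
    table: ContingencyTable,
) -> AgreementResult:
    """All four agreement metrics plus the kappa band for one table."""
    k = cohens_kappa(table)
    sens, ppv, npv = diagnostic_metrics(table)
    band = classify_kappa_band(k.value) if k.defined else None
    return AgreementResult(
        medication_id=table.medication_id,
        window=table.window,
        table=table,
        kappa=k,
        sensitivity=sens,
        ppv=ppv,
        npv=npv,
        band=band,
    )


def select_optimal_window(results: Mapping[LookbackWindow, AgreementResult]) -> LookbackWindow:
    """The window with the highest (unrounded) kappa; ties broken by the
    highest sensitivity, remaining ties by the shortest window."""
    candidates = [(w, r) for w, r in results.items() if r.kappa.defined]
    if not candidates:
        raise ValueError("kappa undefined at every window")

    def key(item):
        w, r = item
        sens = r.sensitivity.value if r.sensitivity.defined else -math.inf
        return (-r.kappa.value, -sens, w.days)

    return min(candidates, key=key)[0]


# ---------------------------------------------------------------------------
# Cohort-level driver and published reference counts
# ---------------------------------------------------------------------------

def agreement_by_medication(
    classified: pd.DataFrame,
    windows: Sequence[LookbackWindow] = STANDARD_WINDOWS,
) -> dict[str, dict[LookbackWindow, AgreementResult]]:
    """Agreement results for every medication x window in a classified
    cohort (output of :func:`medagree.classify.classify_reports`)."""
    out: dict[str, dict[LookbackWindow, AgreementResult]] = {}
    for med_id, grp in classified.groupby("medication_id", sort=True):
        per_window = {}
        for w in windows:
            table = build_contingency(grp[f"validity_{w.label}"], med_id, w)
            per_window[w] = compute_agreement(table)
        try:
            best = select_optimal_window(per_window)
            per_window[best].is_optimal_window = True
        except ValueError:
            pass
        out[str(med_id)] = per_window
    return out


def _fmt(est: MetricEstimate, nd: int = 2) -> str:
    if not est.defined:
        return "undefined"
    return f"{round_half_up(est.value, nd)} ({round_half_up(est.ci_lo, nd)}-{round_half_up(est.ci_hi, nd)})"


def results_frame(
    results: dict[str, dict[LookbackWindow, AgreementResult]],
    medications: Mapping | None = None,
    *,
    optimal_only: bool = False,
) -> pd.DataFrame:
    """Flatten agreement results into a table, one row per medication x
    window (or only the optimal window per medication)."""
    rows = []
    for med_id, per_window in results.items():
        med = medications.get(med_id) if medications else None
        for w, r in sorted(per_window.items(), key=lambda kv: kv[0].days):
            if optimal_only and not r.is_optimal_window:
                continue
            t = r.table
            rows.append({
                "medication_id": med_id,
                "display_name": getattr(med, "display_name", med_id),
                "med_class": getattr(med, "med_class", ""),
                "prescription_only": getattr(med, "prescription_only", ""),
                "window_label": w.label,
                "window_days": w.days,
                "tn": t.tn, "fn": t.fn, "fp": t.fp, "tp": t.tp,
                "excluded": t.excluded,
                "kappa": r.kappa.value, "kappa_lo": r.kappa.ci_lo, "kappa_hi": r.kappa.ci_hi,
                "sensitivity": r.sensitivity.value,
                "sensitivity_lo": r.sensitivity.ci_lo, "sensitivity_hi": r.sensitivity.ci_hi,
                "ppv": r.ppv.value, "ppv_lo": r.ppv.ci_lo, "ppv_hi": r.ppv.ci_hi,
                "npv": r.npv.value, "npv_lo": r.npv.ci_lo, "npv_hi": r.npv.ci_hi,
                "kappa_band": r.band,
                "is_optimal_window": r.is_optimal_window,
            })
    return pd.DataFrame(rows)


def load_reference_counts() -> pd.DataFrame:
    """Published per-medication contingency counts and agreement metrics.

    Bundled reference table from a published validation of medication
    self-report against Australian PBS dispensing claims in an
    inflammatory arthritis registry cohort (35 medications at their
    optimal look-back windows; counts plus the printed kappa /
    sensitivity / PPV / NPV point estimates and 95% CIs at 2 decimals).
    Used for cross-checking the metric implementations and as a worked
    example.
    """
    with resources.files("medagree.data").joinpath("reference_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    int_cols = ["tn", "fn", "fp", "tp", "excluded", "optimal_window_months"]
    df[int_cols] = df[int_cols].astype(int)
    return df


def recompute_reference_metrics() -> pd.DataFrame:
    """Recompute kappa/sensitivity/PPV/NPV from the published counts and
    return them side by side with the printed values (full precision in
    ``*_calc`` columns)."""
    ref = load_reference_counts()
    recs = []
    for row in ref.itertuples(index=False):
        t = ContingencyTable(tp=row.tp, tn=row.tn, fp=row.fp, fn=row.fn,
                             excluded=row.excluded, medication_id=row.medication_id)
        r = compute_agreement(t)
        recs.append({
            "medication_id": row.medication_id,
            "kappa_calc": r.kappa.value,
            "kappa_lo_calc": r.kappa.ci_lo, "kappa_hi_calc": r.kappa.ci_hi,
            "sensitivity_calc": r.sensitivity.value,
            "sensitivity_lo_calc": r.sensitivity.ci_lo, "sensitivity_hi_calc": r.sensitivity.ci_hi,
            "ppv_calc": r.ppv.value, "ppv_lo_calc": r.ppv.ci_lo, "ppv_hi_calc": r.ppv.ci_hi,
            "npv_calc": r.npv.value, "npv_lo_calc": r.npv.ci_lo, "npv_hi_calc": r.npv.ci_hi,
        })
    return ref.merge(pd.DataFrame(recs), on="medication_id")
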