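"""Predictors of discordant medication self-report.

A discordant self-report is a false-positive or false-negative
classification at the medication's optimal look-back window.  With the
questionnaire as the unit of analysis, each prescription-only medication
gets a univariate logistic screen over twelve sociodemographic and
health covariates, then a multivariable logistic model over the screen's
significant covariates; multivariable coefficient p-values are adjusted
with the Benjamini-Hochberg step-up procedure (FDR alpha = 0.05) and
odds ratios for dichotomous covariates are banded by conventional
effect-size thresholds (<1.68 very small; 1.68-<3.47 small;
3.47-<6.71 medium; >=6.71 large, reciprocals for ORs below 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .classify import EXCLUDED, FN, FP, TN, TP
from .synthetic import COVARIATE_COLUMNS

#: Covariates treated as dichotomous for eligibility and effect-size banding.
DICHOTOMOUS_COVARIATES = (
    "female",
    "tertiary_education",
    "married",
    "current_smoker",
    "depressed_anxious",
    "pain",
    "online_modality",
)

MIN_CASES = 10  # minimum count of the rarer outcome per dichotomous level

EFFECT_SIZE_THRESHOLDS = ((1.68, "very_small"), (3.47, "small"), (6.71, "medium"))


def flag_discordant(validity: str) -> bool | None:
    """FP or FN -> True; TP or TN -> False; excluded -> None (dropped)."""
    if validity in (FP, FN):
        return True
    if validity in (TP, TN):
        return False
    if validity == EXCLUDED:
        return None
    raise ValueError(f"unknown validity class {validity!r}")


def build_predictor_frame(
    classified: pd.DataFrame,
    covariates: pd.DataFrame,
    validity_column: str,
) -> pd.DataFrame:
    """Questionnaire-level frame for one medication: discordance outcome
    at the optimal window joined to covariates, complete cases only.

    ``classified`` must be restricted to one medication and carry the
    validity class in ``validity_column``; excluded classifications are
    dropped (the outcome is undefined for them), then any row missing a
    covariate is dropped (complete-case analysis).
    """
    keep = classified[classified[validity_column].isin([TP, TN, FP, FN])]
    disc = keep[validity_column].isin([FP, FN]).astype(int)
    frame = keep[["participant_id", "questionnaire_date"]].copy()
    frame["discordant"] = disc.to_numpy()
    merged = frame.merge(
        covariates[["participant_id", "questionnaire_date", *COVARIATE_COLUMNS]],
        on=["participant_id", "questionnaire_date"],
        how="left",
    )
    return merged.dropna(subset=list(COVARIATE_COLUMNS)).reset_index(drop=True)


def eligibility_filter(frame: pd.DataFrame) -> tuple[bool, str | None]:
    """Minimum-case rule for one medication's predictor frame.

    The medication is analyzable only when, for every dichotomous
    covariate, both covariate levels contain at least ``MIN_CASES`` rows
    of the less frequent outcome class.  Returns ``(eligible,
    failing_covariate)``.
    """
    if len(frame) == 0:
        return False, "empty_frame"
    counts = frame["discordant"].value_counts()
    if len(counts) < 2:
        return False, "single_outcome_class"
    rare = counts.idxmin()
    for covariate in DICHOTOMOUS_COVARIATES:
        levels = frame[covariate]
        for level in (0, 1):
            cell = int(((levels == level) & (frame["discordant"] == rare)).sum())
            if cell < MIN_CASES:
                return False, covariate
    return True, None


@dataclass
class PredictorResult:
    """One covariate's estimate from a logistic model."""

    covariate: str
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    p_adjusted: float | None = None
    fdr_significant: bool | None = None
    effect_size: str | None = None
    estimable: bool = True
    note: str = ""


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit | None:
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=100)
        except (PerfectSeparationWarning, np.linalg.LinAlgError, Exception):
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.bse.to_numpy())):
        return None
    return res


def univariate_screen(frame: pd.DataFrame, covariates=COVARIATE_COLUMNS) -> list[PredictorResult]:
    """One single-covariate logistic regression per covariate.

    Constant covariates and fits with separation or non-convergence are
    flagged non-estimable rather than raising.
    """
    y = frame["discordant"].to_numpy(dtype=float)
    out = []
    for name in covariates:
        x = frame[[name]].astype(float)
        if x[name].nunique() < 2:
            out.append(PredictorResult(name, np.nan, np.nan, np.nan, np.nan,
                                       estimable=False, note="constant covariate"))
            continue
        res = _fit_logit(y, x)
        if res is None:
            out.append(PredictorResult(name, np.nan, np.nan, np.nan, np.nan,
                                       estimable=False, note="separation or non-convergence"))
            continue
        beta, se = res.params[name], res.bse[name]
        z = 1.959963984540054
        out.append(PredictorResult(
            name, float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)),
            float(res.pvalues[name]),
        ))
    return out


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (adjusted p-values, significance flags at ``alpha``).
    Adjusted values are monotone non-decreasing in rank and never below
    the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def or_effect_size(or_value: float) -> str:
    """Chen-style effect-size band for an odds ratio (dichotomous
    covariates); ORs below 1 are banded on the reciprocal scale."""
    if not np.isfinite(or_value) or or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    v = or_value if or_value >= 1.0 else 1.0 / or_value
    for hi, band in EFFECT_SIZE_THRESHOLDS:
        if v < hi:
            return band
    return "large"


def multivariable_model(
    frame: pd.DataFrame,
    covariates,
    alpha: float = 0.05,
) -> list[PredictorResult]:
    """Joint logistic model over the selected covariates with BH-adjusted
    coefficient p-values and effect-size bands (dichotomous covariates).

    Returns an empty list when no covariates are supplied; a
    non-converging joint fit yields a single non-estimable marker result.
    """
    covariates = list(covariates)
    if not covariates:
        return []
    y = frame["discordant"].to_numpy(dtype=float)
    res = _fit_logit(y, frame[covariates].astype(float))
    if res is None:
        return [PredictorResult("(model)", np.nan, np.nan, np.nan, np.nan,
                                estimable=False, note="multivariable fit failed")]
    z = 1.959963984540054
    raw_p = np.array([float(res.pvalues[c]) for c in covariates])
    p_adj, flags = bh_adjust(raw_p, alpha=alpha)
    out = []
    for i, name in enumerate(covariates):
        beta, se = float(res.params[name]), float(res.bse[name])
        orv = float(np.exp(beta))
        out.append(PredictorResult(
            name, orv, float(np.exp(beta - z * se)), float(np.exp(beta + z * se)),
            raw_p[i], p_adjusted=float(p_adj[i]), fdr_significant=bool(flags[i]),
            effect_size=or_effect_size(orv) if name in DICHOTOMOUS_COVARIATES else None,
        ))
    return out


@dataclass
class MedicationPredictorReport:
    """Predictor-stage output for one medication."""

    medication_id: str
    eligible: bool
    exclusion_reason: str | None
    n_rows: int
    n_discordant: int
    univariate: list[PredictorResult]
    multivariable: list[PredictorResult]


def run_predictor_stage(
    frames: dict[str, pd.DataFrame],
    *,
    entry_threshold: float = 0.05,
    alpha: float = 0.05,
    bh_scope: str = "per_medication",
) -> list[MedicationPredictorReport]:
    """Univariate screen then multivariable model per medication.

    ``frames`` maps medication_id to its complete-case predictor frame.
    Covariates with raw univariate p below ``entry_threshold`` enter the
    multivariable model.  With ``bh_scope="per_medication"`` (default) BH
    runs within each medication's model; ``bh_scope="across_medications"``
    pools every multivariable coefficient p-value into one BH family.
    """
    if bh_scope not in ("per_medication", "across_medications"):
        raise ValueError(f"bad bh_scope {bh_scope!r}")
    if not (0.0 < entry_threshold < 1.0):
        raise ValueError("entry threshold must lie in (0, 1)")
    reports = []
    for med_id, frame in frames.items():
        eligible, reason = eligibility_filter(frame)
        n_disc = int(frame["discordant"].sum()) if len(frame) else 0
        if not eligible:
            reports.append(MedicationPredictorReport(
                med_id, False, reason, len(frame), n_disc, [], []))
            continue
        uni = univariate_screen(frame)
        selected = [r.covariate for r in uni if r.estimable and r.p_value < entry_threshold]
        multi = multivariable_model(frame, selected, alpha=alpha)
        reports.append(MedicationPredictorReport(
            med_id, True, None, len(frame), n_disc, uni, multi))

    if bh_scope == "across_medications":
        pooled = [(rep, r) for rep in reports for r in rep.multivariable if r.estimable]
        if pooled:
            p_adj, flags = bh_adjust([r.p_value for _, r in pooled], alpha=alpha)
            for (rep, r), pa, fl in zip(pooled, p_adj, flags):
                r.p_adjusted, r.fdr_significant = float(pa), bool(fl)
    return reports


def predictor_results_frame(reports: list[MedicationPredictorReport], stage: str = "multivariable") -> pd.DataFrame:
    """Flatten predictor reports into a medication x covariate table."""
    rows = []
    for rep in reports:
        for r in getattr(rep, stage):
            rows.append({
                "medication_id": rep.medication_id,
                "covariate": r.covariate,
                "odds_ratio": r.odds_ratio,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "fdr_significant": r.fdr_significant,
                "effect_size": r.effect_size,
                "estimable": r.estimable,
                "note": r.note,
            })
    return pd.DataFrame(rows, columns=[
        "medication_id", "covariate", "odds_ratio", "ci_lo", "ci_hi",
        "p_value", "p_adjusted", "fdr_significant", "effect_size",
        "estimable", "note",
    ])
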