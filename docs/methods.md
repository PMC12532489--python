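# Methods

## The validation model

A participant's self-report of *current* use of medication *j* at
questionnaire date *q* is compared with the dispensing record: the report is
claims-confirmed when at least one supply of *j* (matched by 7-character WHO
ATC level-5 code, or by item code where several questionnaire items share an
ATC code) falls in the window `[q − w, q]`.  Both boundaries are inclusive —
a supply on the questionnaire day itself counts, since "before submission"
plausibly includes a same-day fill and excluding it would drop legitimate
day-of-visit dispensings.  Four windows are examined: w ∈ {30, 90, 182, 365}
days (1, 3, 6, 12 months).

Validity classes follow the current-use rules described in the README.  Two
rules deserve justification:

* **"Stopped" with an in-window supply and no reported stop date → FN.**
  The stop-date carve-out (TN when every supply precedes the stop date) only
  applies when a stop date was actually reported; without one the supply
  contradicts the claim of having stopped.  With multiple supplies straddling
  the stop date, any post-stop supply forces FN.
* **"Never taken" with an in-window supply → FN by default.**  The analysis
  validates *current*-use status, so a recent supply contradicts a negative
  current report regardless of the word used for it.  Whether such reports
  should instead be excluded is genuinely ambiguous; the behaviour sits
  behind `never_with_dispensing={"fn","excluded"}` and both settings are
  oracle-tested.

Missing four-level statuses are excluded from that medication's table;
an unchecked checkbox is a negative report (the questionnaire's stated
convention).  Reports dated outside a medication's subsidy-listing period
are excluded (they cannot be false positives when the claims system could
not have recorded a supply); a medication whose listing period does not
overlap the study period at all is dropped from the analysis set.

## Agreement metrics and numerical choices

Cohen's kappa is computed unadjusted from each 2×2 table with the
large-sample standard error `sqrt(p_o(1 − p_o) / (n(1 − p_e)^2))` for its
95% CI, truncated to [−1, 1].  Sensitivity, PPV and NPV carry exact
Clopper–Pearson intervals (scipy beta quantiles).  These two choices jointly
reproduce all 35 rows of the bundled published reference table — point
estimates *and* printed CIs — at two decimals, which is the strongest
available evidence for the (unstated) interval methods behind that table.

* Rounding for display is decimal half-up at 2 dp; all internal comparisons,
  including optimal-window ties, use full precision.
* A table where one rater is constant while agreement is imperfect has no
  meaningful chance correction: κ is flagged undefined (never reported as 0).
  When both raters are constant and agree, κ = 1 by convention.
* Zero-denominator proportions are flagged undefined, never 0.
* Optimal window: argmax κ, ties by max sensitivity, remaining ties by the
  shortest window (verified over all orderings).

## Predictor stage

The unit of analysis is the questionnaire.  Discordance (FP/FN at the
medication's optimal window) is regressed on twelve covariates; continuous
covariates enter untransformed, so ORs are per year / per point / per
percentile.  Complete-case analysis only.  Eligibility requires ≥10 rows of
the rarer outcome class in both levels of every dichotomous covariate.
The univariate entry threshold is raw p < 0.05 (configurable — no published
convention fixes it), and Benjamini–Hochberg runs within each medication's
multivariable model across its covariates (`bh_scope="per_medication"`;
pooling across medications is available as `"across_medications"`).
Separation and non-convergence are flagged per covariate or per model, never
fatal.  OR effect sizes use the Chen bands, with sub-unity ORs banded on the
reciprocal scale.

## What the synthetic generator emulates

Defaults: 3,400 participants, study window 2012-01-01 to 2023-06-30, claims
available from one year earlier, questionnaires 6-monthly for the first two
years of participation then annual, enrollment uniform over the study window
with exponential retention (mean 8 years — yielding a median of 6
questionnaires per participant against the emulated registry's 7),
covariates matched to the emulated cohort's marginals (age 55.1 ± 14.4,
67.1% female, 50% tertiary-educated, disease duration 15.9 ± 11.2 y, SES
percentile uniform on 1–100, 69% online questionnaires).  HAQ, EQ-5D VAS and
EQ-5D pain share one latent "health" factor (their real-world correlation
matters for multivariable estimates); everything else is independent — a
stipulation, since no joint distribution is published.

Each user of a medication (per-medication prevalence defaults between 0.03
and 0.45) gets one exposure episode; supplies are emitted every
`refill_interval_days × U(1 ± 0.25)` inside the episode, each retained with
a per-medication claims-capture probability (1.0 for high-cost specialty
drugs, 0.35 for the over-the-counter analgesic — private/OTC supply is
invisible to subsidised claims).  Refill defaults are dosing-realistic:
30 days for monthly orals and injections, 45–60 for larger-quantity scripts,
56 for infliximab infusions, 182 for rituximab.

Reporting errors are generated per questionnaire × medication by a logistic
model: a truly-current report flips to "stopped" (no stop date) with
probability `expit(logit(base_fn) + x'β)`, a truly-negative report flips to
"current"/checked with `expit(logit(base_fp) + x'β)`; defaults
base_fp = 0.02, base_fn = 0.05, β = 0.  The planted β are therefore exactly
the log-ORs the predictor stage estimates when discordance coincides with
reporting error.  Four-level questions are additionally answered "don't
know" with probability 0.01.  Genuine "stopped" reports carry a stop date
with probability 0.8, dated 0–5 days after the true episode end (so the
stop-date-present TN branch and the stop-date-absent FN branch are both
exercised; the post-stop-supply FN branch is covered by unit tests).

What passing tests on this cohort do **not** show about real data: no
clustering of repeated questionnaires within participants (real registry
estimates are over-precise for the same reason), no dose/quantity variation,
single exposure episodes, no secular listing-price dynamics, and an error
process that is exactly logistic in the modelled covariates.

## Experiment designs in the acceptance checks

* **Planted-OR recovery** uses 4,000 participants (≈21,000 complete-case
  questionnaires per replicate), a single dense-dispensing four-level
  medication, claims capture 1.0 and base error rates 0.05/0.05 with a
  planted HAQ log-OR of ln 2.  In this regime discordance coincides with the
  error process, so the estimand equals the planted OR of 2.0; 20 replicates
  check 95%-CI coverage ≥ 80%.
* **FDR control** simulates all-null predictor frames directly (n = 3,000
  rows per replicate — large enough that the 10-case eligibility rule
  passes — 200 replicates) and measures the per-covariate FDR-flag rate
  through the full screen + multivariable + BH path.
* **The window trade-off.**  PPV is non-decreasing in window length for
  every medication — structurally: the positive-report set is fixed, and
  matches only accumulate as the window grows.  Sensitivity TP/(TP+FN) is
  non-increasing *only once the window is at least one maximum inter-supply
  gap long* (refill × (1 + jitter)): below that, TP itself is still growing
  with the window and the ratio's direction is a sampling accident — a
  6-monthly infusion at a 30-day window is the canonical counterexample, in
  line with long-dosing-interval drugs being exceptions to the published
  qualitative trade-off.  The property suite therefore asserts raw TP/FP
  count monotonicity and PPV monotonicity unconditionally, and sensitivity
  monotonicity over the windows that cover a dispensing gap.

Problem sizes throughout the suite (150–4,000 participants, 20–200
replicates) were chosen to make every Monte-Carlo check stable at
single-CPU scale.

## Known limitations

Kappa's CI uses the simple asymptotic SE rather than the full
Fleiss–Cohen–Everitt variance; at the table sizes involved (n ≈ 24,000) the
difference is below the displayed precision, and the simple SE is what
reproduces the published CIs.  The generator emits one exposure episode per
user, so restart-after-gap patterns are absent.  The free-text recode
mechanism is declarative (token → medication/status) and cannot reproduce
judgment-based manual recoding.  No participant-level random effects are
fitted anywhere; all inference treats questionnaires as independent.
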