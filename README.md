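# medagree

Validation of questionnaire medication self-reports against prescription
dispensing claims.

Longitudinal patient registries routinely ask participants whether they are
*currently taking* each medication of interest. Claims databases — here the
Australian Pharmaceutical Benefits Scheme (PBS) model, with a date of supply,
a PBS item code and a WHO ATC level-5 code per dispensing — record what was
actually dispensed, and serve as a de facto reference standard.  `medagree`
implements the complete analysis pipeline for this validation problem, for
epidemiologists and registry analysts:

1. **Exposure classification** — each self-report is matched to the
   participant's dispensings inside a look-back window ending on the
   questionnaire date (1, 3, 6 or 12 months; both boundaries inclusive),
   by 7-character ATC code or by item code where one ATC code covers several
   questionnaire items (e.g. oral vs injectable methotrexate), and assigned a
   validity class:
   - *current*/checked + ≥1 dispensing → **TP**, otherwise **FP**;
   - *never*/*stopped*/unchecked + no dispensing → **TN**;
   - *stopped* + dispensing + reported stop date → **TN** if every supply is on
     or before the stop date, **FN** if any supply post-dates it;
   - *stopped* + dispensing without a stop date, or *never*/unchecked + a
     dispensing → **FN** (a policy switch can exclude never+dispensing instead);
   - *don't know* → excluded from the agreement analysis.
   Free-text "other medication" entries can override negative structured
   statuses via a declarative recode table, and subsidy-listing periods
   exclude reports the claims data could never confirm.

2. **Agreement metrics** — per medication × window 2×2 tables, with
   unadjusted Cohen's kappa

   κ = (p_o − p_e) / (1 − p_e),  p_o = (TP+TN)/n,
   p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n²,

   95% CI from the large-sample standard error √(p_o(1−p_o)/(n(1−p_e)²));
   sensitivity TP/(TP+FN), PPV TP/(TP+FP) and NPV TN/(TN+FN) with exact
   Clopper–Pearson intervals.  The optimal look-back window per medication is
   the one with the highest κ, ties broken by sensitivity, then by the
   shorter window; κ is banded ≤0.20 poor / ≤0.40 fair / ≤0.60 moderate /
   ≤0.80 substantial / >0.80 high.

3. **Discordance predictors** — discordance (FP or FN at the optimal window)
   is modelled at the questionnaire level with logistic regression over
   twelve covariates (age, sex, education, marital status, smoking, disease
   duration, SES percentile, EQ-5D anxiety/depression and pain, EQ-5D VAS,
   HAQ score, questionnaire modality): a per-covariate univariate screen,
   then one multivariable model per medication over the screen's significant
   covariates, Benjamini–Hochberg FDR adjustment (α = 0.05) of the model's
   coefficient p-values, and Chen-style OR effect-size bands.  Medications
   need ≥10 rows of the rarer outcome in both levels of every dichotomous
   covariate to be analysed.

4. **Synthetic cohort generator** — because real registry–claims linkages
   are access-restricted, the package ships a generator producing linked
   questionnaire/covariate/claims tables with known ground truth: ~3,400
   participants, 6-monthly-then-annual questionnaires over 2012–2023,
   per-medication exposure episodes with dosing-realistic refill intervals,
   four-level and checkbox questions, and a logistic reporting-error process
   whose planted covariate log-odds effects are exactly what the predictor
   stage estimates.

## Worked example

Recompute agreement metrics from a published contingency table
(azathioprine: TN 23,560, FN 18, FP 43, TP 129, 243 excluded):

```python
import medagree as m

t = m.ContingencyTable(tp=129, tn=23560, fp=43, fn=18, excluded=243)
r = m.compute_agreement(t)
print(f"azathioprine (n = {t.n}, excluded = {t.excluded})")
for name, est in [("kappa", r.kappa), ("sensitivity", r.sensitivity),
                  ("PPV", r.ppv), ("NPV", r.npv)]:
    print(f"  {name:12s} {m.round_half_up(est.value)} "
          f"({m.round_half_up(est.ci_lo)}-{m.round_half_up(est.ci_hi)})")
print("  band:", r.band)
```

```
azathioprine (n = 23750, excluded = 243)
  kappa        0.81 (0.76-0.86)
  sensitivity  0.88 (0.81-0.93)
  PPV          0.75 (0.68-0.81)
  NPV          1.0 (1.0-1.0)
  band: high
```

i.e. self-report and claims agree far beyond chance (κ 0.81, "high"), 88% of
claims-confirmed users self-report correctly, and a negative self-report is
almost always right.  Run the full pipeline on a synthetic cohort:

```python
coh = m.generate_cohort(n_participants=300, seed=42)
cl  = m.classify_reports(coh.questionnaires, coh.claims, coh.medications)
res = m.agreement_by_medication(cl)
print(f"synthetic cohort: {len(coh.covariates)} questionnaires, "
      f"{len(coh.claims)} claims rows")
for med in ("methotrexate_oral", "rituximab", "paracetamol"):
    opt = next(w for w, x in res[med].items() if x.is_optimal_window)
    x = res[med][opt]
    print(f"  {med:18s} optimal window {opt.label:4s} "
          f"kappa {m.round_half_up(x.kappa.value)} "
          f"sens {m.round_half_up(x.sensitivity.value)} "
          f"ppv {m.round_half_up(x.ppv.value)}")
```

```
synthetic cohort: 1785 questionnaires, 12775 claims rows
  methotrexate_oral  optimal window 3mo  kappa 0.91 sens 0.95 ppv 0.89
  rituximab          optimal window 12mo kappa 0.34 sens 0.82 ppv 0.22
  paracetamol        optimal window 12mo kappa 0.75 sens 0.79 ppv 0.76
```

A monthly oral medication is validated well by a 3-month window; a 6-monthly
infusion needs the full 12-month window and still shows poor PPV (most
"current" reports have no recent supply to confirm them), and an
over-the-counter analgesic with partial claims capture sits in between.

The same stages are available from the shell:

```
medagree simulate --config cohort.yaml --seed 1 --out data/
medagree validate --config run.yaml
medagree predictors --config run.yaml
medagree report --config run.yaml
```

writing `agreement_optimal.csv` / `agreement_all_windows.csv`,
`predictors_multivariable.csv` / `predictors_univariate.csv` and a
JSON-lines run log with full row accounting.

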