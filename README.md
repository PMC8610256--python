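# parrisk

External validation of points-based hospital readmission risk scores —
built around the PAR-Risk Score, a 12-item model predicting potentially
avoidable readmissions (PAR) within 30 days of discharge in older internal
medicine patients.

A PAR is an unplanned readmission related to a previously known affliction;
in Swiss hospitals it is adjudicated retrospectively (by the SQLape
screening algorithm), so a prospective risk score is needed to target
discharge interventions. Validating such a score on a local cohort means:
extract the score's predictors from routine EHR tables, compute each
patient's raw score S = Σⱼ wⱼ xⱼ (integer point weights wⱼ over binary
predictors xⱼ present at discharge), stratify into low / medium / high risk
bands, and quantify performance:

* **discrimination** — C statistic (AUC) of the univariable logistic model
  logit P(PAR) = α + βS, with a DeLong 95% interval;
* **accuracy** — Brier score, mean (yᵢ − p̂ᵢ)²;
* **fit** — the le Cessie–van Houwelingen–Copas–Hosmer unweighted
  sum-of-squares test, T = Σ(yᵢ − p̂ᵢ)² standardised by its estimated null
  moments;
* **calibration** — observed vs predicted risk per score point, weighted by
  patients at that point;
* **stratified performance** — per-group odds ratios against the low-risk
  reference (Woolf intervals), sensitivity / specificity / PPV / NPV of
  each group vs low, and observed vs mean predicted risk per group, under
  both the original cut-points (<3 / 3–10 / >10) and cut-points re-adapted
  to the cohort's score tertiles.

The package ships a synthetic cohort generator emulating the validation
study's conditions (published predictor prevalences, 5.7% event rate, 7.2%
missing potassium, 1.5% missing dispensings, exclusion-triggering records),
so the full pipeline is exercised without patient data. The bundled point
weights and ICD-10 code lists are clearly-labelled synthetic stand-ins —
only the anaemia weight (2 points) is public — and can be replaced by your
own transcriptions (see `docs/methods.md`).

## Worked example

Simulate a cohort at the study scale and run every stage:

```sh
parrisk simulate --out demo/cohort --n 5985 --seed 1
parrisk run --input demo/cohort --out demo/report --seed 1
```

`demo/report/performance.csv`:

```
statistic,estimate,ci_low,ci_high
c_statistic,0.6387,0.6096,0.6678
brier_score,0.0559,,
gof_T,334.6199,,
gof_z,-0.1086,,
gof_p,0.913518,,
```

The simulated score discriminates modestly (C = 0.64 — the generator's
effect sizes are the published unadjusted odds ratios, which are small),
the Brier score 0.056 reflects the ~6% event rate, and the goodness-of-fit
test does not reject (p = 0.91), as expected when the fitted model family
matches the generating one. `strata.csv` shows the risk-group contingency
table and odds ratios under both threshold sets, e.g.

```
threshold_set,group,cut_low,cut_high,n_par,n_nonpar,odds_ratio,ci_low,ci_high
adapted,low,11,15,63,2020,1.0,,
adapted,medium,11,15,108,1750,1.98,1.44,2.72
adapted,high,11,15,191,1853,3.3,2.47,4.42
```

— patients in the adapted high-risk tertile have 3.3 times the odds of a
PAR compared with the low tertile. `classification.csv`,
`observed_predicted.csv`, `calibration.csv`, `sensitivity.csv` (the three
missing-data sensitivity cohorts), `characteristics.csv` and
`manifest.json` complete the report; reruns with the same seed are
byte-identical.

The same machinery is available as a library:

```python
from parrisk import StrataTable, group_odds_ratios

table = StrataTable({"low": (9, 293), "medium": (127, 2826),
                     "high": (204, 2526)})
print(group_odds_ratios(table)["high_vs_low"])
# (2.6291897..., 1.3342..., 5.1811...)  -> printed as 2.63 (1.33-5.18)
```

which reproduces the validation study's published high-vs-low odds ratio
from its contingency counts.

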