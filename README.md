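# adherekit

Quantifying antiretroviral-therapy (ART) adherence and its ability to predict
virological failure and HIV drug resistance.

Clinics and trials measure adherence in very different ways — asking the
patient, counting returned pills, mining pharmacy refill records, assaying
drug concentrations, or logging electronic pillbox openings — and these
measures disagree systematically.  `adherekit` implements six of them as one
reproducible pipeline, together with the landmark prediction models used to
compare them, for analysts working with longitudinal HIV-cohort data in
resource-limited settings (and for methodologists studying adherence
measurement error).

## The measures

For a participant randomised at day 0 with a landmark viral load (VL) drawn
at day *t*:

| Measure | Definition | Range |
|---|---|---|
| SR | 3-day self-recall: 100 × (days reported dosed)/3 | {0, 33.3, 66.7, 100} |
| CPC | clinic pill count: 100 × (dispensed − returned)/(days × doses/day) over the last dispensing interval | ≥ 0, may exceed 100 |
| PR-average | 100 × (days of supply dispensed in [0, *t*)) / days in care | ≥ 0, may exceed 100 |
| PR-gaps | 100 × (*t* − medication-free days)/*t*, from a daily stock-on-hand ledger | [0, 100] |
| EAMD | 100 × adherent monitor days / non-censored days in care | [0, 100] |
| TDM | mid-dose efavirenz concentration (mg/L); models use log₁₀ | ≥ 0 |

A monitor day runs 06:00→05:59 local; days with no device heartbeat or a
battery reading below 3660 device units are censored (dead battery), not
counted as non-adherence.  A *medication-free* day is one on which the
participant could not have had drug in hand given dispensing dates and
quantities, with surplus from early refills carried forward.

## The models

Outcomes are per-protocol landmarks: virological failure is a single HIV-RNA
> 400 copies/ml in the week-16 window (weeks 12–20) or > 40 copies/ml in the
week-48 window (weeks 32–64); resistance is ≥ 1 major mutation (user-supplied
catalogue) compromising a regimen drug, assessable when the sample amplifies
(VL > 500 copies/ml).  Each measure enters a logistic regression

  logit P(outcome) = β₀ + β·(adherence/10) [+ age + baseline CD4 + baseline log₁₀ VL]

so exp(β) is the odds ratio per 10% adherence increase (per 1-log for drug
concentration).  Discrimination is summarised by the placement-method
(Mann–Whitney) ROC AUC with DeLong confidence intervals, and measures are
compared pairwise with the paired DeLong test plus a seeded bootstrap.
Complete separation (likely with few resistance events) triggers a
Firth-penalised fallback, flagged in the output.

A statsmodels-style interface carries the core:

```python
import adherekit as ak

model = ak.AdherenceOutcomeModel.from_dataframe(
    df, outcome_col="failed", adherence_col="eamd_pct")
res = model.fit()
print(res.summary())
```

## Worked example

The package ships a seeded synthetic-cohort generator that emulates the data
streams and measurement biases of a 230-participant ART-naïve cohort
(clustered missed-dose gaps, early pharmacy refills, pocket doses the
monitor never records, ~10% dead-battery days, optimistic self-report):

```
adherekit simulate --seed 2 --out data/
adherekit estimate --in data/ --out est/
adherekit model --in data/ --estimates est/adherence_estimates.csv --seed 2 --out mod/
```

On this run the week-48 medians (IQR) per measure were:

```
landmark     method   n  median    q1    q3
  week48         SR 168   100.0 100.0 100.0
  week48        CPC 182    94.3  74.0  98.2
  week48 PR_AVERAGE 182    97.1  85.6 101.8
  week48    PR_GAPS 182    97.0  85.6  99.7
  week48       EAMD 182    87.1  72.2  90.7
  week48        TDM 168     2.0   1.3   3.3
```

(the `adherence_summary` table written by the `report` subcommand, rounded
to one decimal)

reading: everyone *says* they take their pills (SR median 100%), the pill
count and refill measures sit in the mid-90s, and the electronic monitor —
which cannot be flattered, only evaded — reports the lowest adherence
(median 87%).  `mod/model_report.csv` then holds the Table-of-odds-ratios
grid (method × landmark × failure/resistance, univariate and adjusted), with
ROC point files and an AUC comparison of each measure against electronic
monitoring.

## Layout

- `src/adherekit/io.py` — CSV normal form, validation, de-duplication
- `src/adherekit/measures.py` — the six estimators and landmark windows
- `src/adherekit/models.py` — outcomes, logistic models, report grid
- `src/adherekit/roc.py` — placement AUC, DeLong CI, paired comparison
- `src/adherekit/simulate.py` — seeded synthetic cohort generator
- `src/adherekit/cli.py` — `adherekit simulate|estimate|model|report`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
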