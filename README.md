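# lapserisk

Real-time estimation of smoking-lapse risk from ecological momentary
assessments (EMAs), built for researchers developing just-in-time adaptive
interventions for smoking cessation.

During a post-quit week, smokers answer brief phone-delivered surveys
several times a day: four 5-point items (urge to smoke, stress, commitment
to staying smoke free, cigarette availability) and two yes/no items
(interacting with someone smoking, alcohol in the past hour). The question
this package operationalizes: can those six momentary risk factors flag an
**imminent lapse** — a first cigarette within the next 4 hours?

## The estimators

Each EMA is dichotomized into six risk indicators: urge ≥ 4, stress ≥ 4,
motivation ≤ 2, availability ≥ 4, plus the two binaries. Two scores are
computed per assessment:

- **Unweighted**: the count of indicators present, 0–6; an EMA is flagged
  when 3 or more factors are present.
- **Weighted**: a linear score with fixed coefficients,

  ```
  risk = 0.2·(urge − 3) + 0.2·(stress − 3) + 0.7·(availability − 3)
       + 1·[smoker interaction] + 1·[alcohol past hour] − 0.2·(motivation − 3)
  ```

  flagged when the score exceeds 1.0. Over all 2,500 possible response
  profiles the score spans [−2.6, 4.6].

Pre-lapse EMAs of lapsers are labeled `WITHIN_4H` or `PRE_LAPSE_OVER_4H`
by their distance to the first lapse; all EMAs of abstainers are
`ABSTAINER`; post-lapse records are excluded. Evaluation treats `WITHIN_4H`
as the positive class: sensitivity and specificity at a cut-off, Youden's
J = sens + spec − 1, the rank (Mann–Whitney) AUC with a DeLong confidence
interval, a paired correlated-ROC test between the two estimators, and
participant-level detection (the fraction of lapsers flagged at least once
inside the window). A grid search over per-item coefficients reproduces the
iterative weighting procedure that produced the weighted formula.

Because the underlying clinical dataset is not public, the package ships a
seeded synthetic-cohort generator that emulates the study design — 52
lapsers + 40 abstainers, 5 prompted EMAs/day over a 16-hour waking window
for 7 days plus self-initiated EMAs, and class-conditional risk-factor
prevalences — so the entire pipeline is testable end to end.

## Worked example

```python
from lapserisk import (SimConfig, build_analysis_set, evaluate,
                       generate_cohort, score_analysis_set)

cohort = generate_cohort(SimConfig(master_seed=42))
scored = score_analysis_set(build_analysis_set(cohort))
report = evaluate(scored, cohort.roster, seed=1)
```

Running `python examples/02_score_and_evaluate.py` (the same computation)
prints:

```
n_risk_factors at cut-off 3.0 (ge): sensitivity 46.5%, specificity 85.4%
weighted_risk_score at cut-off 1.0 (gt): sensitivity 61.6%, specificity 72.8%
participant-level detection: {'unweighted': '62%', 'weighted': '83%'}
AUC unweighted 0.715 (95% CI 0.662-0.768)
AUC weighted   0.694 (95% CI 0.636-0.752)
paired AUC comparison p = 0.211 (delong)
```

Reading: on this synthetic cohort, 46.5% of EMAs completed within 4 hours
of a first lapse carried ≥3 risk factors, while 85.4% of all other retained
EMAs stayed below that cut-off; 62% of lapsers were flagged by the count
score at least once inside their pre-lapse window (83% by the weighted
score); the AUCs quantify threshold-free discrimination. The
`examples/` directory holds one short script per capability (cohort
generation, scoring/evaluation, weight search, full pipeline).

A thin CLI mirrors the stages:

```sh
lapserisk simulate --out-dir run --seed 7
lapserisk window   --ema run/ema.csv --roster run/roster.csv --out run/labeled.csv
lapserisk score    --labeled run/labeled.csv --out run/scored.csv
lapserisk optimize --scored run/scored.csv --out run/search.json
lapserisk evaluate --scored run/scored.csv --roster run/roster.csv --out run/report.json
lapserisk run      --out-dir run            # all stages + manifest
```

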