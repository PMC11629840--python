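# premo

Point-based risk stratification for childhood myopia, plus the statistical
pipeline used to validate it externally.

The PreMO (Predicting Myopia Onset) risk indicator assigns a non-myopic
child aged 6–10 an integer risk score from three baseline measurements:

| factor | ages 6–8 (points) | ages 9–10 (points) |
|---|---|---|
| myopic parents 0 / 1 / 2 | 0 / 2 / 3 | 0 / 1 / 2 |
| cycloplegic SER | >+1.00 D → 0; +0.75…+1.00 D → 2; <+0.75 D → 3 | >+0.875 D → 0; +0.375…+0.875 D → 1; <+0.375 D → 2 |
| axial length | <22.94 mm → 0; 22.94–23.11 → 1; 23.12–23.18 → 2; ≥23.19 → 3 | <23.33 mm → 0; 23.33–23.61 → 1; ≥23.62 → 2 |

Totals (0–9 for ages 6–8, 0–6 for ages 9–10) map to risk categories
0 / 1–3 / 4–6 / 7–9 = little-no / low / moderate / high risk. Where both
eyes were measured, the least hyperopic eye's SER and AL are scored;
myopia is defined as SER ≤ −0.50 D, and the outcome is myopic/non-myopic
status at age ≥ 15 years.

The validation half of the package evaluates the score (or any
single-feature predictor such as SER < +0.75 D or AL ≥ 23.07 mm) against
those outcomes: ROC curve and trapezoidal AUC (equal to the tie-corrected
Mann–Whitney probability), Youden-optimal cut-off
(J = sensitivity + specificity − 1, ties broken toward sensitivity),
sensitivity/specificity/FPR with their n/n fractions, a stratified
percentile-bootstrap AUC confidence interval, Spearman correlation between
the score and follow-up SER, and cohort incidence.

Because the original validation cohorts are not public, the package also
provides (a) a synthetic cohort generator with a logistic score-to-onset
link and calibrated UK-like / Hong-Kong-like presets, and (b) deterministic
fixture cohorts reconstructed from the published 2×2 contingency counts, on
which the whole pipeline reproduces the published metrics exactly.

Intended users: eye-care researchers evaluating risk-score tools,
and anyone needing a worked, tested reference implementation of
screening-score validation (ROC/Youden/bootstrap) on tabular cohorts.

## Worked example

Score one child through the API:

```python
from premo import ChildObservation, EyePolicy, compute_premo_score, assign_risk_category

obs = ChildObservation(child_id="demo", age_years=7.2, n_myopic_parents=2,
                       ser_right=1.25, ser_left=0.50,
                       al_right=23.02, al_left=23.30,
                       eye_policy=EyePolicy.LEAST_HYPEROPIC)
score = compute_premo_score(obs)
print(score)
print(assign_risk_category(score))
```

```
RiskScore(band=<Band.AGE_6_8: 'age_6_8'>, parental_points=3, ser_points=3, al_points=3, total=9)
RiskCategory(label=<RiskCategoryLabel.HIGH: 'high'>, predicted_outcome='likely to be myopic by 10 years of age')
```

The left eye (SER +0.50 D, the least hyperopic) is selected; +0.50 D is
below +0.75 D (3 points), its AL 23.30 mm is ≥ 23.19 mm (3 points) and two
myopic parents add 3, so the child totals 9/9: high risk, predicted myopic
by age 10.

From the shell, rebuild the UK-like ages 6–8 validation cohort from its
published contingency counts and evaluate three predictors on it:

```sh
premo fixture --which score --row uk_6_8 --out uk.csv
premo validate --cohort uk.csv \
    --predictors "score:ge:4,ser:lt:0.75,al:ge:23.07" \
    --boot 2000 --seed 1 --out report
```

```
cohort n=57, myopes=33, incidence 58%
Spearman rho (score vs outcome SER, n=57): -1.00
premo_score >= 4: AUC 0.99 (0.97-1.00), sens 0.97 (n=32/33), spec 0.96 (n=23/24), FPR 0.04 (n=1/24), optimal cutoff 4
ser < 0.75: AUC 0.90 (0.84-0.95), sens 0.64 (n=21/33), spec 1.00 (n=24/24), FPR 0.00 (n=0/24), optimal cutoff 0.5
al >= 23.07: AUC 0.98 (0.95-1.00), sens 0.97 (n=32/33), spec 0.96 (n=23/24), FPR 0.04 (n=1/24), optimal cutoff 23.15
```

A score ≥ 4 calls 32 of the 33 future myopes (sensitivity 0.97) while
raising only 1 false positive among the 24 children who stayed non-myopic
(specificity 0.96); the Youden-optimal cut-off recovered from the sweep is
4. The incidence line (58%) is the fraction of the cohort that became
myopic by age 15+. The SER and AL rows here are computed on the
score-fixture's recipe values; the published singular-predictor rows have
their own fixtures (`--which singular`). `report.json` carries the same
numbers at full precision. Synthetic cohorts come from
`premo simulate --preset uk_6_8 --n 500 --seed 7 --out sim.csv`.

## Acceptance script

`scripts/acceptance.py` rebuilds every published-count fixture cohort from
scratch, runs it through scoring and validation, and writes the measured
sensitivities, specificities and incidences (risk-score rows and singular
predictors) as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
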