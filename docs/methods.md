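# Methods

## The risk indicator

The score is a sum of age-banded integer points for three baseline
factors measured in a non-myopic child (selected SER > −0.50 D):
parental myopia (0/1/2 myopic parents), cycloplegic spherical equivalent
refraction (SER, dioptres) and axial length (AL, mm). Two point tables
exist: ages 6–8 (components up to 3+3+3, total 0–9) and ages 9–10
(2+2+2, total 0–6). Totals map to categories 0 / 1–3 / 4–6 / 7–9 =
little-no / low / moderate / high risk; the bins are applied unchanged to
the 9–10 band even though its high bin (7–9) is unreachable — the
brute-force test asserts exactly that unreachability rather than rescaling
the bins.

### Interval conventions

The published band edges need two conventions the tables do not spell out:

* **SER** bands are contiguous if the middle band is closed at both ends,
  so we use (+1.00, ∞) → 0, [+0.75, +1.00] → 2, (−∞, +0.75) → 3 for ages
  6–8 and the analogous closed middle band for 9–10. A child at exactly
  +1.00 D therefore scores 2.
* **AL** bands are printed to 0.01 mm and leave gaps (… 23.11 | 23.12 …).
  We close the real line with half-open intervals anchored at the lower
  printed bound of each higher band: [22.94, 23.12) → 1, [23.12, 23.19)
  → 2, etc. A child at 23.115 mm scores 1.

A grid property test confirms every finite SER/AL value maps to exactly
one point value under these conventions. No input rounding is performed.

### Eye selection and age routing

With per-eye data the least hyperopic (algebraically smallest SER) eye is
scored, and AL is taken from that same eye; an exact SER tie selects the
right eye (arbitrary but deterministic). Cohorts with only inter-ocular
means use the means. Ages route as [6, 9) → 6–8 table, [9, 11) → 9–10
table; anything else is an error, since the indicator is not defined
outside 6–10. Missing parental data is an error unless the caller opts
into "assume 0 myopic parents", which is logged.

## Outcome labelling

Myopia at follow-up means SER ≤ −0.50 D measured at age ≥ 15.0 years
(inclusive boundary, ages compared exactly). A child documented as having
become myopic before 15 with no later record is carried forward as myopic
(progression back to non-myopia is not observed in practice); such
records are classification-only and are excluded from the score-vs-SER
rank correlation. A non-myopic measurement before 15 resolves nothing and
the row is rejected. An explicit myopic/non-myopic flag may accompany a
measured SER but must agree with it; contradictions fail the row loudly
rather than silently preferring one source.

## Validation statistics

* **ROC/AUC.** Every distinct feature value is a candidate cut-off
  (positive call: score ≥ t, AL ≥ t, SER below the cut-off — less
  hyperopic reserve is riskier). The AUC is the trapezoid over the
  (FPR, sensitivity) path in descending-threshold order, which handles tie
  diagonals exactly; a property test asserts equality with the
  tie-corrected Mann–Whitney probability P(case > control) + ½P(tie) on
  random cohorts, and an sklearn cross-check agrees.
* **Youden cut-off.** J = sensitivity + specificity − 1, maximised over
  candidate thresholds; ties break toward the lowest (most sensitive)
  threshold, since in a screening context a missed future myope costs
  more than a false alarm. Mathematically tied J values can differ by one
  ulp, so the maximiser is selected with a 1e-12 tolerance.
* **AUC confidence interval.** Stratified percentile bootstrap: children
  are resampled with replacement within outcome classes (n_boot default
  2000, explicit seed required, deterministic). The reference analysis
  does not name its CI method, so intervals are comparable but not
  identical to other software. A percentile interval is not guaranteed to
  bracket the point AUC at small n_boot, though it does on all shipped
  fixtures at the default; empirical coverage on a model with known AUC
  is checked in the acceptance suite (~95%).
* **Spearman.** scipy's implementation (average ranks for ties) behind
  the module surface; tests check it against a hand-rolled rank-Pearson
  oracle and the tie-free closed form 1 − 6Σd²/(n(n²−1)).
* Metrics are kept at full precision; two-decimal rounding happens only
  when a report is rendered (the JSON report carries full precision).

## Synthetic cohorts

`generate_cohort` states a simple generative world: baseline (SER, AL)
bivariate normal with a negative correlation (longer eyes are less
hyperopic), truncated by rejection to non-myopic baselines; parental
myopia multinomial; P(myopic by 15) = expit(intercept + slope·total);
myopic outcome SER drawn below −0.50 D with magnitude increasing in the
score; optionally a fraction of myopes lose their follow-up SER and are
carried forward, mimicking clinic records that stop after onset. One
seeded generator stream drives everything, so cohorts are byte-identical
across runs.

The three presets (`uk_6_8`, `hk_6_8`, `hk_9_10`, YAML files shipped with
the package) emulate the published cohorts' structure: cohort sizes
57/234/75, age means 7.1/7.1/9.7, mean-only eyes for the UK-like cohort
vs least-hyperopic-eye per-eye data for the HK-like ones, and onset
intercepts calibrated by root-finding E[expit(a + b·T)] over a 20 000-draw
score distribution so expected incidence hits the published 58% / 94% /
76% (the last derived from the printed counts 57/75). Baseline biometry
means/SDs and parental-myopia mixtures are stated assumptions — the
source prints no distribution parameters — chosen once at plausible
paediatric values; the HK presets use a flatter onset slope to reflect the
weaker score–outcome separation in a high-incidence setting. A green
generator test therefore establishes internal consistency of this stated
world, not fidelity to the real cohorts' unpublished distributions.

Fixture cohorts are different: they realize printed 2×2 contingency
counts exactly. Each record is a real (parents, SER, AL) combination from
a mid-band recipe table that scores to the intended total through the
scoring module (totals are never injected), with called-positive records
cycling over totals ≥ the cut-off starting at the cut-off itself (so the
Youden sweep recovers the published cut-off of 4) and called-negative
records cycling below. Their outcome SERs track the total only so rank
statistics behave sensibly; fixture AUCs and correlations are properties
of the reconstruction, not published quantities — only the confusion
metrics and incidence are.

## Known limitations

* Published headline AUCs and Spearman correlations of the real cohorts
  are not reproducible from printed information; they are deliberately
  not targeted.
* Two printed cells are inconsistent with their own n/n fractions
  (a sensitivity printed 0.90 beside 51/57 = 0.89, and an FPR printed
  0.16 beside 4/24 = 0.17); the fractions are treated as authoritative.
* The 9–10 table's category bins are the 0–9 bins applied unchanged;
  moderate risk (≥4) is its top reachable category.
* Estimating AL risk when AL is unmeasured, scores outside ages 6–10 and
  onset-age prediction (myopic by 10/13/16) are out of scope.
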