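import numpy as np
import pytest

from premo.synthetic_data import published_fixture
from premo.validation import score_cohort


@pytest.fixture(scope="session")
def uk_6_8():
    """UK-like ages 6-8 cohort reconstructed from published counts."""
    records, cutoff = published_fixture("uk_6_8")
    return records, cutoff


@pytest.fixture(scope="session")
def hk_6_8():
    records, cutoff = published_fixture("hk_6_8")
    return records, cutoff


@pytest.fixture(scope="session")
def hk_9_10():
    records, cutoff = published_fixture("hk_9_10")
    return records, cutoff


@pytest.fixture(scope="session")
def uk_scored(uk_6_8):
    return score_cohort(uk_6_8[0])


def cohort_from_totals(myope_totals, nonmyope_totals, band=None):
    """Build real observations whose risk scores equal the requested totals
    (via the mid-band recipe table), with outcomes attached."""
    from premo.cohort_io import CohortRecord, OutcomeLabel
    from premo.scoring import Band, ChildObservation, EyePolicy
    from premo.synthetic_data import TOTAL_RECIPES

    band = Band.AGE_6_8 if band is None else band
    records = []
    for i, (total, myopic) in enumerate(
        [(t, True) for t in myope_totals] + [(t, False) for t in nonmyope_totals]
    ):
        parents, ser, al = TOTAL_RECIPES[band][total]
        obs = ChildObservation(
            child_id=f"t{i}", age_years=7.0 if band is Band.AGE_6_8 else 9.5,
            n_myopic_parents=parents, ser_mean=ser, al_mean=al,
            eye_policy=EyePolicy.MEAN,
        )
        outcome = OutcomeLabel(
            myopic=myopic, basis="measured_at_15plus",
            outcome_ser=-1.0 if myopic else 1.0, outcome_age_years=16.0,
        )
        records.append(CohortRecord(observation=obs, outcome=outcome))
    return score_cohort(records)


def mann_whitney_auc(cases, controls):
    """Independent pairwise-enumeration oracle: P(case > control) + 0.5
    P(tie), computed by brute force."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    wins = ties = 0
    for x in cases:
        for y in controls:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    return (wins + 0.5 * ties) / (cases.size * controls.size)
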