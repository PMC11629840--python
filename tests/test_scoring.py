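"""Point tables, eye selection, age routing and risk categories."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premo.exceptions import AlreadyMyopicError, BandError, InputError
from premo.scoring import (
    BAND_MAX_TOTAL,
    Band,
    ChildObservation,
    EyePolicy,
    RiskCategoryLabel,
    RiskScore,
    assign_risk_category,
    band_for_age,
    compute_premo_score,
    score_al,
    score_parental,
    score_ser,
    select_eye_measurements,
)


def obs_two_eyes(ser_r, ser_l, al_r=23.0, al_l=23.5, **kw):
    kw.setdefault("child_id", "c1")
    kw.setdefault("age_years", 7.0)
    kw.setdefault("n_myopic_parents", 0)
    return ChildObservation(
        ser_right=ser_r, ser_left=ser_l, al_right=al_r, al_left=al_l,
        eye_policy=EyePolicy.LEAST_HYPEROPIC, **kw,
    )


class TestEyeSelection:
    def test_least_hyperopic_picks_lower_ser_and_its_al(self):
        sel = select_eye_measurements(obs_two_eyes(1.25, 0.75, al_r=22.9, al_l=23.4))
        assert (sel.ser, sel.al, sel.eye_used) == (0.75, 23.4, "left")

    def test_tie_goes_to_right_eye(self):
        sel = select_eye_measurements(obs_two_eyes(1.00, 1.00, al_r=22.9, al_l=23.4))
        assert (sel.eye_used, sel.al) == ("right", 22.9)

    def test_mean_policy_passes_through(self):
        obs = ChildObservation(
            child_id="c", age_years=7.0, n_myopic_parents=0,
            ser_mean=0.75, al_mean=23.00, eye_policy=EyePolicy.MEAN,
        )
        sel = select_eye_measurements(obs)
        assert (sel.ser, sel.al, sel.eye_used) == (0.75, 23.00, "mean")

    def test_missing_fields_for_policy_are_rejected_by_name(self):
        with pytest.raises(InputError, match="al_left"):
            ChildObservation(
                child_id="c", age_years=7.0, n_myopic_parents=0,
                ser_right=1.0, ser_left=1.0, al_right=23.0,
                eye_policy=EyePolicy.LEAST_HYPEROPIC,
            )
        with pytest.raises(InputError, match="ser_mean"):
            ChildObservation(
                child_id="c", age_years=7.0, n_myopic_parents=0,
                al_mean=23.0, eye_policy=EyePolicy.MEAN,
            )


class TestPointTables:
    @pytest.mark.parametrize(
        "n,band,expected",
        [
            (0, Band.AGE_6_8, 0), (1, Band.AGE_6_8, 2), (2, Band.AGE_6_8, 3),
            (0, Band.AGE_9_10, 0), (1, Band.AGE_9_10, 1), (2, Band.AGE_9_10, 2),
        ],
    )
    def test_parental_points(self, n, band, expected):
        assert score_parental(n, band) == expected

    def test_parental_points_reject_out_of_range(self):
        with pytest.raises(InputError):
            score_parental(3, Band.AGE_6_8)

    @pytest.mark.parametrize(
        "ser,band,expected",
        [
            (1.25, Band.AGE_6_8, 0),
            (1.00, Band.AGE_6_8, 2),   # middle band closed at both ends
            (0.75, Band.AGE_6_8, 2),
            (0.50, Band.AGE_6_8, 3),
            (2.00, Band.AGE_9_10, 0),
            (0.875, Band.AGE_9_10, 1),
            (0.50, Band.AGE_9_10, 1),
            (0.375, Band.AGE_9_10, 1),
            (0.20, Band.AGE_9_10, 2),
        ],
    )
    def test_ser_points(self, ser, band, expected):
        assert score_ser(ser, band) == expected

    @pytest.mark.parametrize(
        "al,band,expected",
        [
            (22.50, Band.AGE_6_8, 0),
            (22.94, Band.AGE_6_8, 1),
            (23.00, Band.AGE_6_8, 1),
            (23.115, Band.AGE_6_8, 1),  # printed gap 23.11->23.12: half-open
            (23.12, Band.AGE_6_8, 2),
            (23.19, Band.AGE_6_8, 3),
            (23.00, Band.AGE_9_10, 0),
            (23.33, Band.AGE_9_10, 1),
            (23.50, Band.AGE_9_10, 1),
            (23.62, Band.AGE_9_10, 2),
        ],
    )
    def test_al_points(self, al, band, expected):
        assert score_al(al, band) == expected

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(InputError):
            score_ser(math.nan, Band.AGE_6_8)
        with pytest.raises(InputError):
            score_al(-23.0, Band.AGE_6_8)


class TestComputeScore:
    def test_maximal_six_to_eight_child(self):
        obs = ChildObservation(
            child_id="max", age_years=7.0, n_myopic_parents=2,
            ser_mean=0.50, al_mean=23.20, eye_policy=EyePolicy.MEAN,
        )
        score = compute_premo_score(obs)
        assert (score.parental_points, score.ser_points, score.al_points) == (3, 3, 3)
        assert score.total == 9 and score.band is Band.AGE_6_8

    def test_all_zero_bands(self):
        obs = ChildObservation(
            child_id="z", age_years=7.0, n_myopic_parents=0,
            ser_mean=2.00, al_mean=22.50, eye_policy=EyePolicy.MEAN,
        )
        assert compute_premo_score(obs).total == 0

    def test_nine_to_ten_routing_and_points(self):
        obs = ChildObservation(
            child_id="b", age_years=9.7, n_myopic_parents=1,
            ser_mean=0.50, al_mean=23.50, eye_policy=EyePolicy.MEAN,
        )
        score = compute_premo_score(obs)
        assert score.band is Band.AGE_9_10
        assert (score.parental_points, score.ser_points, score.al_points) == (1, 1, 1)
        assert score.total == 3

    def test_already_myopic_baseline_is_refused(self):
        obs = ChildObservation(
            child_id="m", age_years=7.0, n_myopic_parents=0,
            ser_mean=-0.50, al_mean=23.0, eye_policy=EyePolicy.MEAN,
        )
        with pytest.raises(AlreadyMyopicError):
            compute_premo_score(obs)

    @pytest.mark.parametrize("age", [5.9, 11.0, 14.0])
    def test_unsupported_ages_raise_band_error(self, age):
        with pytest.raises(BandError):
            band_for_age(age)

    @pytest.mark.parametrize(
        "age,band", [(6.0, Band.AGE_6_8), (8.99, Band.AGE_6_8),
                     (9.0, Band.AGE_9_10), (10.9, Band.AGE_9_10)]
    )
    def test_age_routing(self, age, band):
        assert band_for_age(age) is band


class TestCategories:
    @pytest.mark.parametrize(
        "total,label",
        [
            (0, RiskCategoryLabel.LITTLE_NO_RISK),
            (1, RiskCategoryLabel.LOW), (3, RiskCategoryLabel.LOW),
            (4, RiskCategoryLabel.MODERATE), (6, RiskCategoryLabel.MODERATE),
            (7, RiskCategoryLabel.HIGH), (9, RiskCategoryLabel.HIGH),
        ],
    )
    def test_bins(self, total, label):
        assert assign_risk_category(total).label is label

    def test_moderate_category_predicts_myopia_by_13(self):
        cat = assign_risk_category(5)
        assert cat.label is RiskCategoryLabel.MODERATE
        assert "13" in cat.predicted_outcome

    def test_accepts_risk_score_objects(self):
        score = RiskScore(band=Band.AGE_6_8, parental_points=3,
                          ser_points=3, al_points=3)
        assert assign_risk_category(score).label is RiskCategoryLabel.HIGH


class TestProperties:
    """Structural invariants of the point tables."""

    def test_brute_force_totals_and_reachable_categories(self):
        """Enumerating every factor-cell combination confirms the printed
        band maxima (9 and 6) and that only the 9-10 band's high-risk bin
        is unreachable."""
        ser_reps = {Band.AGE_6_8: [2.0, 0.875, 0.5], Band.AGE_9_10: [2.0, 0.5, 0.2]}
        al_reps = {
            Band.AGE_6_8: [22.5, 23.0, 23.15, 23.4],
            Band.AGE_9_10: [23.0, 23.5, 23.8],
        }
        for band, expected_max in BAND_MAX_TOTAL.items():
            totals = {
                score_parental(p, band) + score_ser(s, band) + score_al(a, band)
                for p, s, a in itertools.product((0, 1, 2), ser_reps[band], al_reps[band])
            }
            assert max(totals) == expected_max
            reachable = {assign_risk_category(t).label for t in totals}
            if band is Band.AGE_6_8:
                assert reachable == set(RiskCategoryLabel)
            else:
                assert reachable == set(RiskCategoryLabel) - {RiskCategoryLabel.HIGH}

    @given(
        ser=st.floats(-0.49, 6.0, allow_nan=False),
        al=st.floats(20.0, 27.0, allow_nan=False),
        parents=st.integers(0, 2),
        band=st.sampled_from(list(Band)),
        d_ser=st.floats(0.0, 2.0),
        d_al=st.floats(0.0, 2.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_monotonicity(self, ser, al, parents, band, d_ser, d_al):
        """Less hyperopic SER, longer AL or more myopic parents never lower
        any point component."""
        assert score_ser(ser - d_ser, band) >= score_ser(ser, band)
        assert score_al(al + d_al, band) >= score_al(al, band)
        if parents < 2:
            assert score_parental(parents + 1, band) >= score_parental(parents, band)

    @pytest.mark.parametrize("band", list(Band))
    def test_band_exhaustiveness_on_fine_grid(self, band):
        """Every value on a fine SER/AL grid maps to exactly one point value
        (no gaps despite the printed 0.01 mm AL gaps)."""
        for ser in np.arange(-3.0, 4.0, 0.005):
            assert score_ser(float(ser), band) in (0, 1, 2, 3)
        for al in np.arange(20.0, 26.0, 0.0025):
            assert score_al(float(al), band) in (0, 1, 2, 3)

    def test_category_bins_round_trip(self):
        for total in range(10):
            label = assign_risk_category(total).label
            low, high = {
                RiskCategoryLabel.LITTLE_NO_RISK: (0, 0),
                RiskCategoryLabel.LOW: (1, 3),
                RiskCategoryLabel.MODERATE: (4, 6),
                RiskCategoryLabel.HIGH: (7, 9),
            }[label]
            assert low <= total <= high
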