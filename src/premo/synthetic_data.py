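"""Synthetic cohorts and exact fixture cohorts.

Two kinds of in-silico data support testing and demonstration, since the
original validation cohorts (a UK population study and a Hong Kong clinic
sample) are not publicly deposited:

``generate_cohort``
    Draws a cohort with the statistical structure the analysis assumes:
    correlated baseline SER/AL (longer eyes are less hyperopic, so the
    correlation is negative), multinomial parental myopia, and a myopia
    outcome whose probability follows a logistic function of the total risk
    score.  Calibrated presets emulate the published cohorts' incidences
    (~58% for the UK-like cohort, ~94% for the HK-like ones).

``fixture_from_confusion`` / ``fixture_for_singular_predictor``
    Deterministically reconstruct a cohort from a printed 2x2 contingency
    table so the full scoring + validation pipeline reproduces the printed
    sensitivity/specificity exactly.  Observations are built from real
    mid-band SER/AL/parental values that score to the intended totals
    through the scoring module -- totals are never injected directly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .cohort_io import CohortRecord, OutcomeLabel
from .exceptions import InputError
from .scoring import (
    BAND_MAX_TOTAL,
    Band,
    ChildObservation,
    EyePolicy,
    compute_premo_score,
)
from .validation import ConfusionCounts

_BAND_AGE_RANGE = {Band.AGE_6_8: (6.0, 8.99), Band.AGE_9_10: (9.0, 10.99)}

#: Mid-band factor values per band: for each point value, an (SER, AL) or
#: parent count that lands squarely inside the corresponding scoring band,
#: robust to any reasonable endpoint convention.
MIDBAND_SER_D = {
    Band.AGE_6_8: {0: 2.00, 2: 0.875, 3: 0.50},
    Band.AGE_9_10: {0: 1.50, 1: 0.625, 2: 0.20},
}
MIDBAND_AL_MM = {
    Band.AGE_6_8: {0: 22.50, 1: 23.00, 2: 23.15, 3: 23.40},
    Band.AGE_9_10: {0: 23.00, 1: 23.50, 2: 23.80},
}

#: One factor combination (n_parents, ser, al) per achievable total score.
TOTAL_RECIPES = {
    Band.AGE_6_8: {
        0: (0, 2.00, 22.50),
        1: (0, 2.00, 23.00),
        2: (0, 0.875, 22.50),
        3: (0, 0.875, 23.00),
        4: (0, 0.875, 23.15),
        5: (0, 0.50, 23.15),
        6: (0, 0.50, 23.40),
        7: (2, 0.875, 23.15),
        8: (1, 0.50, 23.40),
        9: (2, 0.50, 23.40),
    },
    Band.AGE_9_10: {
        0: (0, 1.50, 23.00),
        1: (0, 0.625, 23.00),
        2: (0, 0.625, 23.50),
        3: (0, 0.20, 23.50),
        4: (1, 0.20, 23.50),
        5: (1, 0.20, 23.80),
        6: (2, 0.20, 23.80),
    },
}

#: Published score-cutoff (>= 4) contingency counts for the three external
#: validation cohorts, keyed by cohort name.
PUBLISHED_SCORE_COUNTS: dict[str, tuple[Band, ConfusionCounts]] = {
    "uk_6_8": (Band.AGE_6_8, ConfusionCounts(tp=32, fp=1, tn=23, fn=1)),
    "hk_6_8": (Band.AGE_6_8, ConfusionCounts(tp=206, fp=5, tn=9, fn=14)),
    "hk_9_10": (Band.AGE_9_10, ConfusionCounts(tp=51, fp=5, tn=13, fn=6)),
}

#: Published singular-predictor contingency counts at ages 6-8, keyed by
#: (cohort, feature): SER < +0.75 D and AL >= 23.07 mm.
PUBLISHED_SINGULAR_COUNTS: dict[tuple[str, str], ConfusionCounts] = {
    ("uk_6_8", "ser"): ConfusionCounts(tp=32, fp=4, tn=20, fn=1),
    ("uk_6_8", "al"): ConfusionCounts(tp=17, fp=0, tn=24, fn=16),
    ("hk_6_8", "ser"): ConfusionCounts(tp=182, fp=2, tn=12, fn=38),
    ("hk_6_8", "al"): ConfusionCounts(tp=73, fp=2, tn=12, fn=147),
}

PRESETS = ("uk_6_8", "hk_6_8", "hk_9_10")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Baseline SER (dioptres) and AL (mm) are bivariate normal with
    correlation ``ser_al_corr`` (constrained non-positive), truncated to
    non-myopic baselines (SER > -0.50 D) by rejection.  The probability of
    becoming myopic by 15 is ``expit(onset_intercept + onset_slope *
    total)``.  A fraction ``p_outcome_ser_missing`` of the myopes have no
    follow-up SER and are labelled by carried-forward onset, mirroring
    clinic records that stop after myopia onset.
    """

    n: int
    band: Band
    parental_probs: tuple[float, float, float]
    ser_mean: float
    ser_sd: float
    al_mean: float
    al_sd: float
    ser_al_corr: float
    onset_intercept: float
    onset_slope: float
    outcome_ser_noise_sd: float
    seed: int
    age_mean: Optional[float] = None
    age_sd: float = 0.5
    eye_policy: EyePolicy = EyePolicy.MEAN
    p_outcome_ser_missing: float = 0.0
    interocular_ser_sd: float = 0.20
    interocular_al_sd: float = 0.10

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", Band(self.band))
        object.__setattr__(self, "eye_policy", EyePolicy(self.eye_policy))
        object.__setattr__(self, "parental_probs", tuple(self.parental_probs))
        if self.n <= 0:
            raise InputError(f"cohort size must be positive, got {self.n}")
        probs = np.asarray(self.parental_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise InputError(
                f"parental_probs must be 3 non-negative values summing to 1, "
                f"got {self.parental_probs}"
            )
        if self.ser_sd <= 0 or self.al_sd <= 0 or self.outcome_ser_noise_sd <= 0:
            raise InputError("standard deviations must be positive")
        if not -1.0 <= self.ser_al_corr <= 0.0:
            raise InputError(
                f"ser_al_corr must lie in [-1, 0], got {self.ser_al_corr}"
            )
        if not 0.0 <= self.p_outcome_ser_missing <= 1.0:
            raise InputError("p_outcome_ser_missing must lie in [0, 1]")


def load_preset(name: str, n: Optional[int] = None, seed: Optional[int] = None) -> CohortSpec:
    """Load a calibrated preset (``uk_6_8``, ``hk_6_8`` or ``hk_9_10``),
    optionally overriding cohort size and seed."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; available: {PRESETS}")
    text = (
        importlib.resources.files("premo") / "presets" / f"{name}.yaml"
    ).read_text(encoding="utf-8")
    params = yaml.safe_load(text)
    spec = CohortSpec(**params)
    if n is not None:
        spec = replace(spec, n=n)
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec


def _draw_truncated_baselines(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample (SER, AL) pairs with baseline SER > -0.50 D."""
    cov = np.array(
        [
            [spec.ser_sd**2, spec.ser_al_corr * spec.ser_sd * spec.al_sd],
            [spec.ser_al_corr * spec.ser_sd * spec.al_sd, spec.al_sd**2],
        ]
    )
    mean = np.array([spec.ser_mean, spec.al_mean])
    ser = np.empty(spec.n)
    al = np.empty(spec.n)
    filled = 0
    for _ in range(1000):
        batch = rng.multivariate_normal(mean, cov, size=max(spec.n, 256))
        keep = batch[batch[:, 0] > -0.50]
        take = min(spec.n - filled, keep.shape[0])
        ser[filled : filled + take] = keep[:take, 0]
        al[filled : filled + take] = keep[:take, 1]
        filled += take
        if filled == spec.n:
            return ser, al
    raise InputError(
        "could not draw enough non-myopic baselines; the SER distribution "
        f"(mean {spec.ser_mean} D) lies almost entirely below -0.50 D"
    )


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate a fully reproducible synthetic cohort from ``spec``.

    One seeded pseudo-random stream drives the whole cohort; the same spec
    always produces byte-identical records.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = _BAND_AGE_RANGE[spec.band]
    age_mean = spec.age_mean if spec.age_mean is not None else (lo + hi) / 2.0
    ages = np.clip(rng.normal(age_mean, spec.age_sd, spec.n), lo, hi)
    parents = rng.choice(3, size=spec.n, p=np.asarray(spec.parental_probs))
    ser, al = _draw_truncated_baselines(spec, rng)

    records: list[CohortRecord] = []
    for i in range(spec.n):
        if spec.eye_policy is EyePolicy.MEAN:
            obs = ChildObservation(
                child_id=f"sim_{i:05d}",
                age_years=float(ages[i]),
                n_myopic_parents=int(parents[i]),
                ser_mean=float(ser[i]),
                al_mean=float(al[i]),
                eye_policy=EyePolicy.MEAN,
            )
        else:
            # The drawn (SER, AL) pair is the least hyperopic eye; the
            # fellow eye is slightly more hyperopic and marginally shorter.
            fellow_ser = ser[i] + abs(rng.normal(0.0, spec.interocular_ser_sd))
            fellow_al = al[i] - abs(rng.normal(0.0, spec.interocular_al_sd))
            right_is_selected = rng.random() < 0.5
            obs = ChildObservation(
                child_id=f"sim_{i:05d}",
                age_years=float(ages[i]),
                n_myopic_parents=int(parents[i]),
                ser_right=float(ser[i] if right_is_selected else fellow_ser),
                ser_left=float(fellow_ser if right_is_selected else ser[i]),
                al_right=float(al[i] if right_is_selected else fellow_al),
                al_left=float(fellow_al if right_is_selected else al[i]),
                eye_policy=EyePolicy.LEAST_HYPEROPIC,
            )
        total = compute_premo_score(obs).total
        p_myopic = expit(spec.onset_intercept + spec.onset_slope * total)
        myopic = rng.random() < p_myopic

        if myopic:
            magnitude = abs(
                rng.normal(0.25 + 0.25 * total, spec.outcome_ser_noise_sd)
            )
            outcome_ser = -0.50 - magnitude
            if rng.random() < spec.p_outcome_ser_missing:
                # Clinic record stops after onset: carried forward as myopic.
                outcome = OutcomeLabel(
                    myopic=True,
                    basis="carried_forward_onset",
                    outcome_age_years=float(rng.uniform(9.0, 14.5)),
                )
            else:
                outcome = OutcomeLabel(
                    myopic=True,
                    basis="measured_at_15plus",
                    outcome_ser=float(outcome_ser),
                    outcome_age_years=float(15.0 + rng.uniform(0.0, 3.0)),
                )
        else:
            reserve = abs(
                rng.normal(
                    max(0.25, 1.0 - 0.10 * total), spec.outcome_ser_noise_sd
                )
            )
            outcome = OutcomeLabel(
                myopic=False,
                basis="measured_at_15plus",
                outcome_ser=float(-0.45 + reserve),
                outcome_age_years=float(15.0 + rng.uniform(0.0, 3.0)),
            )
        records.append(CohortRecord(observation=obs, outcome=outcome))
    return records


# ---------------------------------------------------------------------------
# Exact fixtures from printed contingency counts


@dataclass(frozen=True)
class FixtureRequest:
    counts: ConfusionCounts
    cutoff: int
    band: Band

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", Band(self.band))
        if self.counts.n == 0:
            raise InputError("fixture request with all-zero counts")
        max_total = BAND_MAX_TOTAL[self.band]
        if not 1 <= self.cutoff <= max_total:
            raise InputError(
                f"cutoff {self.cutoff} not realizable for band {self.band.value} "
                f"(totals 0..{max_total})"
            )


def _observation_for_total(
    child_id: str, band: Band, total: int
) -> ChildObservation:
    parents, ser, al = TOTAL_RECIPES[band][total]
    age = 7.0 if band is Band.AGE_6_8 else 9.5
    obs = ChildObservation(
        child_id=child_id,
        age_years=age,
        n_myopic_parents=parents,
        ser_mean=ser,
        al_mean=al,
        eye_policy=EyePolicy.MEAN,
    )
    achieved = compute_premo_score(obs).total
    assert achieved == total, f"recipe for total {total} scored {achieved}"
    return obs


def _outcome_for(myopic: bool, total: int) -> OutcomeLabel:
    # Outcome SER loosely tracks the risk score so rank statistics on
    # fixtures behave sensibly; classification only needs the label.
    if myopic:
        return OutcomeLabel(
            myopic=True,
            basis="measured_at_15plus",
            outcome_ser=-0.75 - 0.25 * total,
            outcome_age_years=16.0,
        )
    return OutcomeLabel(
        myopic=False,
        basis="measured_at_15plus",
        outcome_ser=1.00 - 0.10 * total,
        outcome_age_years=16.0,
    )


def fixture_from_confusion(req: FixtureRequest) -> list[CohortRecord]:
    """Build a deterministic cohort realizing the requested confusion table
    at the requested score cut-off.

    Called-positive records (tp, fp) cycle through the achievable totals
    from the cut-off upward, starting at the cut-off itself; called-negative
    records (fn, tn) cycle downward from cut-off - 1.  Every observation is
    a real measurement combination that scores to its total through the
    scoring module.
    """
    band = req.band
    max_total = BAND_MAX_TOTAL[band]
    pos_totals = list(range(req.cutoff, max_total + 1))
    neg_totals = list(range(req.cutoff - 1, -1, -1))

    records: list[CohortRecord] = []
    groups = (
        ("tp", req.counts.tp, pos_totals, True),
        ("fn", req.counts.fn, neg_totals, True),
        ("fp", req.counts.fp, pos_totals, False),
        ("tn", req.counts.tn, neg_totals, False),
    )
    for kind, count, totals, myopic in groups:
        for i in range(count):
            total = totals[i % len(totals)]
            records.append(
                CohortRecord(
                    observation=_observation_for_total(
                        f"{band.value}_{kind}_{i:04d}", band, total
                    ),
                    outcome=_outcome_for(myopic, total),
                )
            )
    return records


def fixture_for_singular_predictor(
    feature: str,
    cutoff: float,
    counts: ConfusionCounts,
    band: Band = Band.AGE_6_8,
) -> list[CohortRecord]:
    """Deterministic cohort whose raw SER or AL values realize the requested
    confusion table for a singular predictor (SER: positive below the
    cut-off; AL: positive at or above it)."""
    band = Band(band)
    if feature not in ("ser", "al"):
        raise InputError(f"singular predictor feature must be 'ser' or 'al', got {feature!r}")
    if counts.n == 0:
        raise InputError("fixture request with all-zero counts")

    if feature == "ser":
        pos_ser, neg_ser = cutoff - 0.25, cutoff + 0.50
        pos_al = neg_al = MIDBAND_AL_MM[band][0]
        if pos_ser <= -0.50:
            raise InputError("SER cut-off too low for non-myopic baselines")
        values = {True: (pos_ser, pos_al), False: (neg_ser, neg_al)}
    else:
        pos_ser = neg_ser = MIDBAND_SER_D[band][0]
        values = {True: (pos_ser, cutoff + 0.20), False: (neg_ser, cutoff - 0.50)}

    records: list[CohortRecord] = []
    groups = (
        ("tp", counts.tp, True, True),
        ("fn", counts.fn, False, True),
        ("fp", counts.fp, True, False),
        ("tn", counts.tn, False, False),
    )
    for kind, count, positive, myopic in groups:
        ser, al = values[positive]
        for i in range(count):
            obs = ChildObservation(
                child_id=f"{feature}_{kind}_{i:04d}",
                age_years=7.0 if band is Band.AGE_6_8 else 9.5,
                n_myopic_parents=0,
                ser_mean=ser,
                al_mean=al,
                eye_policy=EyePolicy.MEAN,
            )
            records.append(
                CohortRecord(observation=obs, outcome=_outcome_for(myopic, 0))
            )
    return records


def published_fixture(name: str) -> tuple[list[CohortRecord], int]:
    """Reconstruct one of the published score-cutoff validation cohorts
    (``uk_6_8``, ``hk_6_8``, ``hk_9_10``); returns (records, cutoff)."""
    if name not in PUBLISHED_SCORE_COUNTS:
        raise InputError(
            f"unknown cohort {name!r}; available: {sorted(PUBLISHED_SCORE_COUNTS)}"
        )
    band, counts = PUBLISHED_SCORE_COUNTS[name]
    from .validation import SCORE_CUTOFF

    records = fixture_from_confusion(
        FixtureRequest(counts=counts, cutoff=SCORE_CUTOFF, band=band)
    )
    return records, SCORE_CUTOFF


def published_singular_fixture(name: str, feature: str) -> list[CohortRecord]:
    """Reconstruct a published singular-predictor cohort for ``feature``
    ('ser' or 'al') in cohort ``name`` ('uk_6_8' or 'hk_6_8')."""
    key = (name, feature)
    if key not in PUBLISHED_SINGULAR_COUNTS:
        raise InputError(
            f"unknown singular cohort {key!r}; available: "
            f"{sorted(PUBLISHED_SINGULAR_COUNTS)}"
        )
    from .validation import AL_SINGULAR_CUTOFF_MM, SER_SINGULAR_CUTOFF_D

    cutoff = SER_SINGULAR_CUTOFF_D if feature == "ser" else AL_SINGULAR_CUTOFF_MM
    return fixture_for_singular_predictor(
        feature, cutoff, PUBLISHED_SINGULAR_COUNTS[key], band=Band.AGE_6_8
    )
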