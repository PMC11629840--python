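"""PreMO risk scoring for non-myopic children aged 6-10 years.

The risk indicator assigns integer points for three factors measured at a
baseline visit -- parental myopia (0/1/2 myopic parents), cycloplegic
spherical equivalent refraction (SER, dioptres) and axial length (AL, mm) --
using one of two age-banded point tables:

* ages 6-8 years: components up to (3, 3, 3), total 0-9
* ages 9-10 years: components up to (2, 2, 2), total 0-6

Higher totals indicate greater risk of becoming myopic during childhood.
Totals map onto four fixed risk categories (0 / 1-3 / 4-6 / 7-9).

Interval conventions
--------------------
The published SER bands are contiguous when the middle band is closed at
both ends ([+0.75, +1.00] D and [+0.375, +0.875] D); that convention is
adopted here.  The published AL bands are printed to 0.01 mm and therefore
leave gaps on the real line (e.g. 23.11 -> 23.12 mm); we close them with
half-open intervals anchored at the lower printed bound of each higher
band, so every finite AL maps to exactly one point value.

Where both eyes were measured, scoring uses the least hyperopic (most
emmetropic) eye: the eye with the algebraically smaller SER, with AL taken
from that same eye.  Cohorts that only record inter-ocular means use the
mean values directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .exceptions import AlreadyMyopicError, BandError, InputError

#: SER at or below this value (dioptres) defines myopia.
MYOPIA_SER_THRESHOLD_D = -0.50


class Band(str, Enum):
    """Age band selecting which point table applies."""

    AGE_6_8 = "age_6_8"
    AGE_9_10 = "age_9_10"


class EyePolicy(str, Enum):
    """How to collapse two-eye measurements into one scoring value."""

    LEAST_HYPEROPIC = "least_hyperopic"
    MEAN = "mean"


class RiskCategoryLabel(str, Enum):
    LITTLE_NO_RISK = "little_no_risk"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


#: Category bins over the total score, shared by both bands.  Band 9-10
#: totals cannot exceed 6, so its high-risk bin (7-9) is unreachable; the
#: bins are applied unchanged rather than rescaled.
CATEGORY_BINS = {
    RiskCategoryLabel.LITTLE_NO_RISK: (0, 0),
    RiskCategoryLabel.LOW: (1, 3),
    RiskCategoryLabel.MODERATE: (4, 6),
    RiskCategoryLabel.HIGH: (7, 9),
}

CATEGORY_OUTCOME_TEXT = {
    RiskCategoryLabel.LITTLE_NO_RISK: "likely to remain emmetropic",
    RiskCategoryLabel.LOW: "likely to be myopic by 16 years of age",
    RiskCategoryLabel.MODERATE: "likely to be myopic by 13 years of age",
    RiskCategoryLabel.HIGH: "likely to be myopic by 10 years of age",
}

#: Points for 0/1/2 myopic parents, per band.
PARENTAL_POINTS = {
    Band.AGE_6_8: (0, 2, 3),
    Band.AGE_9_10: (0, 1, 2),
}

#: SER bands as (lower_inclusive, upper_inclusive, points); the open outer
#: bands are encoded with infinities.  Middle bands are closed at both ends.
SER_BANDS_D = {
    Band.AGE_6_8: (
        (1.00, math.inf, 0),      # > +1.00 D (exclusive lower bound)
        (0.75, 1.00, 2),          # +0.75 to +1.00 D inclusive
        (-math.inf, 0.75, 3),     # < +0.75 D (exclusive upper bound)
    ),
    Band.AGE_9_10: (
        (0.875, math.inf, 0),
        (0.375, 0.875, 1),
        (-math.inf, 0.375, 2),
    ),
}

#: AL bands as (lower_inclusive, upper_exclusive, points); half-open, so the
#: printed 0.01 mm gaps are covered by the next band's lower bound.
AL_BANDS_MM = {
    Band.AGE_6_8: (
        (-math.inf, 22.94, 0),
        (22.94, 23.12, 1),
        (23.12, 23.19, 2),
        (23.19, math.inf, 3),
    ),
    Band.AGE_9_10: (
        (-math.inf, 23.33, 0),
        (23.33, 23.62, 1),
        (23.62, math.inf, 2),
    ),
}

#: Maximum total per band (also the sum of the per-factor maxima).
BAND_MAX_TOTAL = {Band.AGE_6_8: 9, Band.AGE_9_10: 6}


@dataclass(frozen=True)
class ChildObservation:
    """One child's baseline measurements and parental history.

    SER values are dioptres, AL values millimetres.  Either per-eye values
    (``ser_right``/``ser_left``, ``al_right``/``al_left``) or inter-ocular
    means (``ser_mean``, ``al_mean``) must be supplied, matching
    ``eye_policy``.
    """

    child_id: str
    age_years: float
    n_myopic_parents: int
    ser_right: Optional[float] = None
    ser_left: Optional[float] = None
    ser_mean: Optional[float] = None
    al_right: Optional[float] = None
    al_left: Optional[float] = None
    al_mean: Optional[float] = None
    eye_policy: EyePolicy = EyePolicy.LEAST_HYPEROPIC

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise InputError(f"age_years must be positive, got {self.age_years}")
        if self.n_myopic_parents not in (0, 1, 2):
            raise InputError(
                f"n_myopic_parents must be 0, 1 or 2, got {self.n_myopic_parents}"
            )
        policy = EyePolicy(self.eye_policy)
        object.__setattr__(self, "eye_policy", policy)
        if policy is EyePolicy.LEAST_HYPEROPIC:
            for name in ("ser_right", "ser_left", "al_right", "al_left"):
                if getattr(self, name) is None:
                    raise InputError(
                        f"eye_policy=least_hyperopic requires field '{name}'"
                    )
        else:
            for name in ("ser_mean", "al_mean"):
                if getattr(self, name) is None:
                    raise InputError(f"eye_policy=mean requires field '{name}'")


@dataclass(frozen=True)
class SelectedMeasures:
    """The single (SER, AL) pair actually scored, and which eye it came from."""

    ser: float
    al: float
    eye_used: str  # "right" | "left" | "mean"


@dataclass(frozen=True)
class RiskScore:
    band: Band
    parental_points: int
    ser_points: int
    al_points: int
    total: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total", self.parental_points + self.ser_points + self.al_points
        )


@dataclass(frozen=True)
class RiskCategory:
    label: RiskCategoryLabel
    predicted_outcome: str


def band_for_age(age_years: float) -> Band:
    """Route a baseline age to its point table.

    Ages in [6, 9) use the 6-8 table, [9, 11) the 9-10 table; anything else
    raises :class:`BandError` -- the indicator is not defined outside 6-10.
    """
    if 6.0 <= age_years < 9.0:
        return Band.AGE_6_8
    if 9.0 <= age_years < 11.0:
        return Band.AGE_9_10
    raise BandError(
        f"age {age_years} years is outside the supported bands (6-8 and 9-10)"
    )


def select_eye_measurements(obs: ChildObservation) -> SelectedMeasures:
    """Pick the (SER, AL) pair to score according to the observation's policy.

    Under ``least_hyperopic`` the eye with the algebraically smaller SER is
    chosen and its AL is used (SER and AL come from the same eye); an exact
    SER tie deterministically selects the right eye.  Under ``mean`` the
    supplied inter-ocular means are returned unchanged.
    """
    if obs.eye_policy is EyePolicy.MEAN:
        return SelectedMeasures(ser=obs.ser_mean, al=obs.al_mean, eye_used="mean")
    if obs.ser_left < obs.ser_right:
        return SelectedMeasures(ser=obs.ser_left, al=obs.al_left, eye_used="left")
    return SelectedMeasures(ser=obs.ser_right, al=obs.al_right, eye_used="right")


def score_parental(n_myopic_parents: int, band: Band) -> int:
    """Points for the number of myopic parents (0, 1 or 2)."""
    if n_myopic_parents not in (0, 1, 2):
        raise InputError(
            f"n_myopic_parents must be 0, 1 or 2, got {n_myopic_parents}"
        )
    return PARENTAL_POINTS[Band(band)][n_myopic_parents]


def _lookup_ser(ser: float, band: Band) -> int:
    for low, high, points in SER_BANDS_D[band]:
        if low == -math.inf:
            if ser < high:
                return points
        elif high == math.inf:
            if ser > low:
                return points
        elif low <= ser <= high:
            return points
    raise AssertionError(f"SER {ser} D matched no band")  # pragma: no cover


def score_ser(ser: float, band: Band) -> int:
    """Points for the baseline cycloplegic SER (dioptres).

    Lower (less hyperopic) SER means less hyperopic reserve and scores more
    points.  The middle band is closed at both ends.
    """
    if not math.isfinite(ser):
        raise InputError(f"SER must be finite, got {ser}")
    return _lookup_ser(ser, Band(band))


def score_al(al: float, band: Band) -> int:
    """Points for the baseline axial length (mm); longer eyes score more."""
    if not (math.isfinite(al) and al > 0):
        raise InputError(f"axial length must be finite and positive, got {al}")
    for low, high, points in AL_BANDS_MM[Band(band)]:
        if low <= al < high:
            return points
    raise AssertionError(f"AL {al} mm matched no band")  # pragma: no cover


def compute_premo_score(obs: ChildObservation) -> RiskScore:
    """Score one baseline observation: select the eye, route the age band,
    and sum the three factor points.

    Raises :class:`AlreadyMyopicError` if the selected SER is at or below
    -0.50 D, and :class:`BandError` for ages outside 6-10 years.
    """
    band = band_for_age(obs.age_years)
    selected = select_eye_measurements(obs)
    if selected.ser <= MYOPIA_SER_THRESHOLD_D:
        raise AlreadyMyopicError(
            f"child {obs.child_id!r}: selected SER {selected.ser:+.2f} D is already "
            f"myopic (<= {MYOPIA_SER_THRESHOLD_D:+.2f} D)"
        )
    return RiskScore(
        band=band,
        parental_points=score_parental(obs.n_myopic_parents, band),
        ser_points=score_ser(selected.ser, band),
        al_points=score_al(selected.al, band),
    )


def assign_risk_category(score: RiskScore | int) -> RiskCategory:
    """Map a total score to its risk category (0 / 1-3 / 4-6 / 7-9)."""
    total = score.total if isinstance(score, RiskScore) else int(score)
    for label, (low, high) in CATEGORY_BINS.items():
        if low <= total <= high:
            return RiskCategory(
                label=label, predicted_outcome=CATEGORY_OUTCOME_TEXT[label]
            )
    raise InputError(f"total score {total} outside the 0-9 category range")
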