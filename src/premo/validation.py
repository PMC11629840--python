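"""External-validation statistics for the risk indicator.

Given a scored cohort with resolved refractive outcomes this module
reproduces the standard evaluation of a screening score:

* ROC curve over all candidate cut-offs, with the area under the curve
  computed by the trapezoidal rule (equal, on every dataset, to the
  tie-corrected Mann-Whitney probability that a random future myope
  outranks a random non-myope);
* the Youden-optimal cut-off, J = sensitivity + specificity - 1, with ties
  broken toward the lowest (most sensitive) threshold -- in a screening
  context a miss is costlier than a false alarm;
* sensitivity / specificity / false-positive rate at a fixed cut-off, with
  their n/n fractions;
* a stratified percentile-bootstrap confidence interval for the AUC
  (child-level resampling within outcome classes; the choice of CI method
  is this package's own -- different software will give slightly different
  intervals);
* Spearman rank correlation between the total score and the follow-up SER,
  restricted to children with a measured SER at age >= 15;
* cohort incidence.

Three predictor conventions are supported: the total risk score (positive
when score >= cut-off), baseline axial length (positive when AL >= cut-off)
and baseline SER (positive when SER < cut-off, since less hyperopic reserve
means higher risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortRecord, spearman_eligible
from .exceptions import InputError, SingleClassError, UndefinedMetricError
from .scoring import (
    RiskCategory,
    RiskScore,
    SelectedMeasures,
    assign_risk_category,
    compute_premo_score,
    select_eye_measurements,
)

FEATURES = ("premo_score", "ser", "al")

#: Published singular-predictor cut-offs for ages 6-8: SER below +0.75 D,
#: AL at or above 23.07 mm (the 75th growth-chart centile).
SER_SINGULAR_CUTOFF_D = 0.75
AL_SINGULAR_CUTOFF_MM = 23.07
#: Risk-score cut-off (>= 4) identified as Youden-optimal in every cohort.
SCORE_CUTOFF = 4


@dataclass(frozen=True)
class ScoredRecord:
    """A cohort record with its selected measures, risk score and category."""

    record: CohortRecord
    selected: SelectedMeasures
    score: RiskScore
    category: RiskCategory

    @property
    def myopic(self) -> bool:
        return self.record.outcome.myopic


@dataclass(frozen=True)
class PredictorSpec:
    """A thresholded single-feature classifier.

    ``direction`` fixes the positive-call convention: ``ge`` calls positive
    when the feature is at or above the cut-off (risk score, AL), ``lt``
    when strictly below it (SER).
    """

    feature: str
    cutoff: float
    direction: str

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise InputError(f"unknown feature {self.feature!r}; expected {FEATURES}")
        if self.direction not in ("ge", "lt"):
            raise InputError(f"direction must be 'ge' or 'lt', got {self.direction!r}")

    @classmethod
    def premo(cls, cutoff: int = SCORE_CUTOFF) -> "PredictorSpec":
        return cls(feature="premo_score", cutoff=cutoff, direction="ge")

    @classmethod
    def ser(cls, cutoff: float = SER_SINGULAR_CUTOFF_D) -> "PredictorSpec":
        return cls(feature="ser", cutoff=cutoff, direction="lt")

    @classmethod
    def al(cls, cutoff: float = AL_SINGULAR_CUTOFF_MM) -> "PredictorSpec":
        return cls(feature="al", cutoff=cutoff, direction="ge")

    def label(self) -> str:
        op = ">=" if self.direction == "ge" else "<"
        return f"{self.feature} {op} {self.cutoff:g}"

    def is_positive(self, value: float) -> bool:
        return value >= self.cutoff if self.direction == "ge" else value < self.cutoff


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positives(self) -> int:
        """Number of children who became myopic."""
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    fpr: float
    youden_j: float


@dataclass(frozen=True)
class RocAnalysis:
    """ROC sweep for one feature on one cohort.

    ``thresholds`` are candidate cut-offs on the feature's native scale,
    ordered from most to least sensitive; a positive call follows the
    feature's direction convention (score/AL: value >= t; SER: value <= t).
    """

    feature: str
    direction: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutoff: float
    youden_j: float
    auc_ci: Optional[tuple[float, float]] = None


def score_cohort(records: Sequence[CohortRecord]) -> list[ScoredRecord]:
    """Score every record; raises on invalid baselines (records from
    ``read_cohort`` are pre-validated and always score)."""
    scored = []
    for record in records:
        score = compute_premo_score(record.observation)
        scored.append(
            ScoredRecord(
                record=record,
                selected=select_eye_measurements(record.observation),
                score=score,
                category=assign_risk_category(score),
            )
        )
    return scored


def feature_values(scored: Sequence[ScoredRecord], feature: str) -> np.ndarray:
    if feature == "premo_score":
        return np.array([s.score.total for s in scored], dtype=float)
    if feature == "ser":
        return np.array([s.selected.ser for s in scored], dtype=float)
    if feature == "al":
        return np.array([s.selected.al for s in scored], dtype=float)
    raise InputError(f"unknown feature {feature!r}; expected {FEATURES}")


def outcome_mask(scored: Sequence[ScoredRecord]) -> np.ndarray:
    return np.array([s.myopic for s in scored], dtype=bool)


def confusion_at_cutoff(
    scored: Sequence[ScoredRecord], spec: PredictorSpec
) -> ConfusionCounts:
    """Cross-tabulate predictor calls against outcomes at a fixed cut-off."""
    if len(scored) == 0:
        raise InputError("cannot tabulate an empty cohort")
    values = feature_values(scored, spec.feature)
    myopic = outcome_mask(scored)
    positive = (
        values >= spec.cutoff if spec.direction == "ge" else values < spec.cutoff
    )
    return ConfusionCounts(
        tp=int(np.sum(positive & myopic)),
        fp=int(np.sum(positive & ~myopic)),
        tn=int(np.sum(~positive & ~myopic)),
        fn=int(np.sum(~positive & myopic)),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, false-positive rate and Youden's J.

    Raw (unrounded) values are returned; rounding to two decimals happens
    only when a report is rendered.
    """
    if counts.n_positives == 0 or counts.n_negatives == 0:
        raise UndefinedMetricError(
            "metrics undefined: need at least one myope and one non-myope "
            f"(got {counts.n_positives} / {counts.n_negatives})"
        )
    sens = counts.tp / counts.n_positives
    spec = counts.tn / counts.n_negatives
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        fpr=counts.fp / counts.n_negatives,
        youden_j=sens + spec - 1.0,
    )


def _oriented(values: np.ndarray, feature: str) -> np.ndarray:
    """Map feature values onto a scale where larger always means riskier."""
    return -values if feature == "ser" else values


def _auc_from_oriented(risk: np.ndarray, myopic: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC (identical to the ROC trapezoid)."""
    n1 = int(myopic.sum())
    n0 = myopic.size - n1
    ranks = stats.rankdata(risk)
    u = ranks[myopic].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scored: Sequence[ScoredRecord], feature: str) -> RocAnalysis:
    """Sweep every distinct feature value as a cut-off and summarise.

    The AUC is the trapezoidal area over the (FPR, sensitivity) points with
    sentinel endpoints (0, 0) and (1, 1); the optimal cut-off maximises
    Youden's J, ties resolved toward the most sensitive threshold.
    """
    myopic = outcome_mask(scored)
    n1, n0 = int(myopic.sum()), int((~myopic).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError(
            f"single-class cohort (myopes={n1}, non-myopes={n0}): ROC undefined"
        )
    risk = _oriented(feature_values(scored, feature), feature)

    # Candidate thresholds: each distinct risk value, ascending; a positive
    # call is risk >= t, so the first threshold calls everyone positive.
    candidates = np.unique(risk)
    sens = np.empty(candidates.size + 1)
    spec = np.empty(candidates.size + 1)
    for i, t in enumerate(candidates):
        positive = risk >= t
        sens[i] = np.sum(positive & myopic) / n1
        spec[i] = np.sum(~positive & ~myopic) / n0
    sens[-1], spec[-1] = 0.0, 1.0  # sentinel: nobody called positive
    fpr = 1.0 - spec

    # In descending-threshold order the ROC points are non-decreasing in
    # both coordinates, running (0,0) -> (1,1); trapezoids over that path
    # handle tie diagonals exactly.
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens[:-1] + spec[:-1] - 1.0
    # lowest threshold among the maximisers; 1e-12 absorbs float noise in
    # mathematically tied J values
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    optimal_risk_cutoff = candidates[best]
    optimal_cutoff = float(
        -optimal_risk_cutoff if feature == "ser" else optimal_risk_cutoff
    )
    if feature == "premo_score":
        optimal_cutoff = int(optimal_cutoff)

    native_thresholds = (
        -candidates if feature == "ser" else candidates
    )
    return RocAnalysis(
        feature=feature,
        direction="le" if feature == "ser" else "ge",
        thresholds=native_thresholds,
        sensitivity=sens[:-1],
        specificity=spec[:-1],
        fpr=fpr[:-1],
        auc=auc,
        optimal_cutoff=optimal_cutoff,
        youden_j=float(j[best]),
    )


def auc_ci(
    scored: Sequence[ScoredRecord],
    feature: str,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC of ``feature``.

    Children are resampled with replacement within their outcome class, so
    every resample keeps both classes; a resample whose feature values are
    degenerate in a way that leaves the AUC undefined is redrawn, up to
    ``max_retries`` times.  Deterministic for a fixed seed.
    """
    myopic = outcome_mask(scored)
    risk = _oriented(feature_values(scored, feature), feature)
    return auc_ci_from_values(
        risk, myopic, n_boot=n_boot, seed=seed, alpha=alpha, max_retries=max_retries
    )


def auc_ci_from_values(
    risk: np.ndarray,
    myopic: np.ndarray,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Bootstrap CI on raw (risk value, outcome) pairs; see :func:`auc_ci`."""
    if n_boot < 100:
        raise InputError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise InputError("auc_ci requires an explicit seed")
    risk = np.asarray(risk, dtype=float)
    myopic = np.asarray(myopic, dtype=bool)
    n1, n0 = int(myopic.sum()), int((~myopic).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("single-class cohort: AUC CI undefined")
    cases = risk[myopic]
    controls = risk[~myopic]

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries + 1):
            case_sample = cases[rng.integers(0, n1, n1)]
            control_sample = controls[rng.integers(0, n0, n0)]
            sample = np.concatenate([case_sample, control_sample])
            labels = np.zeros(n1 + n0, dtype=bool)
            labels[:n1] = True
            aucs[b] = _auc_from_oriented(sample, labels)
            if math.isfinite(aucs[b]):
                break
        else:  # pragma: no cover - stratified resamples cannot degenerate
            raise SingleClassError("bootstrap resampling failed repeatedly")
    low, high = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def spearman_rho(scores: Sequence[float], outcome_ser: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties) between total
    scores and follow-up SER.  More myopic outcomes (more negative SER) at
    higher scores give a negative correlation."""
    scores = np.asarray(scores, dtype=float)
    outcome_ser = np.asarray(outcome_ser, dtype=float)
    if scores.size != outcome_ser.size:
        raise InputError("scores and outcome SERs must be paired")
    if scores.size < 3:
        raise InputError(f"need at least 3 pairs, got {scores.size}")
    if np.unique(scores).size == 1 or np.unique(outcome_ser).size == 1:
        raise UndefinedMetricError("rank correlation undefined for constant input")
    rho = stats.spearmanr(scores, outcome_ser).statistic
    return float(rho)


def incidence(records: Sequence[CohortRecord | ScoredRecord]) -> float:
    """Fraction of the cohort that became myopic (in [0, 1])."""
    if len(records) == 0:
        raise InputError("cannot compute incidence of an empty cohort")
    labels = [
        r.myopic if isinstance(r, ScoredRecord) else r.outcome.myopic
        for r in records
    ]
    return sum(labels) / len(labels)


# ---------------------------------------------------------------------------
# Consolidated report


@dataclass(frozen=True)
class PredictorResult:
    predictor: PredictorSpec
    counts: ConfusionCounts
    metrics: Metrics
    auc: float
    auc_ci: Optional[tuple[float, float]]
    optimal_cutoff: float
    optimal_youden_j: float

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor.label(),
            "feature": self.predictor.feature,
            "cutoff": self.predictor.cutoff,
            "direction": self.predictor.direction,
            "auc": self.auc,
            "auc_ci_low": None if self.auc_ci is None else self.auc_ci[0],
            "auc_ci_high": None if self.auc_ci is None else self.auc_ci[1],
            "sensitivity": self.metrics.sensitivity,
            "sensitivity_fraction": f"{self.counts.tp}/{self.counts.n_positives}",
            "specificity": self.metrics.specificity,
            "specificity_fraction": f"{self.counts.tn}/{self.counts.n_negatives}",
            "fpr": self.metrics.fpr,
            "fpr_fraction": f"{self.counts.fp}/{self.counts.n_negatives}",
            "youden_j": self.metrics.youden_j,
            "optimal_cutoff": self.optimal_cutoff,
            "optimal_youden_j": self.optimal_youden_j,
        }


@dataclass(frozen=True)
class ValidationReport:
    n: int
    n_myopes: int
    incidence: float
    rows: tuple[PredictorResult, ...]
    spearman: Optional[float]
    spearman_n: int
    seed: Optional[int] = None
    n_boot: Optional[int] = None

    def to_dict(self) -> dict:
        """Full-precision machine-readable form."""
        return {
            "n": self.n,
            "n_myopes": self.n_myopes,
            "incidence": self.incidence,
            "incidence_percent": round(100.0 * self.incidence),
            "spearman_rho": self.spearman,
            "spearman_n": self.spearman_n,
            "seed": self.seed,
            "n_boot": self.n_boot,
            "predictors": [row.to_dict() for row in self.rows],
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([row.to_dict() for row in self.rows])

    def to_text(self) -> str:
        """Human-readable rendering, rounded to two decimals like the
        published performance tables."""
        lines = [
            f"cohort n={self.n}, myopes={self.n_myopes}, "
            f"incidence {100 * self.incidence:.0f}%",
        ]
        if self.spearman is not None:
            lines.append(
                f"Spearman rho (score vs outcome SER, n={self.spearman_n}): "
                f"{self.spearman:.2f}"
            )
        for row in self.rows:
            m, c = row.metrics, row.counts
            ci = (
                ""
                if row.auc_ci is None
                else f" ({row.auc_ci[0]:.2f}-{row.auc_ci[1]:.2f})"
            )
            lines.append(
                f"{row.predictor.label()}: AUC {row.auc:.2f}{ci}, "
                f"sens {m.sensitivity:.2f} (n={c.tp}/{c.n_positives}), "
                f"spec {m.specificity:.2f} (n={c.tn}/{c.n_negatives}), "
                f"FPR {m.fpr:.2f} (n={c.fp}/{c.n_negatives}), "
                f"optimal cutoff {row.optimal_cutoff:g}"
            )
        return "\n".join(lines)


def validation_report(
    records: Sequence[CohortRecord],
    predictors: Sequence[PredictorSpec],
    n_boot: Optional[int] = None,
    seed: Optional[int] = None,
) -> ValidationReport:
    """Evaluate each predictor on the cohort and consolidate the results.

    Bootstrap AUC confidence intervals are computed only when both
    ``n_boot`` and ``seed`` are given.  The Spearman correlation between the
    total risk score and the follow-up SER uses only records with a measured
    SER at age >= 15 and is omitted when fewer than 3 such records exist.
    """
    scored = score_cohort(records)
    rows = []
    for spec in predictors:
        counts = confusion_at_cutoff(scored, spec)
        roc = roc_curve(scored, spec.feature)
        ci = (
            auc_ci(scored, spec.feature, n_boot=n_boot, seed=seed)
            if n_boot is not None and seed is not None
            else None
        )
        rows.append(
            PredictorResult(
                predictor=spec,
                counts=counts,
                metrics=metrics(counts),
                auc=roc.auc,
                auc_ci=ci,
                optimal_cutoff=roc.optimal_cutoff,
                optimal_youden_j=roc.youden_j,
            )
        )

    eligible = spearman_eligible(records)
    rho: Optional[float] = None
    if len(eligible) >= 3:
        eligible_scored = score_cohort(eligible)
        try:
            rho = spearman_rho(
                [s.score.total for s in eligible_scored],
                [s.record.outcome.outcome_ser for s in eligible_scored],
            )
        except UndefinedMetricError:
            rho = None

    n_myopes = sum(r.outcome.myopic for r in records)
    return ValidationReport(
        n=len(records),
        n_myopes=n_myopes,
        incidence=incidence(list(records)),
        rows=tuple(rows),
        spearman=rho,
        spearman_n=len(eligible),
        seed=seed,
        n_boot=n_boot,
    )
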