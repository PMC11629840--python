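"""Cohort CSV input/output and outcome labelling.

A cohort file is a UTF-8 CSV with one row per child:

``child_id, age_years, ser_right, ser_left, ser_mean, al_right, al_left,
al_mean, n_myopic_parents, outcome_age_years, outcome_ser, outcome_myopic``

Empty cells are missing values.  A row needs either both per-eye SER/AL
pairs (scored from the least hyperopic eye) or the inter-ocular means.

The refractive outcome is resolved under the definition myopia = SER <=
-0.50 D measured at age >= 15 years.  A child documented as having become
myopic before 15 with no later record is carried forward as myopic; a
non-myopic measurement before age 15 resolves nothing and the row is
rejected as unresolvable.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .exceptions import (
    InputError,
    OutcomeUnresolvableError,
    PremoError,
    SchemaError,
)
from .scoring import (
    MYOPIA_SER_THRESHOLD_D,
    ChildObservation,
    EyePolicy,
    compute_premo_score,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "child_id",
    "age_years",
    "ser_right",
    "ser_left",
    "ser_mean",
    "al_right",
    "al_left",
    "al_mean",
    "n_myopic_parents",
    "outcome_age_years",
    "outcome_ser",
    "outcome_myopic",
)

#: Minimum follow-up age (years) at which a measured SER defines the outcome.
OUTCOME_AGE_YEARS = 15.0


@dataclass(frozen=True)
class OutcomeLabel:
    """Myopic / non-myopic status at follow-up and how it was established.

    ``basis`` records the evidence: a SER measured at age >= 15
    (``measured_at_15plus``), a documented onset before 15 carried forward
    (``carried_forward_onset``, always myopic), or an explicit label
    (``explicit_label``).  Only labels backed by a measured SER at >= 15
    contribute to rank correlations against outcome refraction.
    """

    myopic: bool
    basis: str
    outcome_ser: Optional[float] = None
    outcome_age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.basis not in (
            "measured_at_15plus",
            "carried_forward_onset",
            "explicit_label",
        ):
            raise InputError(f"unknown outcome basis {self.basis!r}")
        if self.basis == "carried_forward_onset" and not self.myopic:
            raise InputError("carried-forward onset can only label a child myopic")

    @property
    def has_measured_outcome_ser(self) -> bool:
        """True when a follow-up SER at age >= 15 is available (usable for
        correlation against the score, not just classification)."""
        return (
            self.outcome_ser is not None
            and self.outcome_age_years is not None
            and self.outcome_age_years >= OUTCOME_AGE_YEARS
        )


@dataclass(frozen=True)
class CohortRecord:
    observation: ChildObservation
    outcome: OutcomeLabel


@dataclass(frozen=True)
class RowIssue:
    line: int
    child_id: Optional[str]
    reason: str


@dataclass(frozen=True)
class CohortReadResult:
    records: tuple[CohortRecord, ...]
    rejected: tuple[RowIssue, ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def label_outcome(
    outcome_ser: Optional[float] = None,
    outcome_age_years: Optional[float] = None,
    onset_before_15: Optional[bool] = None,
    explicit: Optional[bool] = None,
) -> OutcomeLabel:
    """Resolve a refractive outcome label from whatever evidence is present.

    Precedence: a SER measured at age >= 15 is authoritative (an explicit
    label may accompany it but must agree); otherwise an explicit label or a
    documented pre-15 onset is used.  Ages are compared against 15.0 exactly,
    without rounding.

    Raises
    ------
    OutcomeUnresolvableError
        If the only evidence is a SER measured before age 15, or no evidence
        at all.
    InputError
        If an explicit label contradicts a measured outcome SER.
    """
    measured_at_follow_up = (
        outcome_ser is not None
        and outcome_age_years is not None
        and outcome_age_years >= OUTCOME_AGE_YEARS
    )
    if measured_at_follow_up:
        myopic = outcome_ser <= MYOPIA_SER_THRESHOLD_D
        if explicit is not None and explicit != myopic:
            raise InputError(
                f"explicit outcome label ({explicit}) contradicts measured "
                f"outcome SER {outcome_ser:+.2f} D at age {outcome_age_years}"
            )
        return OutcomeLabel(
            myopic=myopic,
            basis="measured_at_15plus",
            outcome_ser=outcome_ser,
            outcome_age_years=outcome_age_years,
        )

    if explicit is True or onset_before_15 is True:
        onset_documented = onset_before_15 is True or (
            outcome_age_years is not None
            and outcome_age_years < OUTCOME_AGE_YEARS
        )
        return OutcomeLabel(
            myopic=True,
            basis="carried_forward_onset" if onset_documented else "explicit_label",
            outcome_ser=outcome_ser,
            outcome_age_years=outcome_age_years,
        )
    if explicit is False:
        if outcome_age_years is not None and outcome_age_years >= OUTCOME_AGE_YEARS:
            return OutcomeLabel(
                myopic=False,
                basis="explicit_label",
                outcome_age_years=outcome_age_years,
            )
        raise OutcomeUnresolvableError(
            "a non-myopic label before age 15 does not resolve the outcome"
        )
    raise OutcomeUnresolvableError(
        "outcome unresolvable: need a SER at age >= 15, a documented pre-15 "
        "onset, or an explicit label at >= 15"
    )


def _parse_float(value: str, column: str) -> Optional[float]:
    value = value.strip()
    if value == "":
        return None
    try:
        parsed = float(value)
    except ValueError as exc:
        raise InputError(f"column {column!r}: unparseable number {value!r}") from exc
    if not math.isfinite(parsed):
        raise InputError(f"column {column!r}: non-finite value {value!r}")
    return parsed


def _parse_bool(value: str, column: str) -> Optional[bool]:
    value = value.strip().lower()
    if value == "":
        return None
    if value in ("1", "true", "yes", "y"):
        return True
    if value in ("0", "false", "no", "n"):
        return False
    raise InputError(f"column {column!r}: unrecognised boolean {value!r}")


def _row_to_record(
    row: dict[str, str], assume_no_parental_myopia: bool
) -> CohortRecord:
    age_years = _parse_float(row["age_years"], "age_years")
    if age_years is None:
        raise InputError("column 'age_years': value is required")

    parents_raw = row["n_myopic_parents"].strip()
    if parents_raw == "":
        if not assume_no_parental_myopia:
            raise InputError(
                "column 'n_myopic_parents': missing (pass "
                "assume_no_parental_myopia=True to score it as 0)"
            )
        logger.warning(
            "child %r: missing parental myopia assumed to be 0", row["child_id"]
        )
        n_parents = 0
    else:
        parsed = _parse_float(parents_raw, "n_myopic_parents")
        if parsed != int(parsed):
            raise InputError(
                f"column 'n_myopic_parents': expected an integer, got {parents_raw!r}"
            )
        n_parents = int(parsed)

    ser_right = _parse_float(row["ser_right"], "ser_right")
    ser_left = _parse_float(row["ser_left"], "ser_left")
    al_right = _parse_float(row["al_right"], "al_right")
    al_left = _parse_float(row["al_left"], "al_left")
    per_eye = all(v is not None for v in (ser_right, ser_left, al_right, al_left))
    policy = EyePolicy.LEAST_HYPEROPIC if per_eye else EyePolicy.MEAN

    obs = ChildObservation(
        child_id=row["child_id"],
        age_years=age_years,
        n_myopic_parents=n_parents,
        ser_right=ser_right,
        ser_left=ser_left,
        ser_mean=_parse_float(row["ser_mean"], "ser_mean"),
        al_right=al_right,
        al_left=al_left,
        al_mean=_parse_float(row["al_mean"], "al_mean"),
        eye_policy=policy,
    )
    # Raises AlreadyMyopicError / BandError for invalid baselines.
    compute_premo_score(obs)

    outcome = label_outcome(
        outcome_ser=_parse_float(row["outcome_ser"], "outcome_ser"),
        outcome_age_years=_parse_float(row["outcome_age_years"], "outcome_age_years"),
        explicit=_parse_bool(row["outcome_myopic"], "outcome_myopic"),
    )
    return CohortRecord(observation=obs, outcome=outcome)


def read_cohort(
    path: str | Path, assume_no_parental_myopia: bool = False
) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Malformed rows (bad numbers, invariant violations, already-myopic
    baselines, unresolvable outcomes) are rejected individually with their
    line number; the remaining rows are returned as validated records.
    Accepted/rejected counts are logged.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")

        records: list[CohortRecord] = []
        rejected: list[RowIssue] = []
        for line_no, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, assume_no_parental_myopia))
            except PremoError as exc:
                rejected.append(
                    RowIssue(
                        line=line_no,
                        child_id=(row.get("child_id") or None),
                        reason=str(exc),
                    )
                )
    logger.info(
        "read %s: %d rows accepted, %d rejected", path, len(records), len(rejected)
    )
    for issue in rejected:
        logger.warning("rejected line %d (%s): %s", issue.line, issue.child_id, issue.reason)
    return CohortReadResult(records=tuple(records), rejected=tuple(rejected))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return repr(float(value)) if isinstance(value, float) else str(value)


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> int:
    """Write records back to the cohort CSV schema; returns the row count.

    ``write_cohort`` then ``read_cohort`` round-trips validated records
    (floats are written with full repr precision).
    """
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COHORT_COLUMNS)
        for record in records:
            obs, out = record.observation, record.outcome
            writer.writerow(
                [
                    obs.child_id,
                    _fmt(obs.age_years),
                    _fmt(obs.ser_right),
                    _fmt(obs.ser_left),
                    _fmt(obs.ser_mean),
                    _fmt(obs.al_right),
                    _fmt(obs.al_left),
                    _fmt(obs.al_mean),
                    obs.n_myopic_parents,
                    _fmt(out.outcome_age_years),
                    _fmt(out.outcome_ser),
                    _fmt(out.myopic),
                ]
            )
            n += 1
    logger.info("wrote %d records to %s", n, path)
    return n


def spearman_eligible(records: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Records with a measured outcome SER at age >= 15 (classification-only
    records, e.g. carried-forward onsets, are excluded)."""
    return [r for r in records if r.outcome.has_measured_outcome_ser]
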