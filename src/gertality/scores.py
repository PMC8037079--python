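"""Score calculators: GERtality, GTOS, ISS and maximum AIS.

GERtality is an additive bedside score for in-hospital mortality of
geriatric trauma patients.  Five binary criteria each contribute one point
when present:

=====================  =============================================
criterion              definition
=====================  =============================================
age_ge_80              age >= 80 years
max_ais_ge_4           maximum AIS in any body region >= 4
prbc_pre_icu           red-cell transfusion before ICU admission
asa_ge_3               pre-injury ASA physical status >= 3
gcs_le_13              Glasgow Coma Scale <= 13
=====================  =============================================

so the total ranges from 0 to 5.  GTOS (Geriatric Trauma Outcome Score) is
``age + 2.5 * ISS + 22`` (the 22 added only if transfused), and ISS is the
standard sum of squares of the three worst regional AIS grades, with any
AIS of 6 setting ISS to 75.

Missing components (GCS, ASA, transfusion status) are handled by an
explicit policy: ``zero_points`` scores unknown criteria as 0 points so the
score stays computable at the bedside with partial data; ``propagate_missing``
makes the whole score missing for complete-case analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional

from .types import Cohort, DomainError, PatientRecord


class CriterionStatus(str, enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    UNKNOWN = "unknown"


class MissingPolicy(str, enum.Enum):
    #: unknown components contribute 0 points
    ZERO_POINTS = "zero_points"
    #: any unknown component makes the total score missing
    PROPAGATE_MISSING = "propagate_missing"


@dataclass(frozen=True)
class Criterion:
    """A named binary criterion worth one point.

    ``predicate`` returns True/False, or None when the record lacks the
    inputs needed to evaluate it.
    """

    name: str
    predicate: Callable[[PatientRecord], Optional[bool]]

    def status(self, record: PatientRecord) -> CriterionStatus:
        result = self.predicate(record)
        if result is None:
            return CriterionStatus.UNKNOWN
        return CriterionStatus.MET if result else CriterionStatus.NOT_MET


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered list of named one-point criteria."""

    name: str
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise DomainError(f"duplicate criterion names: {names}")

    @property
    def max_score(self) -> int:
        return len(self.criteria)

    def components(self, record: PatientRecord) -> dict[str, CriterionStatus]:
        return {c.name: c.status(record) for c in self.criteria}

    def score(
        self,
        record: PatientRecord,
        missing_policy: MissingPolicy = MissingPolicy.ZERO_POINTS,
    ) -> Optional[int]:
        statuses = self.components(record).values()
        if (
            missing_policy is MissingPolicy.PROPAGATE_MISSING
            and CriterionStatus.UNKNOWN in statuses
        ):
            return None
        return sum(s is CriterionStatus.MET for s in statuses)


def threshold_criterion(variable: str, cutoff: float, direction: str) -> Criterion:
    """Build a one-point criterion from a dichotomization of a record field.

    ``direction`` is ``'ge'`` (value >= cutoff is exposed) or ``'le'``.
    Boolean fields (``prbc_pre_icu``) ignore the cutoff.  Names follow the
    ``<variable>_<direction>_<cutoff>`` convention used throughout.
    """
    if direction not in ("ge", "le"):
        raise DomainError(f"direction must be 'ge' or 'le', got {direction!r}")

    if variable == "prbc_pre_icu":
        return Criterion("prbc_pre_icu", lambda r: r.prbc_pre_icu)

    def getter(record: PatientRecord):
        if variable == "max_ais":
            return record.max_ais
        if variable == "iss":
            return iss(record)
        return getattr(record, variable)

    def predicate(record: PatientRecord) -> Optional[bool]:
        value = getter(record)
        if value is None:
            return None
        return value >= cutoff if direction == "ge" else value <= cutoff

    return Criterion(f"{variable}_{direction}_{int(cutoff)}", predicate)


def gertality_criteria() -> ScoreDefinition:
    """The five GERtality criteria, in their canonical order."""
    return ScoreDefinition(
        name="gertality",
        criteria=(
            threshold_criterion("age", 80, "ge"),
            threshold_criterion("max_ais", 4, "ge"),
            threshold_criterion("prbc_pre_icu", 1, "ge"),
            threshold_criterion("asa", 3, "ge"),
            threshold_criterion("gcs", 13, "le"),
        ),
    )


_GERTALITY = gertality_criteria()


def gertality_score(
    record: PatientRecord,
    missing_policy: MissingPolicy = MissingPolicy.ZERO_POINTS,
) -> Optional[int]:
    """GERtality points for one record (0-5, or None under propagation)."""
    return _GERTALITY.score(record, missing_policy)


def gertality_components(record: PatientRecord) -> dict[str, CriterionStatus]:
    return _GERTALITY.components(record)


def max_ais(record: PatientRecord) -> int:
    return record.max_ais


def iss(record: PatientRecord) -> int:
    """Injury Severity Score from the six-region AIS profile.

    Sum of squares of the three highest regional grades; any region graded
    6 forces the maximum of 75.
    """
    severities = sorted(record.ais_by_region.values(), reverse=True)
    if any(not 0 <= s <= 6 for s in severities):
        raise DomainError(f"AIS values out of range: {severities}")
    if severities[0] == 6:
        return 75
    return sum(s * s for s in severities[:3])


def gtos(record: PatientRecord) -> Optional[float]:
    """Geriatric Trauma Outcome Score: age + 2.5*ISS + 22 if transfused.

    Returns None when the transfusion flag is missing.
    """
    if record.prbc_pre_icu is None:
        return None
    return record.age + 2.5 * iss(record) + (22.0 if record.prbc_pre_icu else 0.0)


@dataclass(frozen=True)
class ScoredRecord:
    patient_id: str
    gertality_points: Optional[int]
    gertality_components: dict[str, CriterionStatus]
    gtos: Optional[float]
    iss: int
    max_ais: int


def score_record(
    record: PatientRecord,
    missing_policy: MissingPolicy = MissingPolicy.ZERO_POINTS,
) -> ScoredRecord:
    return ScoredRecord(
        patient_id=record.patient_id,
        gertality_points=gertality_score(record, missing_policy),
        gertality_components=gertality_components(record),
        gtos=gtos(record),
        iss=iss(record),
        max_ais=record.max_ais,
    )


def score_cohort(
    cohort: Cohort,
    missing_policy: MissingPolicy = MissingPolicy.ZERO_POINTS,
) -> list[ScoredRecord]:
    """One ScoredRecord per cohort record, in order."""
    return [score_record(r, missing_policy) for r in cohort.records]
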