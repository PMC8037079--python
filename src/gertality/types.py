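"""Domain types for patient-level trauma-registry records.

A :class:`PatientRecord` is one registry row: demographics, the per-region
anatomical injury profile (AIS, Abbreviated Injury Scale), physiology at
admission (GCS, systolic blood pressure), pre-injury health (ASA physical
status), treatment flags (pre-ICU red-cell transfusion, ICU admission) and
the in-hospital outcome.  A :class:`Cohort` is an ordered collection of
records together with an exclusion log that accounts for every record
removed by the inclusion filter, so that counts are always conserved.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Mechanism(str, enum.Enum):
    TRAFFIC = "traffic"
    LOW_FALL = "low_fall"
    HIGH_FALL = "high_fall"
    PENETRATING = "penetrating"
    OTHER = "other"
    UNKNOWN = "unknown"


class TransferStatus(str, enum.Enum):
    PRIMARY = "primary"
    TRANSFER_IN = "transfer_in"
    EARLY_TRANSFER_OUT = "early_transfer_out"


class HospitalRegion(str, enum.Enum):
    EUROPE = "europe"
    NON_EUROPE = "non_europe"


class ExclusionReason(str, enum.Enum):
    UNDER_65 = "under_65"
    NON_EUROPEAN = "non_european"
    TRANSFER = "transfer"
    MISSING_TRANSFUSION_DATA = "missing_transfusion_data"
    MINOR_TRAUMA_NO_ICU = "minor_trauma_no_icu"
    NONE = "none"


#: The six ISS body regions.  Extremities includes the pelvis.
BODY_REGIONS: tuple[str, ...] = (
    "head_neck",
    "face",
    "chest",
    "abdomen",
    "extremities",
    "external",
)


class DomainError(ValueError):
    """An input violates a domain contract (range, empty cohort, ...)."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or unsatisfiable."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row.

    AIS severities are taken as given integers in [0, 6] over the six ISS
    body regions; GCS in [3, 15] and ASA in [1, 4] when present.  ``None``
    means missing for the optional clinical fields.
    """

    patient_id: str
    age: int
    sex: Sex = Sex.UNKNOWN
    ais_by_region: Mapping[str, int] = field(
        default_factory=lambda: {r: 0 for r in BODY_REGIONS}
    )
    gcs: Optional[int] = None
    asa: Optional[int] = None
    sbp: Optional[int] = None
    prbc_pre_icu: Optional[bool] = None
    icu_admitted: bool = False
    mechanism: Mechanism = Mechanism.UNKNOWN
    transfer_status: TransferStatus = TransferStatus.PRIMARY
    region_of_hospital: HospitalRegion = HospitalRegion.EUROPE
    died_in_hospital: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise DomainError(f"age must be >= 0, got {self.age}")
        if set(self.ais_by_region) != set(BODY_REGIONS):
            raise DomainError(
                "ais_by_region must cover exactly the six ISS body regions "
                f"{BODY_REGIONS}, got {sorted(self.ais_by_region)}"
            )
        for region, severity in self.ais_by_region.items():
            if not 0 <= int(severity) <= 6:
                raise DomainError(
                    f"AIS for {region} must be in [0, 6], got {severity}"
                )
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise DomainError(f"GCS must be in [3, 15], got {self.gcs}")
        if self.asa is not None and not 1 <= self.asa <= 4:
            raise DomainError(f"ASA must be in [1, 4], got {self.asa}")
        if self.sbp is not None and self.sbp < 0:
            raise DomainError(f"SBP must be >= 0, got {self.sbp}")

    @property
    def max_ais(self) -> int:
        """Maximum AIS severity over the six body regions."""
        return max(self.ais_by_region.values())

    @property
    def n_injured_regions(self) -> int:
        return sum(1 for v in self.ais_by_region.values() if v > 0)


@dataclass
class Cohort:
    """Ordered records plus an exclusion log.

    Invariant maintained by the inclusion filter: every input record appears
    exactly once, either among the included ``records`` or in
    ``exclusion_log`` (keyed by patient id), so counts are conserved.
    """

    records: list[PatientRecord] = field(default_factory=list)
    exclusion_log: dict[str, ExclusionReason] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusion_log)
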