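"""Registry I/O and the cohort inclusion filter.

The single on-disk format is plain CSV (UTF-8, header row required).
Column names are configurable through a mapping from canonical field names
to the names used in a given export.  Booleans accept ``1/0/true/false/
yes/no`` (case-insensitive); an empty string means missing.

The inclusion filter mirrors a geriatric severe-trauma selection: patients
aged >= 65 treated primarily in a European hospital, with known
transfusion status, and either relevantly injured (maximum AIS >= 3) or
mildly injured (maximum AIS <= 2) but requiring intensive care.  Every
removed record is logged with the first matching reason in a fixed
precedence order so the exclusion log is deterministic.
"""

from __future__ import annotations

import statistics
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .types import (
    BODY_REGIONS,
    Cohort,
    DomainError,
    ExclusionReason,
    FormatError,
    HospitalRegion,
    Mechanism,
    PatientRecord,
    Sex,
    TransferStatus,
)

#: Canonical field name -> default CSV column name.
DEFAULT_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    **{f"ais_{r}": f"ais_{r}" for r in BODY_REGIONS},
    "gcs": "gcs",
    "asa": "asa",
    "sbp": "sbp",
    "prbc_pre_icu": "prbc_pre_icu",
    "icu_admitted": "icu_admitted",
    "mechanism": "mechanism",
    "transfer_status": "transfer_status",
    "region_of_hospital": "region_of_hospital",
    "died_in_hospital": "died_in_hospital",
}

REQUIRED_FIELDS = ("patient_id", "age", "died_in_hospital") + tuple(
    f"ais_{r}" for r in BODY_REGIONS
)

#: Fixed precedence of exclusion reasons when several rules fire at once.
EXCLUSION_PRECEDENCE = (
    ExclusionReason.UNDER_65,
    ExclusionReason.NON_EUROPEAN,
    ExclusionReason.TRANSFER,
    ExclusionReason.MISSING_TRANSFUSION_DATA,
    ExclusionReason.MINOR_TRAUMA_NO_ICU,
)

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(raw: str, field: str, row: str) -> Optional[bool]:
    s = raw.strip().lower()
    if s == "":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"row {row}: cannot parse boolean {field}={raw!r}")


def _parse_int(raw: str) -> Optional[int]:
    s = raw.strip()
    if s == "":
        return None
    return int(float(s))


def _parse_enum(raw: str, enum_cls, default):
    s = raw.strip().lower()
    if s == "":
        return default
    try:
        return enum_cls(s)
    except ValueError as err:
        raise FormatError(f"unknown {enum_cls.__name__} value {raw!r}") from err


def read_cohort(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> Cohort:
    """Read an unfiltered cohort from a CSV file.

    Unparseable optional fields become missing only when blank; malformed
    non-blank values raise.  Missing required columns raise
    :class:`FormatError` naming the column.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as err:
        raise FormatError(f"{path}: empty file (no header row)") from err
    for field in REQUIRED_FIELDS:
        if columns[field] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {columns[field]!r}"
            )

    def get(row, field: str) -> str:
        col = columns[field]
        return str(row[col]) if col in df.columns else ""

    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        pid = get(row, "patient_id").strip()
        age = _parse_int(get(row, "age"))
        died = _parse_bool(get(row, "died_in_hospital"), "died_in_hospital", pid)
        if age is None or died is None or pid == "":
            raise FormatError(
                f"{path}: row {idx}: required field blank "
                "(patient_id, age, died_in_hospital)"
            )
        ais = {}
        for region in BODY_REGIONS:
            sev = _parse_int(get(row, f"ais_{region}"))
            if sev is None:
                raise FormatError(f"{path}: row {idx}: blank AIS for {region}")
            ais[region] = sev
        icu = _parse_bool(get(row, "icu_admitted"), "icu_admitted", pid)
        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=_parse_enum(get(row, "sex"), Sex, Sex.UNKNOWN),
                ais_by_region=ais,
                gcs=_parse_int(get(row, "gcs")),
                asa=_parse_int(get(row, "asa")),
                sbp=_parse_int(get(row, "sbp")),
                prbc_pre_icu=_parse_bool(get(row, "prbc_pre_icu"), "prbc_pre_icu", pid),
                icu_admitted=bool(icu) if icu is not None else False,
                mechanism=_parse_enum(get(row, "mechanism"), Mechanism, Mechanism.UNKNOWN),
                transfer_status=_parse_enum(
                    get(row, "transfer_status"), TransferStatus, TransferStatus.PRIMARY
                ),
                region_of_hospital=_parse_enum(
                    get(row, "region_of_hospital"), HospitalRegion, HospitalRegion.EUROPE
                ),
                died_in_hospital=died,
            )
        )
    return Cohort(records=records)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "value"):  # enum
        return str(value.value)
    return str(value)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort records as a string-valued DataFrame in canonical columns."""
    rows = []
    for r in cohort.records:
        row = {
            "patient_id": r.patient_id,
            "age": str(r.age),
            "sex": r.sex.value,
            **{f"ais_{k}": str(v) for k, v in r.ais_by_region.items()},
            "gcs": _fmt(r.gcs),
            "asa": _fmt(r.asa),
            "sbp": _fmt(r.sbp),
            "prbc_pre_icu": _fmt(r.prbc_pre_icu),
            "icu_admitted": _fmt(r.icu_admitted),
            "mechanism": r.mechanism.value,
            "transfer_status": r.transfer_status.value,
            "region_of_hospital": r.region_of_hospital.value,
            "died_in_hospital": _fmt(r.died_in_hospital),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write records to CSV in canonical columns (round-trips with read_cohort)."""
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\n")


def write_exclusion_log(cohort: Cohort, path: str | Path) -> None:
    df = pd.DataFrame(
        [(pid, reason.value) for pid, reason in cohort.exclusion_log.items()],
        columns=["patient_id", "reason"],
    )
    df.to_csv(path, index=False, lineterminator="\n")


def exclusion_reason(
    record: PatientRecord,
    *,
    require_european: bool = True,
    require_primary: bool = True,
) -> Optional[ExclusionReason]:
    """First matching exclusion reason in precedence order, or None if kept."""
    checks = {
        ExclusionReason.UNDER_65: record.age < 65,
        ExclusionReason.NON_EUROPEAN: (
            require_european and record.region_of_hospital is not HospitalRegion.EUROPE
        ),
        ExclusionReason.TRANSFER: (
            require_primary and record.transfer_status is not TransferStatus.PRIMARY
        ),
        ExclusionReason.MISSING_TRANSFUSION_DATA: record.prbc_pre_icu is None,
        ExclusionReason.MINOR_TRAUMA_NO_ICU: (
            record.max_ais <= 2 and not record.icu_admitted
        ),
    }
    for reason in EXCLUSION_PRECEDENCE:
        if checks[reason]:
            return reason
    return None


def apply_inclusion_filter(
    cohort: Cohort,
    *,
    require_european: bool = True,
    require_primary: bool = True,
) -> Cohort:
    """Apply the geriatric severe-trauma inclusion criteria.

    Kept records satisfy: age >= 65, European hospital, primary admission,
    known pre-ICU transfusion status, and (max AIS >= 3, or max AIS <= 2
    with ICU admission).  Filtering an already-filtered cohort removes
    nothing further, and |included| + |excluded| equals the input count.
    """
    kept: list[PatientRecord] = []
    log: dict[str, ExclusionReason] = dict(cohort.exclusion_log)
    for record in cohort.records:
        reason = exclusion_reason(
            record,
            require_european=require_european,
            require_primary=require_primary,
        )
        if reason is None:
            kept.append(record)
        else:
            log[record.patient_id] = reason
    return Cohort(records=kept, exclusion_log=log)


def summarize_cohort(cohort: Cohort) -> dict:
    """Table-1-style cohort summary.

    Percentages are 100*count/n rounded to one decimal.  Raises
    :class:`DomainError` on an empty cohort.
    """
    from .scores import iss  # local import to avoid a cycle

    n = len(cohort.records)
    if n == 0:
        raise DomainError("cannot summarize an empty cohort")

    def pct(count: int) -> float:
        return round(100.0 * count / n, 1)

    ages = [r.age for r in cohort.records]
    isses = [iss(r) for r in cohort.records]
    n_regions = [r.n_injured_regions for r in cohort.records]
    deaths = sum(r.died_in_hospital for r in cohort.records)
    males = sum(r.sex is Sex.MALE for r in cohort.records)
    severe_head = sum(r.ais_by_region["head_neck"] >= 3 for r in cohort.records)
    icu = sum(r.icu_admitted for r in cohort.records)
    mech_counts = {
        m.value: sum(r.mechanism is m for r in cohort.records) for m in Mechanism
    }

    def moments(xs):
        return {
            "mean": round(statistics.fmean(xs), 1),
            "median": statistics.median(xs),
            "sd": round(statistics.stdev(xs), 1) if len(xs) > 1 else 0.0,
        }

    return {
        "n": n,
        "age": moments(ages),
        "iss": moments(isses),
        "n_injured_regions": moments(n_regions),
        "male_sex": {"n": males, "pct": pct(males)},
        "mechanism": {
            m: {"n": c, "pct": pct(c)} for m, c in mech_counts.items()
        },
        "severe_head_injury": {"n": severe_head, "pct": pct(severe_head)},
        "icu_treatment": {"n": icu, "pct": pct(icu)},
        "hospital_mortality": {"n": deaths, "pct": pct(deaths)},
    }
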