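"""Registry records, tumour-site classification and cohort descriptives.

A cancer-registry extract arrives as one row per patient (age at diagnosis,
sex, anatomical subsite, residential area, vital status, survival months).
This module classifies subsites into oral-cavity vs oropharyngeal cancer,
applies the under-15 exclusion used for adult oral cancer cohorts, tabulates
the descriptive summary, partitions deaths into 3-year / 5-year / later
strata, and aggregates records into the per-area observed counts that feed
the mapping model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "VitalStatus",
    "SiteClass",
    "RegistryRecord",
    "CohortSummary",
    "DEFAULT_SUBSITE_MAP",
    "classify_site",
    "apply_age_exclusion",
    "cohort_summary",
    "mortality_strata",
    "aggregate_counts",
    "read_registry_csv",
    "write_registry_csv",
]

AGE_EXCLUSION_YEARS = 15  # adults only: under-15 diagnoses are excluded


class Sex(str, Enum):
    female = "female"
    male = "male"


class VitalStatus(str, Enum):
    alive = "alive"
    dead = "dead"


class SiteClass(str, Enum):
    oral_cavity = "oral_cavity"
    oropharynx = "oropharynx"
    not_specified = "not_specified"


#: Anatomical subsite labels -> site class.  Oral cavity covers the anterior
#: tongue, floor of mouth, buccal/labial mucosa, gingiva, hard palate and
#: retromolar area; the oropharynx covers the tongue base, lingual and palatal
#: tonsils, soft palate and oropharyngeal walls.  User-extensible: pass an
#: augmented dict to :func:`classify_site` for local coding practice.
DEFAULT_SUBSITE_MAP: dict[str, SiteClass] = {
    "anterior tongue": SiteClass.oral_cavity,
    "floor of the mouth": SiteClass.oral_cavity,
    "buccal mucosa": SiteClass.oral_cavity,
    "labial mucosa": SiteClass.oral_cavity,
    "gingiva": SiteClass.oral_cavity,
    "hard palate": SiteClass.oral_cavity,
    "retromolar area": SiteClass.oral_cavity,
    "tongue base": SiteClass.oropharynx,
    "lingual tonsil": SiteClass.oropharynx,
    "palatal tonsil": SiteClass.oropharynx,
    "soft palate": SiteClass.oropharynx,
    "oropharyngeal wall": SiteClass.oropharynx,
}


@dataclass
class RegistryRecord:
    """One registry row: a patient with an oral/oropharyngeal cancer."""

    patient_id: str
    age_at_diagnosis: int
    sex: Sex
    subsite: str
    area_id: str
    vital_status: VitalStatus
    survival_months: int = 0
    grade: str = ""  # opaque category; carried but never computed on

    def __post_init__(self) -> None:
        if self.age_at_diagnosis < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        if self.survival_months < 0:
            raise ValueError(f"{self.patient_id}: negative survival time")


def classify_site(
    subsite: str, subsite_map: dict[str, SiteClass] | None = None
) -> SiteClass:
    """Map an anatomical subsite label to its site class.

    Unmapped labels fall back to ``not_specified`` (and are logged), matching
    how registries carry tumours whose precise subsite was never recorded.
    """
    mapping = DEFAULT_SUBSITE_MAP if subsite_map is None else subsite_map
    cls = mapping.get(subsite.strip().lower())
    if cls is None:
        logger.debug("unmapped subsite label %r -> not_specified", subsite)
        return SiteClass.not_specified
    return cls


def apply_age_exclusion(
    records: Iterable[RegistryRecord],
) -> tuple[list[RegistryRecord], list[tuple[RegistryRecord, str]]]:
    """Split records into (included, excluded) at age 15 (inclusive).

    Excluded records are kept with a reason tag for audit.
    """
    included, excluded = [], []
    for r in records:
        if r.age_at_diagnosis >= AGE_EXCLUSION_YEARS:
            included.append(r)
        else:
            excluded.append((r, f"age {r.age_at_diagnosis} < {AGE_EXCLUSION_YEARS}"))
    return included, excluded


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in cohort tables."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class CohortSummary:
    """Counts and one-decimal percentages over the included cohort."""

    n_included: int
    n_excluded_under15: int
    age_bands: dict[str, tuple[int, float]]
    sex: dict[str, tuple[int, float]]
    site: dict[str, tuple[int, float]]
    vital_status: dict[str, tuple[int, float]]
    grade: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variable, table in [
            ("age", self.age_bands),
            ("sex", self.sex),
            ("site", self.site),
            ("grade", self.grade),
            ("vital_status", self.vital_status),
        ]:
            for category, (count, pct) in table.items():
                rows.append(
                    {"variable": variable, "category": category,
                     "count": count, "percent": pct}
                )
        return pd.DataFrame(rows)


def _band(age: int) -> str:
    if age < 40:
        return "<40"
    if age <= 64:
        return "40-64"
    return ">=65"


def cohort_summary(
    records: Sequence[RegistryRecord],
    n_excluded_under15: int = 0,
    subsite_map: dict[str, SiteClass] | None = None,
) -> CohortSummary:
    """Tabulate the cohort by age band (<40, 40–64, ≥65), sex, site class,
    grade and vital status.  ``records`` must already be age-filtered."""
    if not records:
        raise ValueError("empty cohort: nothing to summarize")
    n = len(records)

    def tab(keys: Iterable[str], order: Sequence[str]) -> dict[str, tuple[int, float]]:
        counts: dict[str, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        ordered = [k for k in order if k in counts]
        ordered += [k for k in counts if k not in ordered]
        return {k: (counts[k], _pct(counts[k], n)) for k in ordered}

    summary = CohortSummary(
        n_included=n,
        n_excluded_under15=n_excluded_under15,
        age_bands=tab((_band(r.age_at_diagnosis) for r in records),
                      ["<40", "40-64", ">=65"]),
        sex=tab((r.sex.value for r in records), [s.value for s in Sex]),
        site=tab((classify_site(r.subsite, subsite_map).value for r in records),
                 [s.value for s in SiteClass]),
        vital_status=tab((r.vital_status.value for r in records),
                         [v.value for v in VitalStatus]),
    )
    if any(r.grade for r in records):
        summary.grade = tab((r.grade or "unknown" for r in records), [])
    return summary


def mortality_strata(records: Iterable[RegistryRecord]) -> dict[str, int]:
    """Partition deaths by survival time: within 3 years (≤36 months),
    3–5 years (37–60), and beyond 5 years (>60).  Strata sum to total deaths.
    """
    d36 = d60 = later = 0
    for r in records:
        if r.vital_status != VitalStatus.dead:
            continue
        if r.survival_months is None:
            raise ValueError(f"dead record {r.patient_id} has no survival time")
        if r.survival_months <= 36:
            d36 += 1
        elif r.survival_months <= 60:
            d60 += 1
        else:
            later += 1
    return {
        "deaths_within_36mo": d36,
        "deaths_37_to_60mo": d60,
        "deaths_after_60mo": later,
        "total_deaths": d36 + d60 + later,
    }


_STRATA = ("incidence", "overall_death", "death_within_36mo", "death_within_60mo")


def aggregate_counts(
    records: Iterable[RegistryRecord],
    area_ids: Sequence[str],
    stratum: str = "incidence",
) -> pd.Series:
    """Per-area observed counts O_i for one outcome stratum.

    ``incidence`` counts every record; the death strata count dead records,
    optionally restricted by survival months (≤36 or ≤60).
    """
    if stratum not in _STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; choose from {_STRATA}")
    counts = pd.Series(0, index=pd.Index(area_ids, name="area_id"), dtype=int)
    unknown = []
    for r in records:
        if stratum == "overall_death" and r.vital_status != VitalStatus.dead:
            continue
        if stratum == "death_within_36mo" and not (
            r.vital_status == VitalStatus.dead and r.survival_months <= 36
        ):
            continue
        if stratum == "death_within_60mo" and not (
            r.vital_status == VitalStatus.dead and r.survival_months <= 60
        ):
            continue
        if r.area_id not in counts.index:
            unknown.append(r.area_id)
            continue
        counts[r.area_id] += 1
    if unknown:
        raise ValueError(f"records reference unknown area_ids: {sorted(set(unknown))}")
    return counts


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["patient_id", "age", "sex", "subsite", "area_id",
                "vital_status", "survival_months", "grade"]


def read_registry_csv(path) -> list[RegistryRecord]:
    """Read a registry CSV (patient_id, age, sex, subsite, area_id,
    vital_status, survival_months[, grade])."""
    df = pd.read_csv(path, dtype={"patient_id": str, "area_id": str})
    missing = [c for c in _CSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        grade = getattr(row, "grade", "")
        records.append(
            RegistryRecord(
                patient_id=row.patient_id,
                age_at_diagnosis=int(row.age),
                sex=Sex(row.sex),
                subsite=str(row.subsite),
                area_id=row.area_id,
                vital_status=VitalStatus(row.vital_status),
                survival_months=int(row.survival_months),
                grade="" if pd.isna(grade) else str(grade),
            )
        )
    return records


def write_registry_csv(records: Sequence[RegistryRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age": r.age_at_diagnosis,
                "sex": r.sex.value,
                "subsite": r.subsite,
                "area_id": r.area_id,
                "vital_status": r.vital_status.value,
                "survival_months": r.survival_months,
                "grade": r.grade,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)
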