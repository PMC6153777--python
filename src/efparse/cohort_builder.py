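"""Patient-level cohort construction from note-level EF extractions.

Each patient's classifying EF is the one from their most recent
echocardiogram that yielded an extraction; echocardiograms from which no EF
could be extracted are ignored when picking the latest (an older extractable
echo still classifies the patient).  Ties on the same calendar date break by
note_id in lexicographic order (latest wins).  Patients whose every echo is
unextractable are reported separately, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .ef_normalization import (
    ClassificationThresholds,
    EFValue,
    QualitativeMap,
    classify_binary,
    classify_threeway,
)

__all__ = [
    "NoteEF",
    "PatientEFRecord",
    "CohortSummary",
    "latest_ef_per_patient",
    "build_cohort",
]


@dataclasses.dataclass(frozen=True)
class NoteEF:
    """One echocardiogram's extraction outcome, dated and patient-attributed.

    ``ef`` is None when no EF could be extracted from the note.
    """

    patient_id: str
    note_id: str
    note_date: datetime.date
    ef: EFValue | None


@dataclasses.dataclass(frozen=True)
class PatientEFRecord:
    """A patient's most recent extractable EF and derived cohort classes."""

    patient_id: str
    latest_note_id: str
    latest_note_date: datetime.date
    ef: EFValue
    binary_class: str
    threeway_class: str | None
    n_echos_seen: int
    n_echos_extractable: int


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Distribution tables over the patient records.

    ``pattern_group_table`` counts patients by the pattern group of their
    classifying mention; ``stratum_table`` counts numeric classifying EFs by
    three-way stratum (qualitative EFs are excluded, tracked separately in
    ``n_qualitative``).  Percentages are rounded half-up to integers; raw
    proportions are preserved alongside.
    """

    pattern_group_table: dict[str, dict[str, float]]
    stratum_table: dict[str, dict[str, float]]
    n_patients_total: int
    n_patients_hfref: int
    n_numeric: int
    n_qualitative: int


def latest_ef_per_patient(
    extractions: Iterable[NoteEF],
    thresholds: ClassificationThresholds | None = None,
    qmap: QualitativeMap | None = None,
) -> tuple[list[PatientEFRecord], list[str]]:
    """Reduce note-level EFs to one record per patient.

    Returns ``(records, excluded_patients)`` where ``excluded_patients`` are
    patients with echocardiograms but no extractable EF in any of them.
    Records are sorted by patient_id for deterministic output.
    """
    thresholds = thresholds or ClassificationThresholds()
    by_patient: dict[str, list[NoteEF]] = defaultdict(list)
    for item in extractions:
        by_patient[item.patient_id].append(item)

    records: list[PatientEFRecord] = []
    excluded: list[str] = []
    for patient_id in sorted(by_patient):
        items = by_patient[patient_id]
        extractable = [i for i in items if i.ef is not None]
        if not extractable:
            excluded.append(patient_id)
            continue
        latest = max(extractable, key=lambda i: (i.note_date, i.note_id))
        binary = (classify_binary(latest.ef, thresholds, qmap)
                  if (qmap is not None or latest.ef.kind != "qualitative")
                  else None)
        if binary is None:
            raise ValueError(
                "a QualitativeMap is required to classify qualitative EFs"
            )
        records.append(PatientEFRecord(
            patient_id=patient_id,
            latest_note_id=latest.note_id,
            latest_note_date=latest.note_date,
            ef=latest.ef,
            binary_class=binary,
            threeway_class=classify_threeway(latest.ef, thresholds),
            n_echos_seen=len(items),
            n_echos_extractable=len(extractable),
        ))
    return records, excluded


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def _table(counts: Counter, categories: Sequence[str]) -> dict[str, dict[str, float]]:
    total = sum(counts[c] for c in categories)
    table = {}
    for c in categories:
        n = counts[c]
        prop = n / total if total else 0.0
        table[c] = {"count": n, "percent": _round_half_up(100 * prop),
                    "proportion": prop}
    table["total"] = {"count": total, "percent": 100 if total else 0,
                      "proportion": 1.0 if total else 0.0}
    return table


def build_cohort(
    records: Sequence[PatientEFRecord],
    thresholds: ClassificationThresholds | None = None,
) -> tuple[list[PatientEFRecord], CohortSummary]:
    """Flag HFrEF membership and summarize the cohort's EF distributions.

    A patient is HFrEF iff the binary class of their latest EF is rEF.
    The stratum table covers numeric classifying EFs only; qualitative EFs
    participate in the binary cohort split via the lookup map but have no
    stratum.
    """
    del thresholds  # classes were fixed at record construction

    group_counts = Counter(r.ef.source_group for r in records)
    stratum_counts = Counter(
        r.threeway_class for r in records if r.threeway_class is not None
    )
    n_qual = sum(1 for r in records if r.ef.kind == "qualitative")
    summary = CohortSummary(
        pattern_group_table=_table(
            group_counts, ("tabular", "numerical", "range", "qualitative")
        ),
        stratum_table=_table(stratum_counts, ("HFrEF", "HFmEF", "HFpEF")),
        n_patients_total=len(records),
        n_patients_hfref=sum(1 for r in records if r.binary_class == "rEF"),
        n_numeric=len(records) - n_qual,
        n_qualitative=n_qual,
    )
    return list(records), summary
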