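"""Reading and writing note corpora, extraction outputs, and the unmatched log.

A corpus is a flat collection of clinical notes, each carrying the five-field
schema ``patient_id, note_id, note_type_code, note_date, text``.  Two on-disk
formats are supported: JSONL (one object per line, keys exactly the field
names) and CSV (header row of the same names), both UTF-8.

Echocardiogram identification is a two-step, human-in-the-loop process:
:func:`discover_echo_codes` surfaces note-type codes whose notes mention the
anchor phrase (sorted by frequency, with sampled note ids for manual review),
and :func:`is_echocardiogram` then filters against an explicit, config-supplied
accept list.  Acceptance is never inferred automatically from a code prefix.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import random
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ClinicalNote",
    "EchoCodeCandidate",
    "UnmatchedLogEntry",
    "CorpusSchemaError",
    "DuplicateNoteError",
    "ConfigurationError",
    "NOTE_FIELDS",
    "UNMATCHED_STAGES",
    "EXTRACTION_FIELDS",
    "read_notes",
    "write_notes",
    "read_extractions",
    "write_extractions",
    "discover_echo_codes",
    "is_echocardiogram",
    "read_unmatched_log",
    "write_unmatched_log",
    "export_unmatched_sample",
]

NOTE_FIELDS = ("patient_id", "note_id", "note_type_code", "note_date", "text")

#: Columns of the note-level extraction output.
EXTRACTION_FIELDS = (
    "note_id", "patient_id", "note_date", "pattern_group", "raw_snippet",
    "span_start", "span_end", "value_low", "value_high", "qualitative_key",
)

#: Stages at which a note can drop out of the extraction cascade.
UNMATCHED_STAGES = (
    "not-echo",
    "no-anchor-keywords",
    "no-lv-section",
    "no-pattern-matched",
)


class CorpusSchemaError(ValueError):
    """A corpus record violates the five-field note schema."""


class DuplicateNoteError(ValueError):
    """Two records in one corpus share a note_id."""


class ConfigurationError(ValueError):
    """A required configuration value is missing or invalid."""


@dataclasses.dataclass(frozen=True)
class ClinicalNote:
    """One clinical note: the pipeline's atomic input.

    ``note_date`` is a calendar date; dates are accepted in ISO-8601 only so
    that the latest-echocardiogram ordering is unambiguous.  ``text`` may be
    empty — an empty note simply yields a no-pattern result downstream.
    """

    patient_id: str
    note_id: str
    note_type_code: str
    note_date: datetime.date
    text: str


@dataclasses.dataclass(frozen=True)
class EchoCodeCandidate:
    """A note-type code proposed for human review as an echocardiogram code."""

    note_type_code: str
    note_count: int
    corpus_fraction: float
    sample_note_ids: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class UnmatchedLogEntry:
    """One note that produced no extraction, with the stage it dropped out at."""

    note_id: str
    stage_reached: str
    excerpt: str


def _parse_date(raw: object, note_id: object, lineno: int) -> datetime.date:
    if isinstance(raw, datetime.date):
        return raw
    try:
        return datetime.date.fromisoformat(str(raw))
    except ValueError:
        raise CorpusSchemaError(
            f"unparseable ISO-8601 note_date {raw!r} for note_id {note_id!r} "
            f"(record {lineno})"
        ) from None


def _build_note(record: dict, lineno: int) -> ClinicalNote:
    for field in NOTE_FIELDS:
        if field not in record or record[field] is None:
            raise CorpusSchemaError(
                f"record {lineno} is missing required field {field!r}"
            )
    return ClinicalNote(
        patient_id=str(record["patient_id"]),
        note_id=str(record["note_id"]),
        note_type_code=str(record["note_type_code"]),
        note_date=_parse_date(record["note_date"], record["note_id"], lineno),
        text=str(record["text"]),
    )


def read_notes(path: str | Path, format: str = "jsonl") -> list[ClinicalNote]:
    """Read a note corpus from ``path`` in file order.

    Parameters
    ----------
    path:
        File containing one record per note.
    format:
        ``"jsonl"`` or ``"csv"``.

    Raises
    ------
    CorpusSchemaError
        If a record is missing a field or carries an unparseable date.
    DuplicateNoteError
        If two records share a note_id.
    """
    path = Path(path)
    records: list[tuple[int, dict]] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                records.append((lineno, json.loads(line)))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(NOTE_FIELDS) - set(reader.fieldnames or ())
            if missing:
                raise CorpusSchemaError(
                    f"CSV header is missing field(s) {sorted(missing)}"
                )
            for lineno, row in enumerate(reader, start=2):
                records.append((lineno, row))
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    for lineno, record in records:
        note = _build_note(record, lineno)
        if note.note_id in seen:
            raise DuplicateNoteError(
                f"duplicate note_id {note.note_id!r} at record {lineno}"
            )
        seen.add(note.note_id)
        notes.append(note)
    return notes


def write_notes(notes: Iterable[ClinicalNote], path: str | Path,
                format: str = "jsonl") -> None:
    """Write notes to ``path``; inverse of :func:`read_notes`."""
    path = Path(path)
    rows = [
        {
            "patient_id": n.patient_id,
            "note_id": n.note_id,
            "note_type_code": n.note_type_code,
            "note_date": n.note_date.isoformat(),
            "text": n.text,
        }
        for n in notes
    ]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=NOTE_FIELDS)
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def write_extractions(rows: Iterable[dict], path: str | Path,
                      format: str = "csv") -> None:
    """Write note-level extraction rows (one per extracted mention)."""
    path = Path(path)
    rows = list(rows)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=EXTRACTION_FIELDS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if row.get(k) is None else row[k])
                                 for k in EXTRACTION_FIELDS})
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps({k: row.get(k) for k in EXTRACTION_FIELDS},
                                    ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown extraction format {format!r}")


def read_extractions(path: str | Path, format: str = "csv") -> list[dict]:
    """Read extraction rows back; numeric fields parsed, blanks -> None."""
    path = Path(path)
    raw_rows: list[dict] = []
    if format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            raw_rows = list(csv.DictReader(fh))
    elif format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            raw_rows = [json.loads(line) for line in fh if line.strip()]
    else:
        raise ValueError(f"unknown extraction format {format!r}")
    rows = []
    for raw in raw_rows:
        row = dict(raw)
        for key in ("span_start", "span_end"):
            row[key] = int(row[key]) if row.get(key) not in ("", None) else None
        for key in ("value_low", "value_high"):
            row[key] = (float(row[key])
                        if row.get(key) not in ("", None) else None)
        if row.get("qualitative_key") == "":
            row["qualitative_key"] = None
        rows.append(row)
    return rows


def _collapse_ws(s: str) -> str:
    return " ".join(s.lower().split())


def discover_echo_codes(
    notes: Sequence[ClinicalNote],
    anchor_phrase: str = "ejection fraction",
    min_fraction: float = 0.01,
    sample_k: int = 3,
    seed: int = 0,
) -> list[EchoCodeCandidate]:
    """Propose note-type codes likely to denote echocardiogram reports.

    Notes containing ``anchor_phrase`` (case-insensitive, internal whitespace
    collapsed) are grouped by note-type code; codes covering at least
    ``min_fraction`` of the anchor-bearing notes are returned in descending
    note-count order, each with up to ``sample_k`` randomly sampled note ids
    for manual review.  The accept list itself is a human/config decision —
    this function only emits candidates.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if sample_k < 1:
        raise ValueError("sample_k must be >= 1")
    phrase = _collapse_ws(anchor_phrase)
    by_code: dict[str, list[str]] = defaultdict(list)
    total = 0
    for note in notes:
        if phrase in _collapse_ws(note.text):
            by_code[note.note_type_code].append(note.note_id)
            total += 1
    if total == 0:
        return []
    rng = random.Random(seed)
    candidates = []
    # deterministic order: count desc, code asc
    for code in sorted(by_code, key=lambda c: (-len(by_code[c]), c)):
        ids = by_code[code]
        fraction = len(ids) / total
        if fraction < min_fraction:
            continue
        sample = ids if len(ids) <= sample_k else rng.sample(ids, sample_k)
        candidates.append(
            EchoCodeCandidate(
                note_type_code=code,
                note_count=len(ids),
                corpus_fraction=fraction,
                sample_note_ids=tuple(sample),
            )
        )
    return candidates


def is_echocardiogram(note: ClinicalNote, accept_codes: set[str] | frozenset[str]) -> bool:
    """True iff the note's type code is on the explicit accept list."""
    if not accept_codes:
        raise ConfigurationError(
            "echo_codes accept list is empty; echocardiogram filtering requires "
            "an explicit list of accepted note-type codes"
        )
    return note.note_type_code in accept_codes


def write_unmatched_log(entries: Iterable[UnmatchedLogEntry],
                        path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(dataclasses.asdict(e), ensure_ascii=False) + "\n")


def read_unmatched_log(path: str | Path) -> list[UnmatchedLogEntry]:
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            entries.append(UnmatchedLogEntry(
                note_id=d["note_id"],
                stage_reached=d["stage_reached"],
                excerpt=d["excerpt"],
            ))
    return entries


def export_unmatched_sample(
    log: Sequence[UnmatchedLogEntry],
    stage: str,
    n: int,
    seed: int = 0,
) -> list[UnmatchedLogEntry]:
    """Sample unmatched-log entries at one stage for manual review.

    Drives the iterative pattern-development loop: a reviewer inspects the
    sample and either extends an existing pattern or writes a new one.
    Sampling is uniform without replacement and seeded; if fewer than ``n``
    entries exist at the stage, all are returned (in log order).
    """
    if stage not in UNMATCHED_STAGES:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {UNMATCHED_STAGES}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [e for e in log if e.stage_reached == stage]
    if len(pool) <= n:
        return pool
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(pool)), n))
    return [pool[i] for i in idx]
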