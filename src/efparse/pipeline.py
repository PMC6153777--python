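"""End-to-end composition: echo filtering -> sectioning -> cascade -> normalization.

One call, :func:`process_corpus`, runs every note of a corpus through the
pipeline and returns per-note outcomes plus the unmatched log.  Conservation
holds by construction: every processed note lands in exactly one of the two —
an extraction outcome with a mention, or an unmatched-log entry recording the
stage it dropped out at (not-echo, no-anchor-keywords, no-lv-section,
no-pattern-matched).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .cohort_builder import NoteEF
from .corpus_io import ClinicalNote, UnmatchedLogEntry, is_echocardiogram
from .ef_extraction import ExtractionResult, extract_ef
from .ef_normalization import (
    ClassificationThresholds,
    EFValue,
    classify_binary,
    classify_threeway,
    qualitative_map_from_config,
    normalize,
)
from .sectioner import SectionHeadingSet

__all__ = [
    "NoteOutcome",
    "PipelineOutput",
    "process_corpus",
    "heading_set_from_config",
    "extraction_rows",
]

_EXCERPT_CHARS = 120


def heading_set_from_config(config: Mapping) -> SectionHeadingSet:
    sec = config["sections"]
    return SectionHeadingSet(headings=tuple(sec["headings"]),
                             lv_heading_aliases=tuple(sec["lv_aliases"]))


@dataclasses.dataclass(frozen=True)
class NoteOutcome:
    """Everything the pipeline derived from one echocardiogram note."""

    note: ClinicalNote
    result: ExtractionResult
    ef: EFValue | None
    binary_class: str | None
    threeway_class: str | None


@dataclasses.dataclass(frozen=True)
class PipelineOutput:
    outcomes: tuple[NoteOutcome, ...]       # echo notes, extracted or not
    unmatched: tuple[UnmatchedLogEntry, ...]
    n_processed: int
    n_echo: int
    n_extracted: int

    def note_efs(self) -> list[NoteEF]:
        """Dated, patient-attributed EFs for cohort construction."""
        return [
            NoteEF(patient_id=o.note.patient_id, note_id=o.note.note_id,
                   note_date=o.note.note_date, ef=o.ef)
            for o in self.outcomes
        ]


def extraction_rows(output: PipelineOutput) -> list[dict]:
    """Serialize extracted mentions as flat rows for ``write_extractions``."""
    rows = []
    for o in output.outcomes:
        m = o.result.mention
        if m is None:
            continue
        if m.pattern_group == "range":
            low, high = m.low, m.high
        elif m.value is not None:
            low = high = m.value
        else:
            low = high = None
        rows.append({
            "note_id": o.note.note_id,
            "patient_id": o.note.patient_id,
            "note_date": o.note.note_date.isoformat(),
            "pattern_group": m.pattern_group,
            "raw_snippet": m.raw_snippet,
            "span_start": m.char_span[0],
            "span_end": m.char_span[1],
            "value_low": low,
            "value_high": high,
            "qualitative_key": m.qualitative_key,
        })
    return rows


def process_corpus(
    notes: Sequence[ClinicalNote],
    config: Mapping,
) -> PipelineOutput:
    """Run the full pipeline over a corpus.

    Non-echocardiogram notes are logged at stage ``not-echo`` and skipped.
    Echo notes run the cascade; mentions are normalized and classified, and
    stage outcomes are logged. ``n_processed == len(outcomes with mention) +
    len(unmatched)`` always.
    """
    headings = heading_set_from_config(config)
    qmap = qualitative_map_from_config(config)
    thresholds = ClassificationThresholds.from_config(config)
    accept = set(config["echo_codes"])

    outcomes: list[NoteOutcome] = []
    unmatched: list[UnmatchedLogEntry] = []
    for note in notes:
        if not is_echocardiogram(note, accept):
            unmatched.append(UnmatchedLogEntry(
                note_id=note.note_id, stage_reached="not-echo",
                excerpt=note.text[:_EXCERPT_CHARS]))
            continue
        result = extract_ef(note, headings, config)
        if result.mention is None:
            unmatched.append(UnmatchedLogEntry(
                note_id=note.note_id, stage_reached=result.stage,
                excerpt=note.text[:_EXCERPT_CHARS]))
            outcomes.append(NoteOutcome(note, result, None, None, None))
            continue
        ef = normalize(result.mention, qmap)
        outcomes.append(NoteOutcome(
            note=note, result=result, ef=ef,
            binary_class=classify_binary(ef, thresholds, qmap),
            threeway_class=classify_threeway(ef, thresholds),
        ))
    return PipelineOutput(
        outcomes=tuple(outcomes),
        unmatched=tuple(unmatched),
        n_processed=len(notes),
        n_echo=sum(1 for o in outcomes),
        n_extracted=sum(1 for o in outcomes if o.ef is not None),
    )
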