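"""Section-heading discovery and note segmentation.

Echocardiography reports are organised as per-chamber narrative sections
("LEFT VENTRICLE:", "RIGHT VENTRICLE:", ...) under free-form preamble text.
Headings are discovered empirically — the most frequent lines across a corpus
are candidate headings, curated by a human into a heading set — and each note
is then sliced into labelled sections at lines whose normalized form is in
that set.

A heading must occupy its own line (after trimming) to count as a boundary;
inline occurrences of heading words never split a section.  Normalization is
lowercase + trim + strip one trailing colon, which is idempotent.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Sequence

from .corpus_io import ClinicalNote

__all__ = [
    "PREAMBLE",
    "SectionHeadingSet",
    "Section",
    "SectionedReport",
    "normalize_heading",
    "discover_headings",
    "segment",
    "find_lv_section",
]

#: Sentinel heading for text before the first recognized heading.
PREAMBLE = "__preamble__"


def normalize_heading(line: str) -> str:
    """Lowercase, trim, and strip one trailing colon. Idempotent."""
    s = line.strip().lower()
    if s.endswith(":"):
        s = s[:-1].rstrip()
    return s


@dataclasses.dataclass(frozen=True)
class SectionHeadingSet:
    """Curated set of section headings plus the aliases naming the LV section."""

    headings: tuple[str, ...]
    lv_heading_aliases: tuple[str, ...] = ("left ventricle",)

    def __post_init__(self):
        norm = tuple(dict.fromkeys(normalize_heading(h) for h in self.headings))
        object.__setattr__(self, "headings", norm)
        object.__setattr__(
            self,
            "lv_heading_aliases",
            tuple(dict.fromkeys(normalize_heading(a) for a in self.lv_heading_aliases)),
        )

    def is_heading(self, line: str) -> bool:
        return normalize_heading(line) in set(self.headings)

    def is_lv(self, heading: str) -> bool:
        return normalize_heading(heading) in set(self.lv_heading_aliases)


@dataclasses.dataclass(frozen=True)
class Section:
    heading: str  # normalized heading, or PREAMBLE
    body: str
    char_span: tuple[int, int]  # half-open, includes the heading line


@dataclasses.dataclass(frozen=True)
class SectionedReport:
    note_id: str
    text: str
    sections: tuple[Section, ...]


def discover_headings(
    notes: Iterable[ClinicalNote],
    top_n: int = 20,
    min_count: int = 2,
) -> list[tuple[str, int]]:
    """Rank normalized line frequencies across a corpus as heading candidates.

    Returns up to ``top_n`` (line, count) pairs with count >= ``min_count``,
    in descending count order, ties broken lexicographically.  The output is
    meant for human curation into a :class:`SectionHeadingSet`.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: Counter[str] = Counter()
    for note in notes:
        for line in note.text.splitlines():
            norm = normalize_heading(line)
            if norm:
                counts[norm] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(line, c) for line, c in ranked if c >= min_count][:top_n]


def segment(note: ClinicalNote, headings: SectionHeadingSet) -> SectionedReport:
    """Slice a note into sections at recognized heading lines.

    Every character of the original text belongs to exactly one section span
    (spans are disjoint, ordered, and tile ``[0, len(text))``); a section's
    span includes its heading line, while ``body`` is the text after it.  Text
    before the first recognized heading becomes a single PREAMBLE section; a
    note with no recognized heading yields one PREAMBLE section, and an empty
    note yields no sections.
    """
    if not headings.headings:
        raise ValueError("heading set is empty")
    text = note.text
    if not text:
        return SectionedReport(note_id=note.note_id, text=text, sections=())

    # line offsets
    lines: list[tuple[int, int, str]] = []  # (start, end, content w/o newline)
    pos = 0
    for raw in text.splitlines(keepends=True):
        content = raw.rstrip("\r\n")
        lines.append((pos, pos + len(raw), content))
        pos += len(raw)

    boundaries = [
        i for i, (_, _, content) in enumerate(lines) if headings.is_heading(content)
    ]
    sections: list[Section] = []
    if not boundaries or boundaries[0] > 0:
        first = boundaries[0] if boundaries else len(lines)
        span = (0, lines[first - 1][1] if first > 0 else 0)
        sections.append(Section(PREAMBLE, text[span[0]:span[1]], span))
    for k, i in enumerate(boundaries):
        start = lines[i][0]
        end = lines[boundaries[k + 1]][0] if k + 1 < len(boundaries) else len(text)
        body_start = lines[i][1]  # after the heading line
        sections.append(
            Section(
                heading=normalize_heading(lines[i][2]),
                body=text[body_start:end],
                char_span=(start, end),
            )
        )
    return SectionedReport(note_id=note.note_id, text=text, sections=tuple(sections))


def find_lv_section(
    report: SectionedReport, headings: SectionHeadingSet
) -> Section | None:
    """Return the first left-ventricle section of the report, or None."""
    for section in report.sections:
        if section.heading != PREAMBLE and headings.is_lv(section.heading):
            return section
    return None
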