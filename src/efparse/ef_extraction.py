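"""The EF pattern cascade: tabular, range, numerical, and qualitative matchers.

Echocardiography reports document the left ventricular ejection fraction
(LVEF) in four recurrent styles:

* **tabular** — a measurements row, ``Ejection Fraction 20% (A) (Range: 50 - 75)``,
  where the parenthesized text is a *normal reference range*, not the value;
* **numerical** — a narrative sentence, ``The left ventricular ejection
  fraction is 60%``;
* **range** — a low–high pair, ``Estimated left ventricular ejection fraction
  is 45-50%`` or ``ef 50 to 55``;
* **qualitative** — prose severity, ``Left ventricular systolic function is
  moderately impaired``.

:func:`extract_ef` applies these in decreasing order of precedence: a tabular
match anywhere in the note wins outright; otherwise the left-ventricle section
is searched for a range and then a single number (range first, so ``45-50%``
is never truncated to 45); qualitative expressions are the last resort.  Every
note yields exactly one :class:`ExtractionResult` — either a mention or the
stage at which it dropped out (no anchor keywords, no LV section, or no
pattern matched), which feeds the unmatched log.

Value capture is anchored: a percentage is only taken within a bounded filler
window after an anchor token ("ejection fraction", "lvef", or "ef" as a whole
word), must fall inside a plausibility band (1–99, integers or half-integers),
and parenthesized reference ranges are masked out beforehand.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Mapping, Sequence

from .corpus_io import ClinicalNote, ConfigurationError
from .sectioner import Section, SectionHeadingSet, find_lv_section, segment

__all__ = [
    "EFMention",
    "ExtractionResult",
    "PATTERN_GROUPS",
    "mask_reference_ranges",
    "build_phrasebook",
    "match_tabular",
    "match_numeric",
    "match_range",
    "match_qualitative",
    "extract_ef",
]

PATTERN_GROUPS = ("tabular", "numerical", "range", "qualitative")

# Anchor tokens licensing value capture; "ef" only as a whole word so that
# "left"/"useful" never anchor a match.
_ANCHOR = r"(?:ejection\s+fraction|lvef|ef)"
_ANCHOR_RE = re.compile(rf"\b{_ANCHOR}\b", re.IGNORECASE)

# One filler word: starts with a letter, no digits, no sentence-final period.
_FILL_WORD = r"[A-Za-z][A-Za-z()',-]*"

_VALUE = r"\d{1,3}(?:\.\d+)?"
# Forbid a digit (or decimal continuation) right after a captured value so
# backtracking can never split "45" into a bare "4".
_VALUE_END = r"(?!\.?\d)"
# A value is rejected if a range joiner and another number follow: that text
# is a low-high range and must be captured by the range matcher instead.
_NOT_RANGE_CONT = r"(?!(?:\s*%)?\s*(?:-|–|\bto\b)\s*\d)"

_REFRANGE_RE = re.compile(r"\(\s*range\b[^)]*\)", re.IGNORECASE)


def mask_reference_ranges(text: str) -> str:
    """Blank out parenthesized reference ranges like ``(Range: 50 - 75)``.

    The replacement preserves length, so character offsets into the masked
    text are valid in the original.
    """
    return _REFRANGE_RE.sub(lambda m: " " * len(m.group(0)), text)


@dataclasses.dataclass(frozen=True)
class EFMention:
    """A matched EF snippet.

    ``raw_snippet`` always equals the note text over ``char_span`` (0-based,
    half-open).  Exactly the fields relevant to ``pattern_group`` are set:
    ``value`` for tabular/numerical, ``(low, high)`` for range (ordered), and
    ``qualitative_key`` for qualitative.
    """

    note_id: str
    pattern_group: str
    raw_snippet: str
    char_span: tuple[int, int]
    value: float | None = None
    low: float | None = None
    high: float | None = None
    qualitative_key: str | None = None


@dataclasses.dataclass(frozen=True)
class ExtractionResult:
    """Outcome of the cascade for one note: a mention xor a drop-out stage."""

    note_id: str
    mention: EFMention | None
    stage: str | None
    anchor_found: bool
    lv_section_found: bool

    def __post_init__(self):
        if (self.mention is None) == (self.stage is None):
            raise ValueError("exactly one of mention/stage must be set")


def _plausible(token: str, lo: float, hi: float) -> float | None:
    """Parse a candidate percentage; None if outside bounds or not a
    half-integer."""
    v = float(token)
    if not lo <= v <= hi:
        return None
    if (v * 2) != int(v * 2):
        return None
    return v


def _compile_tabular() -> re.Pattern:
    # Label at line start (no prose before it), optional separator, value.
    return re.compile(
        rf"^[ \t]*{_ANCHOR}\s*[:=]?[ \t]*(?P<val>{_VALUE}){_VALUE_END}{_NOT_RANGE_CONT}\s*%?",
        re.IGNORECASE,
    )


def _compile_numeric(w: int) -> re.Pattern:
    return re.compile(
        rf"\b{_ANCHOR}\b(?:\s+{_FILL_WORD}){{0,{w}}}[\s:=]+"
        rf"(?P<val>{_VALUE}){_VALUE_END}{_NOT_RANGE_CONT}\s*%?",
        re.IGNORECASE,
    )


def _compile_range(w: int) -> re.Pattern:
    return re.compile(
        rf"\b{_ANCHOR}\b(?:\s+{_FILL_WORD}){{0,{w}}}[\s:=]+"
        rf"(?P<lo>{_VALUE}){_VALUE_END}\s*%?\s*(?:-|–|to)\s*"
        rf"(?P<hi>{_VALUE}){_VALUE_END}\s*%?",
        re.IGNORECASE,
    )


_TABULAR_RE = _compile_tabular()


def match_tabular(
    text: str,
    note_id: str = "",
    min_value: float = 1,
    max_value: float = 99,
) -> EFMention | None:
    """Match a tabular EF row: label at line start followed by the value.

    Parenthesized reference ranges are masked before capture, so the measured
    value is taken even when a ``(Range: lo - hi)`` decoration follows it.
    Returns the first valid match in reading order.
    """
    masked = mask_reference_ranges(text)
    offset = 0
    for raw in masked.splitlines(keepends=True):
        for m in _TABULAR_RE.finditer(raw.rstrip("\r\n")):
            value = _plausible(m.group("val"), min_value, max_value)
            if value is None:
                continue
            span = (offset + m.start(), offset + m.end())
            return EFMention(
                note_id=note_id,
                pattern_group="tabular",
                raw_snippet=text[span[0]:span[1]],
                char_span=span,
                value=value,
            )
        offset += len(raw)
    return None


def match_numeric(
    text: str,
    note_id: str = "",
    offset: int = 0,
    filler_window: int = 8,
    min_value: float = 1,
    max_value: float = 99,
    source_text: str | None = None,
) -> EFMention | None:
    """Match anchor + up to ``filler_window`` filler words + one percentage.

    Does not fire when the value opens an explicit low-to-high range (the
    range matcher owns those). ``offset`` shifts the reported span when
    ``text`` is a section body of a larger note (``source_text``).
    """
    source = source_text if source_text is not None else text
    masked = mask_reference_ranges(text)
    for m in _compile_numeric(filler_window).finditer(masked):
        value = _plausible(m.group("val"), min_value, max_value)
        if value is None:
            continue
        span = (offset + m.start(), offset + m.end())
        return EFMention(
            note_id=note_id,
            pattern_group="numerical",
            raw_snippet=source[span[0]:span[1]],
            char_span=span,
            value=value,
        )
    return None


def match_range(
    text: str,
    note_id: str = "",
    offset: int = 0,
    filler_window: int = 8,
    min_value: float = 1,
    max_value: float = 99,
    source_text: str | None = None,
) -> EFMention | None:
    """Match anchor + fillers + a low-high percentage pair.

    The bounds may be joined by "-", an en-dash, or the word "to"; the "%"
    sign is optional on the low bound. The captured pair is ordered.
    """
    source = source_text if source_text is not None else text
    masked = mask_reference_ranges(text)
    for m in _compile_range(filler_window).finditer(masked):
        lo = _plausible(m.group("lo"), min_value, max_value)
        hi = _plausible(m.group("hi"), min_value, max_value)
        if lo is None or hi is None:
            continue
        lo, hi = min(lo, hi), max(lo, hi)
        span = (offset + m.start(), offset + m.end())
        return EFMention(
            note_id=note_id,
            pattern_group="range",
            raw_snippet=source[span[0]:span[1]],
            char_span=span,
            low=lo,
            high=hi,
        )
    return None


Phrasebook = list[tuple[str, list[re.Pattern]]]


def build_phrasebook(phrases: Mapping[str, Sequence[str]]) -> Phrasebook:
    """Compile a key -> regex-alternatives mapping into a phrasebook."""
    if not phrases:
        raise ConfigurationError("qualitative phrasebook is empty")
    return [
        (key, [re.compile(p, re.IGNORECASE) for p in patterns])
        for key, patterns in phrases.items()
    ]


def match_qualitative(
    text: str,
    phrasebook: Phrasebook,
    note_id: str = "",
    offset: int = 0,
    source_text: str | None = None,
) -> EFMention | None:
    """Match the earliest qualitative LV-function phrase in the text.

    ``captured`` is the canonical phrase key (e.g. ``moderately-reduced``
    for "moderately impaired/decreased/reduced"). Phrases are specific to the
    left ventricle, so right-ventricular prose never matches.
    """
    if not phrasebook:
        raise ConfigurationError("qualitative phrasebook is empty")
    source = source_text if source_text is not None else text
    best: tuple[int, int, str] | None = None
    for key, patterns in phrasebook:
        for pat in patterns:
            m = pat.search(text)
            if m and (best is None or m.start() < best[0]):
                best = (m.start(), m.end(), key)
    if best is None:
        return None
    start, end, key = best
    span = (offset + start, offset + end)
    return EFMention(
        note_id=note_id,
        pattern_group="qualitative",
        raw_snippet=source[span[0]:span[1]],
        char_span=span,
        qualitative_key=key,
    )


def _keyword_screen(text: str, keywords: Sequence[str]) -> bool:
    for kw in keywords:
        pattern = r"\b" + r"\s+".join(map(re.escape, kw.split())) + r"\b"
        if re.search(pattern, text, re.IGNORECASE):
            return True
    return False


def _body_offset(section: Section) -> int:
    return section.char_span[1] - len(section.body)


def extract_ef(
    note: ClinicalNote,
    headings: SectionHeadingSet,
    config: Mapping,
) -> ExtractionResult:
    """Run the full precedence cascade on one echocardiogram note.

    Order: (a) keyword screen — a note with no anchor keyword anywhere is
    ``no-anchor-keywords``; (b) tabular match over the whole note; (c) within
    the left-ventricle section, range then numerical; (d) qualitative in the
    LV section, falling back to the whole note (config-selectable); (e)
    ``no-pattern-matched`` — or ``no-lv-section`` when the note had no LV
    section and qualitative fallback also failed.
    """
    pat = config["patterns"]
    w = int(pat["filler_window"])
    lo, hi = float(pat["min_value"]), float(pat["max_value"])
    phrasebook = build_phrasebook(pat["phrasebook"])
    keywords = config["anchors"]["keywords"]

    if not _keyword_screen(note.text, keywords):
        return ExtractionResult(note.note_id, None, "no-anchor-keywords",
                                anchor_found=False, lv_section_found=False)

    report = segment(note, headings)
    lv = find_lv_section(report, headings)
    lv_found = lv is not None

    mention = match_tabular(note.text, note.note_id, lo, hi)
    if mention is None and lv is not None:
        off = _body_offset(lv)
        mention = match_range(lv.body, note.note_id, off, w, lo, hi,
                              source_text=note.text)
        if mention is None:
            mention = match_numeric(lv.body, note.note_id, off, w, lo, hi,
                                    source_text=note.text)
        if mention is None:
            mention = match_qualitative(lv.body, phrasebook, note.note_id, off,
                                        source_text=note.text)
    if mention is None and pat.get("qualitative_scope", "note") == "note":
        mention = match_qualitative(note.text, phrasebook, note.note_id)

    if mention is not None:
        return ExtractionResult(note.note_id, mention, None,
                                anchor_found=True, lv_section_found=lv_found)
    stage = "no-pattern-matched" if lv_found else "no-lv-section"
    return ExtractionResult(note.note_id, None, stage,
                            anchor_found=True, lv_section_found=lv_found)
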