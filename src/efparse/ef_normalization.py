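"""Normalization of EF mentions and heart-failure classification.

A mention becomes a normalized :class:`EFValue`: tabular and numerical
mentions carry their captured percentage as a point value; range mentions are
converted to the arithmetic mean of their bounds (kept at half-integer
precision — no rounding, so 45–50 becomes 47.5 exactly); qualitative mentions
carry only their canonical phrase key and classify through a lookup map.

Two classifications are derived:

* binary — rEF iff EF <= 40 (boundary inclusive), else not-rEF; qualitative
  mentions take the class their phrase key maps to;
* three-way — HFrEF for EF < 40, HFmEF for 40 <= EF <= 50, HFpEF for EF > 50;
  qualitative mentions are not applicable.

The two rules deliberately disagree at EF exactly 40 (rEF under the binary
cut, HFmEF under the strata): both boundary conventions are in clinical use
and each is preserved verbatim rather than reconciled.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

from .ef_extraction import EFMention

__all__ = [
    "EFValue",
    "QualitativeMap",
    "ClassificationThresholds",
    "UnmappedPhraseError",
    "BINARY_CLASSES",
    "THREEWAY_CLASSES",
    "normalize",
    "classify_binary",
    "classify_threeway",
]

BINARY_CLASSES = ("rEF", "not-rEF")
THREEWAY_CLASSES = ("HFrEF", "HFmEF", "HFpEF")


class UnmappedPhraseError(KeyError):
    """A qualitative phrase key has no entry in the lookup map."""

    def __init__(self, key: str):
        super().__init__(key)
        self.key = key

    def __str__(self) -> str:
        return f"qualitative phrase key {self.key!r} has no qualitative_map entry"


@dataclasses.dataclass(frozen=True)
class EFValue:
    """A normalized EF with provenance.

    ``kind`` is ``point`` (value = captured percentage), ``range`` (value =
    (low+high)/2 exactly), or ``qualitative`` (no numeric value; the phrase
    key drives classification). ``source_group`` records the pattern group
    the mention came from.
    """

    note_id: str
    kind: str
    value: float | None
    low: float | None = None
    high: float | None = None
    qualitative_key: str | None = None
    source_group: str | None = None


@dataclasses.dataclass(frozen=True)
class QualitativeMap:
    """Lookup from canonical phrase key to binary EF class.

    Total over the shipped phrasebook: an unknown key at runtime raises
    :class:`UnmappedPhraseError` rather than defaulting silently.
    """

    entries: Mapping[str, str]

    def __post_init__(self):
        for key, cls in self.entries.items():
            if cls not in BINARY_CLASSES:
                raise ValueError(
                    f"qualitative_map[{key!r}] = {cls!r}; expected one of "
                    f"{BINARY_CLASSES}"
                )

    def binary_class(self, key: str) -> str:
        try:
            return self.entries[key]
        except KeyError:
            raise UnmappedPhraseError(key) from None


@dataclasses.dataclass(frozen=True)
class ClassificationThresholds:
    """EF cut points, in percent.

    ``binary_cut``: rEF iff EF <= cut (default 40, inclusive).
    ``threeway``: (low, high) strata bounds — HFrEF < low, HFmEF in
    [low, high], HFpEF > high; defaults (40, 50).
    """

    binary_cut: float = 40.0
    threeway: tuple[float, float] = (40.0, 50.0)

    def __post_init__(self):
        lo, hi = self.threeway
        if not (0 < self.binary_cut < 100 and 0 < lo <= hi < 100):
            raise ValueError("thresholds must lie strictly inside (0, 100)")

    @classmethod
    def from_config(cls, config: Mapping) -> "ClassificationThresholds":
        t = config["normalization"]["thresholds"]
        return cls(binary_cut=float(t["binary_cut"]),
                   threeway=tuple(float(x) for x in t["threeway"]))


def qualitative_map_from_config(config: Mapping) -> QualitativeMap:
    return QualitativeMap(dict(config["normalization"]["qualitative_map"]))


def normalize(mention: EFMention, qmap: QualitativeMap) -> EFValue:
    """Convert a matched mention into a normalized EF value.

    Tabular/numerical -> point; range -> midpoint of the bounds; qualitative
    -> the canonical key, validated against the lookup map.
    """
    if mention.pattern_group in ("tabular", "numerical"):
        return EFValue(note_id=mention.note_id, kind="point",
                       value=mention.value, source_group=mention.pattern_group)
    if mention.pattern_group == "range":
        mid = (mention.low + mention.high) / 2
        return EFValue(note_id=mention.note_id, kind="range", value=mid,
                       low=mention.low, high=mention.high,
                       source_group="range")
    if mention.pattern_group == "qualitative":
        qmap.binary_class(mention.qualitative_key)  # fail fast on unknown key
        return EFValue(note_id=mention.note_id, kind="qualitative", value=None,
                       qualitative_key=mention.qualitative_key,
                       source_group="qualitative")
    raise ValueError(f"unknown pattern group {mention.pattern_group!r}")


def classify_binary(
    ef: EFValue,
    thresholds: ClassificationThresholds,
    qmap: QualitativeMap,
) -> str:
    """rEF iff EF <= binary cut; qualitative values classify via the map."""
    if ef.kind == "qualitative":
        return qmap.binary_class(ef.qualitative_key)
    return "rEF" if ef.value <= thresholds.binary_cut else "not-rEF"


def classify_threeway(
    ef: EFValue,
    thresholds: ClassificationThresholds,
) -> str | None:
    """HFrEF / HFmEF / HFpEF stratum for numeric EFs; None for qualitative."""
    if ef.kind == "qualitative":
        return None
    lo, hi = thresholds.threeway
    if ef.value < lo:
        return "HFrEF"
    if ef.value <= hi:
        return "HFmEF"
    return "HFpEF"
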