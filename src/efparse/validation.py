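"""Validation against labels and pattern-prevalence reporting.

The extraction pipeline is validated at the report level on the binary EF
classes (LVEF <= 40 vs LVEF > 40): system output is tallied against labels —
human annotations or synthetic-corpus truth — into a 2x2 confusion matrix,
from which accuracy is derived.  Pattern-prevalence tables summarize how the
corpus distributes over the cascade's outcome categories, the tool's main
instrument for steering iterative pattern development.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

from .ef_extraction import ExtractionResult

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "accuracy",
    "pattern_prevalence",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 tally for the binary classes; cells are (predicted, true)."""

    tp: int  # predicted rEF, true rEF
    fp: int  # predicted rEF, true not-rEF
    fn: int  # predicted not-rEF, true rEF
    tn: int  # predicted not-rEF, true not-rEF

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {"predicted_rEF_true_rEF": self.tp,
                "predicted_rEF_true_not_rEF": self.fp,
                "predicted_not_rEF_true_rEF": self.fn,
                "predicted_not_rEF_true_not_rEF": self.tn,
                "n_total": self.n_total}


def confusion_matrix(
    predictions: Mapping[str, str],
    labels: Mapping[str, str],
) -> ConfusionMatrix:
    """Tally predicted vs true binary classes keyed by note_id.

    Every prediction must have a label; unlabeled predictions raise a
    reconciliation error listing the offending note ids.
    """
    missing = sorted(set(predictions) - set(labels))
    if missing:
        raise KeyError(
            f"{len(missing)} prediction(s) have no label: {missing[:10]}"
        )
    cells = Counter()
    for note_id, pred in predictions.items():
        cells[(pred == "rEF", labels[note_id] == "rEF")] += 1
    return ConfusionMatrix(
        tp=cells[(True, True)], fp=cells[(True, False)],
        fn=cells[(False, True)], tn=cells[(False, False)],
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified reports; undefined on an empty tally."""
    if cm.n_total == 0:
        raise ZeroDivisionError("accuracy is undefined for an empty matrix")
    return (cm.tp + cm.tn) / cm.n_total


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def _table(counts: Counter, categories: Sequence[str]) -> dict:
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


def pattern_prevalence(results: Sequence[ExtractionResult]) -> dict:
    """Distribution tables over the cascade's outcome categories.

    Returns two tables:

    * ``high_level`` — every result, over {tabular, lv-section,
      no-lv-section, no-anchor}: tabular mentions; mentions found via the LV
      section; notes without an LV section (whether or not the whole-note
      qualitative fallback extracted something); notes without EF keywords.
    * ``pattern`` — results whose note had EF keywords, over {numerical,
      range, qualitative, no-pattern}; tabular and narrative point values
      pool as "numerical" since both yield a single number.

    Counts in each table sum to the number of results they cover.
    """
    high = Counter()
    pattern = Counter()
    for r in results:
        if not r.anchor_found:
            high["no-anchor"] += 1
            continue
        group = r.mention.pattern_group if r.mention else None
        if group == "tabular":
            high["tabular"] += 1
        elif not r.lv_section_found:
            high["no-lv-section"] += 1
        else:
            high["lv-section"] += 1
        if group in ("tabular", "numerical"):
            pattern["numerical"] += 1
        elif group in ("range", "qualitative"):
            pattern[group] += 1
        else:
            pattern["no-pattern"] += 1
    return {
        "high_level": _table(
            high, ("tabular", "lv-section", "no-lv-section", "no-anchor")),
        "pattern": _table(
            pattern, ("numerical", "range", "qualitative", "no-pattern")),
        "n_results": len(results),
    }
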