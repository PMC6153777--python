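"""Seeded generator of synthetic echocardiogram reports with ground truth.

Emulates the documentation styles seen in real echocardiography dictation —
a tabular measurements row, narrative point values and low–high ranges inside
a "LEFT VENTRICLE" section, qualitative severity prose, plus the failure
modes (notes without EF keywords, notes without an LV section) — so that
every pipeline stage can be exercised without clinical data.  Each note is
paired with a :class:`SyntheticTruth` carrying the intended EF and the
classes it should produce under the pipeline's own thresholds.

Defaults state the corpus the generator emulates: the style mix puts 74% of
notes in tabular form, 3% with no EF keywords, 2% with no LV section, and
splits the remaining narrative mass 85/9/6 across numerical, range, and
qualitative sentences; EF values fall 18% below 40, 14% in 40–50, and 68%
above 50.  A ``distractor_rate`` fraction of notes carries a parenthesized
normal reference range ``(Range: 50 - 75)`` that the extractor must not
mistake for the measurement.

Generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import random
from typing import Mapping, Sequence

from .corpus_io import ClinicalNote

__all__ = [
    "STYLES",
    "GeneratorConfig",
    "SyntheticTruth",
    "GenerationError",
    "render_report",
    "generate_corpus",
    "make_validation_corpus",
]

STYLES = ("tabular", "numerical", "range", "qualitative",
          "no-anchor", "no-lv-section")

#: Narrative mass (1 - .74 - .03 - .02 = .21) split 85/9/6.
_DEFAULT_STYLE_MIX = {
    "tabular": 0.74,
    "numerical": 0.1785,
    "range": 0.0189,
    "qualitative": 0.0126,
    "no-anchor": 0.03,
    "no-lv-section": 0.02,
}

#: (probability, low, high) per EF stratum: reduced / mid-range / preserved.
_DEFAULT_EF_STRATA = ((0.18, 10, 39), (0.14, 40, 50), (0.68, 51, 75))

_ECHO_CODES = ("ECH01", "ECH02", "ECH03")
_NON_ECHO_CODES = ("RAD05", "CAR02", "PRG01")


class GenerationError(ValueError):
    """A truth record is internally inconsistent with its style."""


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults are the stated world above."""

    n_notes: int = 1000
    n_patients: int | None = None  # default: n_notes // 2, floor 1
    seed: int = 0
    style_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_STYLE_MIX))
    ef_strata: tuple = _DEFAULT_EF_STRATA
    date_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2016, 1, 1), datetime.date(2017, 12, 31))
    distractor_rate: float = 0.3
    non_echo_rate: float = 0.1
    adversarial: bool = False

    def __post_init__(self):
        total = sum(self.style_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"style_mix must sum to 1, got {total}")
        unknown = set(self.style_mix) - set(STYLES)
        if unknown:
            raise ValueError(f"unknown styles in style_mix: {sorted(unknown)}")
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate must lie in [0, 1]")
        if not 0 <= self.non_echo_rate <= 1:
            raise ValueError("non_echo_rate must lie in [0, 1]")

    @property
    def effective_n_patients(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        return max(1, self.n_notes // 2)


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated note.

    ``true_ef`` is the intended percentage (midpoint for ranges), the
    qualitative key for qualitative styles, or None when the note carries no
    EF at all.  Classes are computed with the pipeline's default thresholds
    (binary cut at 40 inclusive; strata <40 / 40–50 / >50) and default
    qualitative map, so a perfect extraction reproduces them exactly.
    """

    note_id: str
    true_style: str
    true_ef: float | str | None
    true_low: float | None = None
    true_high: float | None = None
    true_binary_class: str | None = None
    true_threeway_class: str | None = None
    has_distractor: bool = False
    is_echo: bool = True


# ---------------------------------------------------------------- templates

_NUMERICAL_TEMPLATES = (
    "The left ventricular ejection fraction is {v}%.",
    "lv ejection fraction {v}%",
    "LVEF by visual estimation is around {v}%.",
    "The LVEF is {v}%.",
    "Estimated ejection fraction is {v}.",
    "Overall left ventricular ejection fraction is estimated at {v}%.",
)

_RANGE_TEMPLATES = (
    "Estimated left ventricular ejection fraction is {lo}-{hi}%.",
    "The LVEF is visually estimated at {lo}-{hi}%.",
    "The left ventricular ejection fraction is {lo} to {hi}%.",
    "lv ejection fraction {lo}-{hi}%",
)

_QUALITATIVE_TEMPLATES = {
    "low-normal": ("LVEF appears at the lower limits of normal.",),
    "normal": ("Left ventricular systolic function is normal.",),
    "hyperdynamic": ("Left ventricular systolic function is hyperdynamic.",),
    "mildly-reduced": (
        "Left ventricular systolic function is mildly impaired.",
        "Left ventricular systolic function is mildly reduced.",
    ),
    "moderately-reduced": (
        "Left ventricular systolic function is moderately impaired.",
        "Left ventricular systolic function is moderately decreased.",
    ),
    "severely-reduced": (
        "Left ventricular systolic function is severely reduced.",
        "Left ventricular systolic function is severely impaired.",
    ),
}

_QUALITATIVE_BINARY = {
    "low-normal": "not-rEF",
    "normal": "not-rEF",
    "hyperdynamic": "not-rEF",
    "mildly-reduced": "not-rEF",
    "moderately-reduced": "rEF",
    "severely-reduced": "rEF",
}

_TABULAR_TEMPLATES = (
    "Ejection Fraction  {v}%  (A)",
    "Ejection Fraction {v}%",
    "LVEF: {v}%",
)

# Digit-free filler so the clean tier has no off-context numbers near anchors.
_LV_FILLER = (
    "Left ventricular cavity size is normal.",
    "Left ventricular wall thickness is normal.",
    "No regional wall motion abnormality identified.",
)
_RV_BODY = "Right ventricular size and contraction are normal."
_VALVES_BODY = "No significant valvular abnormality."
_PREAMBLE = "Transthoracic echocardiogram. Study quality adequate."
_ADVERSARIAL_LINES = (
    "Heart Rate 72 (Range: 60 - 100)",
    "Blood pressure 120/80 mmHg recorded at time of study.",
    "Study performed in 2017 using standard imaging windows.",
)


def _binary_of(value: float) -> str:
    return "rEF" if value <= 40 else "not-rEF"


def _threeway_of(value: float) -> str:
    if value < 40:
        return "HFrEF"
    if value <= 50:
        return "HFmEF"
    return "HFpEF"


def render_report(truth: SyntheticTruth, rng: random.Random) -> str:
    """Render one multi-section report realizing the truth record.

    The EF statement instantiates a randomly chosen template of the truth's
    style; a truth with ``has_distractor`` decorates the tabular row with a
    parenthesized reference range and adds a heart-rate reference line.
    Deterministic for a given truth and rng state.
    """
    style = truth.true_style
    lines: list[str] = [_PREAMBLE]

    if truth.has_distractor:
        lines.append("Heart Rate 72 (Range: 60 - 100)")
    if style == "tabular":
        if not isinstance(truth.true_ef, (int, float)):
            raise GenerationError("tabular truth requires a numeric true_ef")
        row = rng.choice(_TABULAR_TEMPLATES).format(v=_fmt(truth.true_ef))
        if truth.has_distractor:
            row += "  (Range: 50 - 75)"
        lines += ["", row]

    lv_lines: list[str] = [rng.choice(_LV_FILLER)]
    if style == "numerical":
        if not isinstance(truth.true_ef, (int, float)):
            raise GenerationError("numerical truth requires a numeric true_ef")
        lv_lines.append(
            rng.choice(_NUMERICAL_TEMPLATES).format(v=_fmt(truth.true_ef)))
    elif style == "range":
        if truth.true_low is None or truth.true_high is None:
            raise GenerationError("range truth requires true_low/true_high")
        lv_lines.append(rng.choice(_RANGE_TEMPLATES).format(
            lo=_fmt(truth.true_low), hi=_fmt(truth.true_high)))
    elif style == "qualitative":
        if truth.true_ef not in _QUALITATIVE_TEMPLATES:
            raise GenerationError(
                f"qualitative truth requires a known key, got {truth.true_ef!r}")
        lv_lines.append(rng.choice(_QUALITATIVE_TEMPLATES[truth.true_ef]))

    if style == "no-lv-section":
        if truth.true_ef not in _QUALITATIVE_TEMPLATES:
            raise GenerationError(
                f"no-lv-section truth requires a qualitative key, "
                f"got {truth.true_ef!r}")
        # qualitative phrase outside any LV section
        lines += ["", rng.choice(_QUALITATIVE_TEMPLATES[truth.true_ef])]
    else:
        lines += ["", "LEFT VENTRICLE:"] + lv_lines

    lines += ["", "RIGHT VENTRICLE:", _RV_BODY, "", "VALVES:", _VALVES_BODY]
    return "\n".join(lines)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else str(v)


def _draw_ef(rng: random.Random, strata) -> int:
    u = rng.random()
    acc = 0.0
    for prob, lo, hi in strata:
        acc += prob
        if u < acc:
            return rng.randint(lo, hi)
    prob, lo, hi = strata[-1]
    return rng.randint(lo, hi)


def _draw_style(rng: random.Random, mix: Mapping[str, float]) -> str:
    u = rng.random()
    acc = 0.0
    for style in STYLES:
        acc += mix.get(style, 0.0)
        if u < acc:
            return style
    return next(s for s in reversed(STYLES) if mix.get(s, 0.0) > 0)


def _make_truth(note_id: str, style: str, cfg: GeneratorConfig,
                rng: random.Random) -> SyntheticTruth:
    distractor = rng.random() < cfg.distractor_rate
    if style in ("tabular", "numerical"):
        v = _draw_ef(rng, cfg.ef_strata)
        return SyntheticTruth(note_id, style, float(v),
                              true_binary_class=_binary_of(v),
                              true_threeway_class=_threeway_of(v),
                              has_distractor=distractor)
    if style == "range":
        lo = _draw_ef(rng, cfg.ef_strata)
        lo = 5 * round(lo / 5)
        hi = lo + 5
        mid = (lo + hi) / 2
        return SyntheticTruth(note_id, style, mid, true_low=float(lo),
                              true_high=float(hi),
                              true_binary_class=_binary_of(mid),
                              true_threeway_class=_threeway_of(mid),
                              has_distractor=distractor)
    if style in ("qualitative", "no-lv-section"):
        key = rng.choice(sorted(_QUALITATIVE_TEMPLATES))
        return SyntheticTruth(note_id, style, key,
                              true_binary_class=_QUALITATIVE_BINARY[key],
                              has_distractor=distractor)
    if style == "no-anchor":
        return SyntheticTruth(note_id, style, None, has_distractor=distractor)
    raise GenerationError(f"unknown style {style!r}")


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[ClinicalNote], list[SyntheticTruth]]:
    """Generate ``n_notes`` notes over ``n_patients`` patients with truths.

    Style assignment is multinomial over ``style_mix``; a ``non_echo_rate``
    fraction of notes receives a non-echocardiogram type code and EF-free
    text.  Dates are uniform over the date window; note ids are sequential,
    patient assignment uniform, so patients typically hold several dated
    reports.  Two runs with the same config are byte-identical.
    """
    rng = random.Random(config.seed)
    n_patients = config.effective_n_patients
    d0, d1 = config.date_window
    n_days = (d1 - d0).days

    notes: list[ClinicalNote] = []
    truths: list[SyntheticTruth] = []
    for i in range(config.n_notes):
        note_id = f"N{i:06d}"
        patient_id = f"P{rng.randrange(n_patients):05d}"
        note_date = d0 + datetime.timedelta(days=rng.randint(0, n_days))
        if rng.random() < config.non_echo_rate:
            truth = SyntheticTruth(note_id, "no-anchor", None, is_echo=False)
            text = "Chest radiograph. No acute cardiopulmonary process."
            code = rng.choice(_NON_ECHO_CODES)
        else:
            style = _draw_style(rng, config.style_mix)
            truth = _make_truth(note_id, style, config, rng)
            text = render_report(truth, rng)
            if config.adversarial:
                text = rng.choice(_ADVERSARIAL_LINES) + "\n" + text
            code = rng.choice(_ECHO_CODES)
        notes.append(ClinicalNote(patient_id=patient_id, note_id=note_id,
                                  note_type_code=code, note_date=note_date,
                                  text=text))
        truths.append(truth)
    return notes, truths


def make_validation_corpus(
    n: int = 339,
    seed: int = 0,
) -> tuple[list[ClinicalNote], list[SyntheticTruth]]:
    """A labeled validation set: every note carries a binary EF truth.

    Mirrors a manual-annotation validation design: ``n`` echocardiogram
    reports spanning all extractable styles (tabular, numerical, range,
    qualitative, and qualitative-outside-LV-section), with reference-range
    distractors enabled at the default rate and no non-echo notes.
    """
    mix = {k: v for k, v in _DEFAULT_STYLE_MIX.items() if k != "no-anchor"}
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    cfg = GeneratorConfig(n_notes=n, seed=seed, style_mix=mix,
                          non_echo_rate=0.0)
    return generate_corpus(cfg)
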