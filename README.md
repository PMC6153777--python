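# efparse

Rule-based extraction of **left ventricular ejection fraction (LVEF)** from
free-text echocardiography reports, for building heart-failure cohorts.

LVEF — the percentage of blood ejected from the left ventricle per beat — is
the key quantity deciding whether a heart-failure patient has *reduced*
ejection fraction (HFrEF, the group eligible for most guideline therapies) or
mid-range/preserved EF. In practice LVEF lives in free-text echo reports, in
wildly varying forms: a measurements-table row
(`Ejection Fraction 20% (A) (Range: 50 - 75)` — where `(Range: ...)` is a
normal *reference* interval, not the measurement), a narrative sentence
(`The left ventricular ejection fraction is 60%`), a low–high range
(`Estimated left ventricular ejection fraction is 45-50%`), or qualitative
prose (`Left ventricular systolic function is moderately impaired`).

`efparse` implements a precedence-ordered cascade of regular-expression
matchers for these styles, plus everything around it: corpus I/O,
echocardiogram identification from note metadata, section segmentation,
normalization and classification, patient-level cohort reduction, a seeded
synthetic-report generator, and confusion-matrix validation. It is aimed at
clinical-informatics teams doing EHR phenotyping who need an auditable,
config-extensible extractor that runs on a desk-scale note dump (JSONL/CSV)
with no model training and no clinical data required for testing.

## The algorithm

For each echocardiogram note (confirmed by an explicit accept list of
note-type codes):

1. **Keyword screen** — a note with no EF anchor keyword anywhere
   (`ejection fraction`, `lvef`, `ef` as a whole word, or `systolic
   function`) is logged as `no-anchor-keywords`.
2. **Tabular pattern** — an EF label at line start followed directly by a
   percentage. Parenthesized `(Range: ...)` text is masked before capture.
   A tabular match anywhere in the note takes precedence over everything.
3. **Left-ventricle section** — the note is sliced into sections at curated
   heading lines; within the `left ventricle` section a **range** pattern
   (`45-50%`, `40 to 50`) is tried before a **numeric** one, so a range is
   never truncated to its lower bound. Values are captured only within a
   bounded filler-word window after an anchor and must fall in [1, 99].
4. **Qualitative** — severity phrases (`moderately impaired`, `lower limits
   of normal`, ...) matched in the LV section, falling back to the whole
   note; each maps to a canonical key.
5. Otherwise the note is logged (`no-lv-section` / `no-pattern-matched`);
   seeded samples from this log drive iterative pattern extension.

Normalization maps mentions to EF values (ranges become the midpoint:
45–50 → 47.5), then to classes: **binary** rEF iff EF ≤ 40, and **three-way**
HFrEF < 40, HFmEF 40–50, HFpEF > 50 (the two conventions intentionally
disagree at exactly 40; see `docs/methods.md`). Patient-level cohort class
comes from the latest-dated extractable echocardiogram.

## Worked example

```python
import datetime
from efparse import (ClinicalNote, extract_ef, normalize,
                     classify_binary, classify_threeway, load_config)
from efparse.pipeline import heading_set_from_config
from efparse.ef_normalization import (ClassificationThresholds,
                                      qualitative_map_from_config)

config = load_config()
headings = heading_set_from_config(config)
qmap = qualitative_map_from_config(config)
thresholds = ClassificationThresholds.from_config(config)

note = ClinicalNote(
    patient_id="P0001", note_id="N000001", note_type_code="ECH01",
    note_date=datetime.date(2017, 6, 1),
    text=("Transthoracic echocardiogram.\n"
          "Ejection Fraction 20% (A) (Range: 50 - 75)\n\n"
          "LEFT VENTRICLE:\n"
          "The left ventricular ejection fraction is 60%\n"),
)
result = extract_ef(note, headings, config)
ef = normalize(result.mention, qmap)
print("pattern group:", result.mention.pattern_group)
print("snippet:      ", result.mention.raw_snippet)
print("EF value:     ", ef.value)
print("binary class: ", classify_binary(ef, thresholds, qmap))
print("stratum:      ", classify_threeway(ef, thresholds))
```

prints

```
pattern group: tabular
snippet:       Ejection Fraction 20%
EF value:      20.0
binary class:  rEF
stratum:       HFrEF
```

The note contains two candidate EF statements; the tabular row wins by
precedence, its value is 20 (not the 50–75 reference range), and at EF ≤ 40
the report is classed rEF / HFrEF.

## Command line

```bash
efparse simulate --seed 3 --n-notes 1000 --out sim/    # synthetic corpus + truth
efparse extract  --corpus sim/corpus.jsonl --out ex/   # cascade + unmatched log
efparse cohort   --extractions ex/extractions.csv --out co/
efparse validate --predictions pred.csv --labels labels.csv --out val/
```

Every stage is governed by one YAML config (deep-merged over the shipped
defaults in `src/efparse/data/default_config.yaml`): echo-code accept list,
anchor keywords, section headings, pattern knobs, the qualitative lookup map,
and the classification thresholds. Extraction rows + unmatched-log rows
always sum to the number of notes processed, and fixed-seed runs are
byte-identical.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the cascade's captured values on the canonical
worked-example excerpts (tabular-with-reference-range, narrative point
values, a low–high range), and the binary-classification accuracy of the
full pipeline on a seeded 339-report synthetic validation corpus spanning
all documentation styles with reference-range distractors enabled. Results
are written as JSON to `--out`.
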