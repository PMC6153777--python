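# Methods

## Problem and scope

`efparse` extracts left ventricular ejection fraction (LVEF) from free-text
echocardiography reports and reduces it to heart-failure cohort membership.
The artifact consumes an already-assembled note dump (patient id, note id,
note-type code, ISO date, text); registry querying, ICD-based cohort
filtering, de-identification, negation/historical-mention handling, and
distributed execution are out of scope. Extraction is restricted to
echocardiogram reports — LVEF mentions in visit notes that merely summarize
an echo are deliberately not parsed.

## Echocardiogram identification

Note-type codes are institution-specific. `discover_echo_codes` surfaces the
codes of notes containing the phrase "ejection fraction" (case-insensitive,
whitespace collapsed), sorted by descending frequency and filtered at a
configurable corpus-fraction floor (default 1%), each with up to `sample_k`
seeded sample note ids for manual review. The accept list itself is always
an explicit config value: echo codes are *often* ECH-prefixed, but prefix
matching would silently over-include, so automation stops at candidate
generation.

## Sectioning

Headings are discovered as the most frequent normalized lines of a corpus
(lowercase, trimmed, one trailing colon stripped — an idempotent
normalization) and curated into a config list; a default list of twelve
cardiology headings ships with the package. A heading must occupy its own
line to act as a boundary; inline occurrences of heading words never split
sections. Section spans tile the note text exactly (disjoint, ordered,
covering every character), which makes downstream character spans auditable
against the original note. When several left-ventricle sections exist, the
first in reading order is used.

## The cascade and its precedence

Matching proceeds tabular → LV-section range → LV-section numeric →
qualitative, consulting later tiers only when earlier tiers fail. The
precedence is structural, not positional: a tabular row anywhere in the note
beats any narrative sentence. Within a tier, first match in reading order
wins.

Numeric design choices:

- **Anchors**: `ejection fraction`, `lvef`, `ef` (whole word only). The
  *keyword screen* that routes notes to the `no-anchor-keywords` log
  additionally includes `systolic function`, because qualitative statements
  such as "left ventricular systolic function is moderately impaired" never
  name the ejection fraction, yet must reach the qualitative tier.
- **Filler window**: up to 8 words between anchor and value (covers "by
  visual estimation is around"); bounded so capture cannot wander into an
  unrelated sentence. Filler words contain no digits, so the first number
  after the anchor is always the one captured.
- **Plausibility band**: captured values must be integers or half-integers
  in [1, 99]; implausible candidates (years, heart rates) are skipped and
  the scan continues.
- **Reference-range masking**: any parenthesized group starting with
  "Range" is blanked (length-preserving, so spans survive) before capture.
- **Range priority**: the numeric matcher refuses a value followed by a
  range joiner (`-`, en-dash, `to`) and a second number, and refuses to
  split a number by backtracking (`45` can never yield `4`), so a rendered
  range sentence never produces a bare point mention of the lower bound.
- **Tabular vs narrative**: a tabular row requires the anchor at line start
  with the value following directly (optional colon); any intervening prose
  word makes it narrative. This keeps sentence-style mentions inside the LV
  section from being mislabeled tabular.

Qualitative matching uses a config phrasebook of regex alternatives mapping
to canonical keys (`low-normal`, `mildly-reduced`, `moderately-reduced`,
`severely-reduced`, `normal`, `hyperdynamic`). Phrases are LV-specific, so
right-ventricular prose cannot match. By default the qualitative tier falls
back from the LV section to the whole note (`patterns.qualitative_scope`),
so reports without an LV section can still be classified from prose; this
fallback is config-selectable because source corpora differ in whether
qualitative statements appear outside chamber sections.

## Normalization and classification

Point mentions keep their captured value; range mentions become the exact
arithmetic midpoint, kept at half-integer precision (45–50 → 47.5) to avoid
rounding artifacts at the class boundaries; qualitative mentions carry only
their key and classify through a total lookup map — an unknown key is an
error, never a silent default.

Two classifications coexist:

- binary: **rEF iff EF ≤ 40** (boundary inclusive);
- three-way: **HFrEF < 40, HFmEF 40–50 (inclusive both ends), HFpEF > 50**.

The conventions disagree at EF exactly 40 (rEF but HFmEF). Both boundary
rules are in clinical use and each is preserved verbatim rather than
reconciled; the discordance is asserted in the tests as documented behavior.
Ranges are averaged *before* classification, so 35–45 → 40 → rEF. The
qualitative map's class-level defaults (hyperdynamic / normal / low-normal /
mildly-reduced → not-rEF; moderately- and severely-reduced → rEF) are a
package choice — the mildly-reduced assignment in particular is the
conservative reading and is config-overridable; no numeric EF is ever
imputed from a phrase.

## Cohort construction

A patient's classifying EF is taken from their latest-dated echocardiogram
with an extractable EF; unextractable echoes are skipped when choosing the
latest, so an older extractable echo still classifies the patient.
Same-date ties break by note id, lexicographically latest first — a
deterministic, documented choice where source data gives no ordering.
Patients whose every echo is unextractable are emitted in a separate
exclusions file for audit, never dropped silently. Qualitative latest EFs
participate in the binary HFrEF/not-HFrEF split via the map but are excluded
from the numeric strata table.

## Synthetic corpus: what it emulates and what it does not

The generator states a fixed world: 74% of echo reports carry a tabular EF
row, 3% contain no EF keywords at all, 2% state EF qualitatively outside any
LV section, and the remaining narrative mass splits 85/9/6 across numerical,
range, and qualitative sentences. EF values fall 18% below 40, 14% in
40–50, and 68% above 50 (integers in [10, 75]; ranges are 5-point-wide,
5-aligned). A `distractor_rate` (default 0.3) fraction of notes carries a
`(Range: 50 - 75)` reference-range decoration plus a heart-rate reference
line; 10% of notes default to non-echo type codes. Dates are uniform over a
two-year window with roughly two reports per patient. All draws come from
one seeded generator and runs are byte-reproducible.

Templates instantiate the observed documentation styles plus systematic
lexical variants (case, optional `%`, joiner `-`/`to`, filler words). An
`adversarial` flag prepends off-context numeric lines (heart rate with a
reference range, a year, a blood pressure) for robustness testing, kept out
of the clean tier so oracle-equivalence tests measure correctness, not
robustness.

What synthetic data does **not** emulate: clinically coherent hemodynamics,
valve grading, dictation typos, OCR noise, multi-study addenda, or
institution-specific table layouts beyond the shipped templates. A green
synthetic validation therefore establishes that the cascade implements its
stated rules exactly on the stated styles — not that it generalizes to an
unseen institution's formatting, which is precisely why the unmatched log
and config-extensible pattern set exist.

## Validation

Validation is report-level on the binary classes (LVEF ≤ 40 vs > 40):
predictions are tallied against labels into a 2×2 confusion matrix, accuracy
is the diagonal fraction. The shipped replica generates a 339-report labeled
corpus across all extractable styles with distractors enabled and requires
off-diagonal zeros. Pattern-prevalence tables (counts, integer percentages
rounded half-up, raw proportions) summarize outcomes at two levels —
tabular / LV-section / no-LV-section / no-keywords, and numerical / range /
qualitative / no-pattern with tabular pooled into numerical — and a
generator configured at given proportions is recovered within three binomial
standard errors.

## Numerical and degenerate-input choices

- Character spans are 0-based half-open into the original note text;
  `raw_snippet` always equals the text over the span.
- Empty note text yields a no-pattern result, never an error; an empty
  corpus yields empty outputs.
- Dates are ISO-8601 only; anything else is rejected at read time so that
  latest-echo ordering can never be locale-ambiguous.
- The run manifest records the config hash and input digest instead of a
  wall-clock timestamp, keeping every output of a fixed-seed run
  byte-identical.
- Percentage tables round half-up to integers; raw proportions are emitted
  alongside so no information is lost to rounding.

## Known limitations

- Negated or historical EF mentions ("prior EF 25%, now recovered") are not
  detected; every match is treated as current.
- Only the first mention per tier is used; multiple conflicting
  measurements within one LV section (e.g. biplane vs visual estimate)
  resolve to reading order, not method preference.
- Qualitative phrases map to classes, not values, so qualitative-only
  patients never enter numeric strata.
- The shipped heading list and phrasebook are starting points; real
  deployments are expected to grow them through the unmatched-log loop.
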