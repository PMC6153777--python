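import random

import pytest

from efparse.corpus_io import ConfigurationError
from efparse.ef_extraction import (
    extract_ef,
    mask_reference_ranges,
    match_numeric,
    match_qualitative,
    match_range,
    match_tabular,
)
from efparse.synthetic_corpus import (
    GeneratorConfig,
    SyntheticTruth,
    generate_corpus,
    render_report,
)

from conftest import anchor_window_numbers, make_note


class TestMaskReferenceRanges:
    def test_masks_preserving_offsets(self):
        text = "Ejection Fraction 20% (A) (Range: 50 - 75)"
        masked = mask_reference_ranges(text)
        assert len(masked) == len(text)
        assert "50" not in masked and "75" not in masked
        assert masked.startswith("Ejection Fraction 20% (A)")

    def test_case_insensitive(self):
        assert "60" not in mask_reference_ranges("x (RANGE 50-60) y")


class TestMatchTabular:
    def test_captures_measured_value_not_reference_range(self):
        m = match_tabular("Ejection Fraction 20% (A) (Range: 50 - 75)")
        assert m.pattern_group == "tabular"
        assert m.value == 20
        assert m.raw_snippet == "Ejection Fraction 20%"

    def test_no_ef_label_means_no_match(self):
        assert match_tabular("Heart Rate 72 (Range: 60 - 100)") is None

    def test_prose_label_is_not_tabular(self):
        # a label mid-sentence or followed by filler words is narrative
        assert match_tabular("The left ventricular ejection fraction is 60%") is None
        assert match_tabular("Ejection fraction is 60%") is None

    def test_first_match_in_reading_order(self):
        text = "LVEF: 30%\nEjection Fraction 55%"
        assert match_tabular(text).value == 30

    def test_randomized_decorations_recover_truth(self):
        rng = random.Random(0)
        for i in range(200):
            v = rng.randint(10, 75)
            truth = SyntheticTruth(f"N{i}", "tabular", float(v),
                                   true_binary_class="x",
                                   has_distractor=rng.random() < 0.5)
            m = match_tabular(render_report(truth, rng))
            assert m is not None and m.value == v


class TestMatchNumeric:
    @pytest.mark.parametrize("text,value", [
        ("The left ventricular ejection fraction is 60%", 60),
        ("lv ejection fraction 66%", 66),
        ("LVEF by visual estimation is around 35%", 35),
        ("Estimated ejection fraction is 55.", 55),  # % sign optional
        ("EF = 62.5%", 62.5),  # half-integer precision
    ])
    def test_point_values(self, text, value):
        m = match_numeric(text)
        assert m is not None and m.value == value

    def test_does_not_truncate_a_range(self):
        assert match_numeric("ejection fraction is 45-50%") is None

    def test_implausible_values_skipped(self):
        assert match_numeric("ejection fraction measured in 2017") is None
        assert match_numeric("ef 0%") is None
        assert match_numeric("ef 120%") is None

    def test_anchor_required_as_whole_word(self):
        assert match_numeric("useful measurement 55%") is None
        assert match_numeric("left side shows 55%") is None

    def test_filler_window_is_bounded(self):
        far = ("ejection fraction " + "word " * 12 + "55%")
        assert match_numeric(far) is None

    def test_span_matches_source_text(self):
        text = "x\nThe LVEF is 40%."
        m = match_numeric(text)
        assert text[m.char_span[0]:m.char_span[1]] == m.raw_snippet


class TestMatchRange:
    @pytest.mark.parametrize("text,lo,hi", [
        ("Estimated left ventricular ejection fraction is 45-50%", 45, 50),
        ("The LVEF is visually estimated at 30-35%", 30, 35),
        ("ef 50 to 55", 50, 55),
        ("ejection fraction 40%-45%", 40, 45),
    ])
    def test_bounds(self, text, lo, hi):
        m = match_range(text)
        assert (m.low, m.high) == (lo, hi)

    def test_bounds_are_ordered(self):
        m = match_range("ef 55 to 50")
        assert (m.low, m.high) == (50, 55)

    def test_reference_range_not_captured(self):
        assert match_range("Ejection Fraction 20% (Range: 50 - 75)") is None


class TestMatchQualitative:
    @pytest.mark.parametrize("text,key", [
        ("LVEF appears at the lower limits of normal", "low-normal"),
        ("Left ventricular systolic function is moderately impaired",
         "moderately-reduced"),
        ("Left ventricular systolic function is moderately decreased",
         "moderately-reduced"),
        ("Left ventricular systolic function is severely reduced",
         "severely-reduced"),
        ("Left ventricular systolic function is normal", "normal"),
    ])
    def test_phrase_keys(self, text, key, phrasebook):
        m = match_qualitative(text, phrasebook)
        assert m is not None and m.qualitative_key == key

    def test_wrong_chamber_does_not_match(self, phrasebook):
        assert match_qualitative(
            "Right ventricular function is reduced", phrasebook) is None

    def test_empty_phrasebook_is_config_error(self):
        with pytest.raises(ConfigurationError):
            match_qualitative("anything", [])


class TestCascade:
    def test_tabular_precedence_over_lv_sentence(self, headings, config):
        note = make_note(
            "Ejection Fraction 20% (A) (Range: 50 - 75)\n\n"
            "LEFT VENTRICLE:\nThe left ventricular ejection fraction is 60%")
        r = extract_ef(note, headings, config)
        assert r.mention.pattern_group == "tabular"
        assert r.mention.value == 20

    def test_range_in_lv_section(self, headings, config):
        note = make_note(
            "LEFT VENTRICLE:\nThe LVEF is visually estimated at 30-35%")
        r = extract_ef(note, headings, config)
        assert r.mention.pattern_group == "range"
        assert (r.mention.low, r.mention.high) == (30, 35)

    def test_range_has_priority_over_numeric(self, headings, config):
        # a rendered range sentence never yields a bare numerical mention
        note = make_note(
            "LEFT VENTRICLE:\nEstimated left ventricular ejection fraction "
            "is 45-50%")
        r = extract_ef(note, headings, config)
        assert r.mention.pattern_group == "range"

    def test_no_anchor_keywords(self, headings, config):
        note = make_note("LEFT VENTRICLE:\nNormal cavity size.")
        r = extract_ef(note, headings, config)
        assert r.stage == "no-anchor-keywords"
        assert not r.anchor_found

    def test_qualitative_fallback_outside_lv_section(self, headings, config):
        note = make_note(
            "Left ventricular systolic function is severely impaired.\n"
            "RIGHT VENTRICLE:\nNormal.")
        r = extract_ef(note, headings, config)
        assert r.mention.pattern_group == "qualitative"
        assert r.mention.qualitative_key == "severely-reduced"
        assert not r.lv_section_found

    def test_no_pattern_matched_with_lv_section(self, headings, config):
        note = make_note(
            "LEFT VENTRICLE:\nejection fraction could not be assessed.")
        r = extract_ef(note, headings, config)
        assert r.stage == "no-pattern-matched"
        assert r.lv_section_found

    def test_empty_note_never_crashes(self, headings, config):
        r = extract_ef(make_note(""), headings, config)
        assert r.stage == "no-anchor-keywords"

    def test_deterministic(self, headings, config):
        note = make_note("LEFT VENTRICLE:\nThe LVEF is 40%.")
        assert extract_ef(note, headings, config) == \
            extract_ef(note, headings, config)

    def test_injected_tabular_line_switches_outcome(self, headings, config):
        notes, _ = generate_corpus(GeneratorConfig(
            n_notes=60, seed=11, non_echo_rate=0.0,
            style_mix={"numerical": 0.4, "range": 0.3, "qualitative": 0.3}))
        switched = 0
        for note in notes:
            base = extract_ef(note, headings, config)
            if base.mention is None:
                continue
            injected = make_note("Ejection Fraction 25%\n" + note.text,
                                 note_id=note.note_id)
            r = extract_ef(injected, headings, config)
            assert r.mention.pattern_group == "tabular"
            assert r.mention.value == 25
            switched += 1
        assert switched > 50

    def test_oracle_equivalence_on_clean_notes(self, headings, config):
        """Cascade output equals the brute-force anchor-window scanner on
        clean single-statement notes."""
        notes, truths = generate_corpus(GeneratorConfig(
            n_notes=300, seed=23, non_echo_rate=0.0, distractor_rate=0.0,
            style_mix={"tabular": 0.4, "numerical": 0.4, "range": 0.2}))
        for note, truth in zip(notes, truths):
            r = extract_ef(note, headings, config)
            expected = anchor_window_numbers(note.text)
            m = r.mention
            got = sorted({m.value} if m.value is not None
                         else {m.low, m.high})
            assert got == expected, note.text
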