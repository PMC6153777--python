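import datetime
import json

import pytest

from efparse.corpus_io import (
    ClinicalNote,
    ConfigurationError,
    CorpusSchemaError,
    DuplicateNoteError,
    UnmatchedLogEntry,
    discover_echo_codes,
    export_unmatched_sample,
    is_echocardiogram,
    read_notes,
    write_notes,
)
from efparse.synthetic_corpus import GeneratorConfig, generate_corpus

from conftest import make_note


def _write_jsonl(path, records):
    path.write_text("".join(json.dumps(r) + "\n" for r in records))


GOOD = [
    {"patient_id": "P1", "note_id": "N1", "note_type_code": "ECH01",
     "note_date": "2017-01-01", "text": "hello"},
    {"patient_id": "P1", "note_id": "N2", "note_type_code": "ECH01",
     "note_date": "2017-02-01", "text": ""},
    {"patient_id": "P2", "note_id": "N3", "note_type_code": "RAD05",
     "note_date": "2017-03-01", "text": "x\ny"},
]


class TestReadNotes:
    def test_reads_jsonl_in_file_order(self, tmp_path):
        p = tmp_path / "corpus.jsonl"
        _write_jsonl(p, GOOD)
        notes = read_notes(p, "jsonl")
        assert [n.note_id for n in notes] == ["N1", "N2", "N3"]
        assert notes[0].note_date == datetime.date(2017, 1, 1)
        assert notes[2].text == "x\ny"

    def test_missing_field_names_the_field(self, tmp_path):
        p = tmp_path / "corpus.jsonl"
        bad = dict(GOOD[0])
        del bad["text"]
        _write_jsonl(p, [bad])
        with pytest.raises(CorpusSchemaError, match="text"):
            read_notes(p, "jsonl")

    def test_duplicate_note_id_rejected(self, tmp_path):
        p = tmp_path / "corpus.jsonl"
        _write_jsonl(p, [GOOD[0], GOOD[0]])
        with pytest.raises(DuplicateNoteError, match="N1"):
            read_notes(p, "jsonl")

    def test_bad_date_rejected_with_note_id(self, tmp_path):
        p = tmp_path / "corpus.jsonl"
        bad = dict(GOOD[0], note_date="01/02/2017")
        _write_jsonl(p, [bad])
        with pytest.raises(CorpusSchemaError, match="N1"):
            read_notes(p, "jsonl")

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_round_trip_synthetic_corpus(self, tmp_path, fmt):
        notes, _ = generate_corpus(GeneratorConfig(n_notes=50, seed=3))
        p = tmp_path / f"corpus.{fmt}"
        write_notes(notes, p, fmt)
        assert read_notes(p, fmt) == notes


class TestDiscoverEchoCodes:
    def test_single_code_corpus(self):
        notes = [make_note("The ejection fraction is 55%", note_id=f"N{i}")
                 for i in range(4)]
        (cand,) = discover_echo_codes(notes)
        assert cand.note_type_code == "ECH01"
        assert cand.corpus_fraction == 1.0

    def _mixed_corpus(self):
        notes = []
        for i in range(100):
            code = "ECH01" if i < 70 else ("ECH02" if i < 95 else "XRA09")
            notes.append(make_note("Ejection Fraction 60%",
                                   note_id=f"N{i}", code=code))
        return notes

    def test_counts_and_order_match_direct_tally(self):
        cands = discover_echo_codes(self._mixed_corpus(), min_fraction=0.01)
        assert [(c.note_type_code, c.note_count) for c in cands] == [
            ("ECH01", 70), ("ECH02", 25), ("XRA09", 5)]

    def test_min_fraction_excludes_rare_codes(self):
        cands = discover_echo_codes(self._mixed_corpus(), min_fraction=0.10)
        assert [c.note_type_code for c in cands] == ["ECH01", "ECH02"]

    def test_anchor_match_case_insensitive_and_ws_collapsed(self):
        notes = [make_note("EJECTION   FRACTION 60")]
        assert len(discover_echo_codes(notes)) == 1

    def test_empty_corpus_gives_empty_result(self):
        assert discover_echo_codes([]) == []

    def test_samples_drawn_from_codes_own_notes(self):
        cands = discover_echo_codes(self._mixed_corpus(), sample_k=3, seed=1)
        by_code = {c.note_type_code: c for c in cands}
        assert set(by_code["ECH02"].sample_note_ids) <= {
            f"N{i}" for i in range(70, 95)}


class TestIsEchocardiogram:
    def test_accept_list_membership(self):
        accept = {"ECH01", "ECH02"}
        assert is_echocardiogram(make_note("", code="ECH01"), accept)
        assert not is_echocardiogram(make_note("", code="RAD05"), accept)

    def test_empty_accept_list_is_config_error(self):
        with pytest.raises(ConfigurationError):
            is_echocardiogram(make_note(""), set())

    def test_generator_echo_labels_recovered(self):
        notes, truths = generate_corpus(
            GeneratorConfig(n_notes=100, seed=5, non_echo_rate=0.2))
        accept = {"ECH01", "ECH02", "ECH03"}
        flags = [is_echocardiogram(n, accept) for n in notes]
        assert flags == [t.is_echo for t in truths]


class TestExportUnmatchedSample:
    @staticmethod
    def _log(n, stage="no-pattern-matched"):
        return [UnmatchedLogEntry(f"N{i}", stage, "...") for i in range(n)]

    def test_seeded_sample_is_reproducible(self):
        log = self._log(100)
        a = export_unmatched_sample(log, "no-pattern-matched", 10, seed=42)
        b = export_unmatched_sample(log, "no-pattern-matched", 10, seed=42)
        assert a == b
        assert len(a) == len({e.note_id for e in a}) == 10

    def test_exhaustion_returns_all(self):
        log = self._log(3)
        assert len(export_unmatched_sample(log, "no-pattern-matched", 10)) == 3

    def test_different_seeds_are_subsets_of_stage(self):
        log = self._log(100) + self._log(5, stage="no-lv-section")
        a = export_unmatched_sample(log, "no-pattern-matched", 20, seed=1)
        b = export_unmatched_sample(log, "no-pattern-matched", 20, seed=2)
        pool = {e.note_id for e in log if e.stage_reached == "no-pattern-matched"}
        assert {e.note_id for e in a} <= pool
        assert {e.note_id for e in b} <= pool
        assert a != b

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            export_unmatched_sample(self._log(5), "nonsense", 1)
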