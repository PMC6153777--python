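import datetime
import re

import pytest

from efparse.config import default_config
from efparse.corpus_io import ClinicalNote
from efparse.ef_extraction import build_phrasebook
from efparse.ef_normalization import (
    ClassificationThresholds,
    qualitative_map_from_config,
)
from efparse.pipeline import heading_set_from_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def headings(config):
    return heading_set_from_config(config)


@pytest.fixture(scope="session")
def phrasebook(config):
    return build_phrasebook(config["patterns"]["phrasebook"])


@pytest.fixture(scope="session")
def qmap(config):
    return qualitative_map_from_config(config)


@pytest.fixture(scope="session")
def thresholds():
    return ClassificationThresholds()


def make_note(text, note_id="N1", patient_id="P1", code="ECH01",
              date=datetime.date(2017, 6, 1)):
    return ClinicalNote(patient_id=patient_id, note_id=note_id,
                        note_type_code=code, note_date=date, text=text)


_ANCHOR_RE = re.compile(r"\b(?:ejection\s+fraction|lvef|ef)\b", re.IGNORECASE)


def anchor_window_numbers(text, window=60):
    """Independent brute-force oracle: every integer in [1, 99] occurring
    within `window` characters after any anchor token."""
    numbers = set()
    for m in _ANCHOR_RE.finditer(text):
        tail = text[m.end():m.end() + window]
        for nm in re.finditer(r"(?<![\d.])(\d+)(?!\d)", tail):
            v = int(nm.group(1))
            if 1 <= v <= 99:
                numbers.add(v)
    return sorted(numbers)
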