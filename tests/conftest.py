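from pathlib import Path

import numpy as np
import pytest

import formtypic as ft

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def inventory():
    return ft.load_inventory()


@pytest.fixture(scope="session")
def fixture_entries():
    return ft.synth.make_fixture()


@pytest.fixture(scope="session")
def fixture_lexicon_path():
    return FIXTURES / "mini_lexicon.csv"


@pytest.fixture(scope="session")
def expected_vectors_path():
    return FIXTURES / "expected_form_vectors.csv"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_entry(word="bala", trans="b a . l a", stress=1, pos="noun",
               vm=5.0, vs=1.0, am=5.0, asd=1.0):
    phonemes, breaks = ft.parse_transcription(trans)
    return ft.WordEntry(word=word, phonemes=phonemes, syllable_breaks=breaks,
                        stress_syllable=stress, pos=pos,
                        ratings=ft.AffectRatings(valence_mean=vm, valence_sd=vs,
                                                 arousal_mean=am, arousal_sd=asd))
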