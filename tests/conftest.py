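import numpy as np
import pytest
from hypothesis import settings

from adspeech.chat_io import AudioClip, TranscriptDoc, Utterance
from adspeech.features import default_resources
from adspeech.synthetic_data import CohortConfig, generate_cohort

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def resources():
    return default_resources()


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort with audio, shared across tests."""
    return generate_cohort(CohortConfig(n_per_group=6, seed=5))


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort, resources):
    from adspeech.features import extract_cohort
    return extract_cohort(small_cohort.pairs(), resources)


def make_doc(token_lists, subject_id="s1", **meta) -> TranscriptDoc:
    utts = [Utterance(speaker="PAR", tokens=list(toks))
            for toks in token_lists]
    return TranscriptDoc(subject_id=subject_id, utterances=utts, meta=meta)


@pytest.fixture
def sine_clip():
    rate = 16000
    t = np.arange(2 * rate) / rate
    return AudioClip(samples=0.6 * np.sin(2 * np.pi * 440.0 * t), rate=rate)
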