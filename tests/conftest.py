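import numpy as np
import pytest

from speechtrf.stimulus import Phoneme, Sentence, SpeechAnnotation, Word
from speechtrf.synthetic import CohortConfig, simulate_cohort
from speechtrf.trf import LagAxis


@pytest.fixture(scope="session")
def lag_axis():
    return LagAxis()


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """3 trials, 2 participants, no noise; generating scheme word_class."""
    cfg = CohortConfig(n_participants=2, n_trials=3, trial_duration_s=30.0,
                       snr_db=np.inf, seed=3)
    return simulate_cohort(cfg, include_phonemes=False)


@pytest.fixture()
def toy_annotation():
    """Hand-built two-sentence trial: 6 words, vowel nuclei for syllables."""
    words = [
        Word(1.0, "the", "article_determiner", 0),
        Word(1.4, "dog", "general_noun", 0),
        Word(1.9, "runs", "verb", 0),
        Word(3.0, "very", "adverb", 1),
        Word(3.5, "fast", "adjective", 1),
        Word(4.0, "uh", "others", 1),
    ]
    phonemes = [
        Phoneme(1.05, "short_vowel"), Phoneme(1.45, "short_vowel"),
        Phoneme(1.95, "short_vowel"), Phoneme(3.05, "short_vowel"),
        Phoneme(3.3, "long_vowel"), Phoneme(3.55, "diphthong"),
        Phoneme(4.05, "fricative"),
    ]
    sentences = [Sentence(0, 0.9, 2.5, False), Sentence(1, 2.9, 4.5, False)]
    return SpeechAnnotation("toy", 6.0, words, phonemes, sentences)
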