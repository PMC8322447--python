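"""Speech annotations and impulse stimulus matrices.

Words, phonemes and sentence boundaries of a speech trial are represented as
timed events with linguistic labels.  Each annotation can be expanded into one
of four binary "impulse" stimulus matrices (features x time points) that serve
as the design input for temporal response function estimation: the matrix
carries a 1 at the sample nearest each event onset on the row of the feature
the event belongs to, and 0 elsewhere.

The four schemes are

``word_class``      open vs. closed class words
``word_position``   beginning / middle / end position within the trial
``speech_rate``     fast vs. slow sentences (syllables per minute >= 230)
``parts_of_speech`` the 14 analysed part-of-speech classes ("others" dropped)

Every scheme is augmented with nine articulatory phoneme-class rows and
sentence-beginning / sentence-ending rows (these can be switched off for
small simulation studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OPEN_POS_CLASSES",
    "CLOSED_POS_CLASSES",
    "POS_CLASSES",
    "PHONEME_CLASSES",
    "VOWEL_NUCLEI",
    "SCHEMES",
    "Word",
    "Phoneme",
    "Sentence",
    "SpeechAnnotation",
    "WordClassification",
    "StimulusMatrix",
    "classify_word",
    "compute_speech_rate",
    "assign_position",
    "build_stimulus_matrix",
    "read_annotation_tsv",
    "write_annotation_tsv",
]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations or inputs."""


# ---------------------------------------------------------------------------
# Inventories
# ---------------------------------------------------------------------------

#: Six open-class (content word) part-of-speech classes.
OPEN_POS_CLASSES = (
    "general_noun",
    "proper_noun",
    "verb",
    "adjective",
    "adverb",
    "number",
)

#: Eight closed-class (function word) part-of-speech classes.
CLOSED_POS_CLASSES = (
    "article_determiner",
    "pronoun",
    "interrogative_word",
    "relative_pronoun",
    "be_verb",
    "auxiliary_verb",
    "preposition",
    "conjunction",
)

#: The full 15-class part-of-speech inventory.
POS_CLASSES = OPEN_POS_CLASSES + CLOSED_POS_CLASSES + ("others",)

#: Nine articulatory phoneme classes.
PHONEME_CLASSES = (
    "short_vowel",
    "long_vowel",
    "diphthong",
    "plosive",
    "affricate",
    "fricative",
    "nasal",
    "liquid",
    "semivowel",
)

#: Phoneme classes that count as syllable nuclei.
VOWEL_NUCLEI = ("short_vowel", "long_vowel", "diphthong")

SCHEMES = ("word_class", "word_position", "speech_rate", "parts_of_speech")

#: Sentences at or above this syllables-per-minute rate count as "fast".
FAST_SPM_THRESHOLD = 230.0

# Common Penn-Treebank-style tags mapped onto the 15-class inventory, so that
# externally tagged transcripts can be ingested without re-labelling.
_PENN_TAG_MAP = {
    "NN": "general_noun", "NNS": "general_noun",
    "NNP": "proper_noun", "NNPS": "proper_noun",
    "VB": "verb", "VBD": "verb", "VBG": "verb", "VBN": "verb",
    "VBP": "verb", "VBZ": "verb",
    "JJ": "adjective", "JJR": "adjective", "JJS": "adjective",
    "RB": "adverb", "RBR": "adverb", "RBS": "adverb",
    "CD": "number",
    "DT": "article_determiner", "PDT": "article_determiner",
    "PRP": "pronoun", "PRP$": "pronoun",
    "WP": "interrogative_word", "WRB": "interrogative_word",
    "WDT": "relative_pronoun",
    "MD": "auxiliary_verb",
    "IN": "preposition", "TO": "preposition",
    "CC": "conjunction",
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Word:
    onset_s: float
    form: str
    pos_tag: str
    sentence_id: int


@dataclass(frozen=True)
class Phoneme:
    onset_s: float
    phoneme_class: str


@dataclass(frozen=True)
class Sentence:
    sentence_id: int
    onset_s: float
    offset_s: float
    interrogative: bool = False


@dataclass
class SpeechAnnotation:
    """Timed word/phoneme/sentence events of one speech trial."""

    trial_id: str
    duration_s: float
    words: list[Word] = field(default_factory=list)
    phonemes: list[Phoneme] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise AnnotationError("trial duration must be positive")
        sent_ids = {s.sentence_id for s in self.sentences}
        for w in self.words:
            if not (0.0 <= w.onset_s <= self.duration_s):
                raise AnnotationError(
                    f"word onset {w.onset_s} outside trial [0, {self.duration_s}]"
                )
            if w.sentence_id not in sent_ids:
                raise AnnotationError(f"unknown sentence_id {w.sentence_id}")
        for p in self.phonemes:
            if p.phoneme_class not in PHONEME_CLASSES:
                raise AnnotationError(f"unknown phoneme class {p.phoneme_class!r}")
            if not (0.0 <= p.onset_s <= self.duration_s):
                raise AnnotationError("phoneme onset outside trial")

    def sentence(self, sentence_id: int) -> Sentence:
        for s in self.sentences:
            if s.sentence_id == sentence_id:
                return s
        raise AnnotationError(f"no sentence {sentence_id}")


@dataclass(frozen=True)
class WordClassification:
    pos_class: str
    word_class: str  # open | closed | other


@dataclass
class StimulusMatrix:
    """Binary features x time impulse array for one trial and scheme."""

    scheme: str
    feature_names: list[str]
    values: np.ndarray  # (n_features, n_samples), entries in {0, 1}
    fs: float
    trial_id: str

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, feature: str) -> np.ndarray:
        return self.values[self.feature_names.index(feature)]


# ---------------------------------------------------------------------------
# Word classification
# ---------------------------------------------------------------------------

def classify_word(pos_tag: str) -> WordClassification:
    """Map a part-of-speech tag onto the 15-class inventory and open/closed.

    Canonical class names (``general_noun`` ... ``conjunction``) and common
    Penn-style tags are recognised; anything else falls back to
    ``others``/``other``.
    """
    if not pos_tag:
        raise AnnotationError("empty part-of-speech tag")
    tag = pos_tag.strip()
    if tag.lower() in POS_CLASSES:
        pos_class = tag.lower()
    else:
        pos_class = _PENN_TAG_MAP.get(tag.upper(), "others")
    if pos_class in OPEN_POS_CLASSES:
        word_class = "open"
    elif pos_class in CLOSED_POS_CLASSES:
        word_class = "closed"
    else:
        word_class = "other"
    return WordClassification(pos_class, word_class)


# ---------------------------------------------------------------------------
# Speech rate
# ---------------------------------------------------------------------------

def compute_speech_rate(annotation: SpeechAnnotation, sentence_id: int
                        ) -> tuple[float, str]:
    """Syllables per minute of a sentence and its fast/slow class.

    Syllables are counted as vowel-nucleus phonemes (short vowel, long vowel,
    diphthong) whose onset falls inside the sentence interval.  A sentence is
    ``fast`` iff SPM >= 230 (boundary inclusive), else ``slow``.
    """
    sent = annotation.sentence(sentence_id)
    dur = sent.offset_s - sent.onset_s
    if dur <= 0:
        raise AnnotationError(f"sentence {sentence_id} has non-positive duration")
    n_syll = sum(
        1 for p in annotation.phonemes
        if p.phoneme_class in VOWEL_NUCLEI and sent.onset_s <= p.onset_s < sent.offset_s
    )
    spm = n_syll * 60.0 / dur
    return spm, ("fast" if spm >= FAST_SPM_THRESHOLD else "slow")


# ---------------------------------------------------------------------------
# Word position
# ---------------------------------------------------------------------------

def _final_interrogative_id(annotation: SpeechAnnotation) -> int | None:
    if not annotation.sentences:
        return None
    last = max(annotation.sentences, key=lambda s: s.offset_s)
    return last.sentence_id if last.interrogative else None


def assign_position(annotation: SpeechAnnotation, word_index: int) -> str:
    """Beginning/middle/end position of a word within its trial.

    Words belonging to a trial-final interrogative sentence are ``excluded``.
    The remaining words are split by ordinal into tertiles with boundaries at
    ceil(n/3) and ceil(2n/3).
    """
    if not (0 <= word_index < len(annotation.words)):
        raise AnnotationError("word_index out of range")
    excl_id = _final_interrogative_id(annotation)
    eligible = [i for i, w in enumerate(annotation.words)
                if w.sentence_id != excl_id]
    if annotation.words[word_index].sentence_id == excl_id:
        return "excluded"
    rank = eligible.index(word_index)
    n = len(eligible)
    if rank < math.ceil(n / 3):
        return "beginning"
    if rank < math.ceil(2 * n / 3):
        return "middle"
    return "end"


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _word_feature(annotation: SpeechAnnotation, scheme: str, idx: int,
                  word: Word) -> str | None:
    """Feature row a word maps to under a scheme, or None if excluded."""
    cls = classify_word(word.pos_tag)
    if scheme == "word_class":
        return cls.word_class if cls.word_class in ("open", "closed") else None
    if scheme == "parts_of_speech":
        return cls.pos_class if cls.pos_class != "others" else None
    if scheme == "word_position":
        pos = assign_position(annotation, idx)
        return None if pos == "excluded" else pos
    if scheme == "speech_rate":
        _, rate = compute_speech_rate(annotation, word.sentence_id)
        return rate
    raise AnnotationError(f"unknown scheme {scheme!r}")


def scheme_features(scheme: str) -> list[str]:
    """Word-feature rows of a scheme (without phoneme/boundary rows)."""
    if scheme == "word_class":
        return ["open", "closed"]
    if scheme == "word_position":
        return ["beginning", "middle", "end"]
    if scheme == "speech_rate":
        return ["fast", "slow"]
    if scheme == "parts_of_speech":
        return [c for c in POS_CLASSES if c != "others"]
    raise AnnotationError(f"unknown scheme {scheme!r}")


def build_stimulus_matrix(annotation: SpeechAnnotation, scheme: str, fs: float,
                          *, word_filter: str = "all",
                          include_phonemes: bool = True,
                          include_boundaries: bool = True) -> StimulusMatrix:
    """Expand an annotation into the binary impulse matrix of one scheme.

    Parameters
    ----------
    word_filter
        ``all`` uses every (non-excluded) word; ``open``/``closed`` restricts
        the word rows to one word class first.  Restriction is used when
        late-component features are extracted for open-class words only.
    include_phonemes, include_boundaries
        Whether the nine phoneme-class rows and the sentence-beginning /
        sentence-ending rows are appended (both on by default).
    """
    if fs <= 0:
        raise AnnotationError("sampling rate must be positive")
    if word_filter not in ("all", "open", "closed"):
        raise AnnotationError(f"bad word_filter {word_filter!r}")

    features = list(scheme_features(scheme))
    if include_phonemes:
        features += list(PHONEME_CLASSES)
    if include_boundaries:
        features += ["sentence_beginning", "sentence_ending"]

    n_samples = int(round(annotation.duration_s * fs))
    values = np.zeros((len(features), n_samples), dtype=np.float64)
    col_of = {f: i for i, f in enumerate(features)}

    def put(feature: str, onset_s: float) -> None:
        col = _round_half_away(onset_s * fs)
        if col == n_samples and onset_s <= annotation.duration_s:
            col -= 1  # in-range event rounding up to the end clamps back
        if not (0 <= col < n_samples):
            raise AnnotationError(
                f"onset {onset_s}s outside trial of {annotation.duration_s}s")
        values[col_of[feature], col] = 1.0

    for idx, word in enumerate(annotation.words):
        if word_filter != "all":
            if classify_word(word.pos_tag).word_class != word_filter:
                continue
        feat = _word_feature(annotation, scheme, idx, word)
        if feat is not None:
            put(feat, word.onset_s)

    if include_phonemes:
        for ph in annotation.phonemes:
            put(ph.phoneme_class, ph.onset_s)
    if include_boundaries:
        for sent in annotation.sentences:
            put("sentence_beginning", sent.onset_s)
            put("sentence_ending", sent.offset_s)

    return StimulusMatrix(scheme=scheme, feature_names=features, values=values,
                          fs=fs, trial_id=annotation.trial_id)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["trial_id", "kind", "onset_s", "label", "pos_tag",
                "sentence_id", "interrogative_flag"]


def write_annotation_tsv(annotations: list[SpeechAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        rows.append((ann.trial_id, "trial", ann.duration_s, "", "", -1, 0))
        for w in ann.words:
            rows.append((ann.trial_id, "word", w.onset_s, w.form, w.pos_tag,
                         w.sentence_id, 0))
        for p in ann.phonemes:
            rows.append((ann.trial_id, "phoneme", p.onset_s, p.phoneme_class,
                         "", -1, 0))
        for s in ann.sentences:
            rows.append((ann.trial_id, "sentence_on", s.onset_s, "", "",
                         s.sentence_id, int(s.interrogative)))
            rows.append((ann.trial_id, "sentence_off", s.offset_s, "", "",
                         s.sentence_id, int(s.interrogative)))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[SpeechAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: list[SpeechAnnotation] = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        dur_rows = grp[grp["kind"] == "trial"]
        duration = float(dur_rows["onset_s"].iloc[0]) if len(dur_rows) else \
            float(grp["onset_s"].max())
        words = [Word(float(r.onset_s), str(r.label), str(r.pos_tag),
                      int(r.sentence_id))
                 for r in grp[grp["kind"] == "word"].itertuples()]
        phonemes = [Phoneme(float(r.onset_s), str(r.label))
                    for r in grp[grp["kind"] == "phoneme"].itertuples()]
        ons = {int(r.sentence_id): (float(r.onset_s), bool(r.interrogative_flag))
               for r in grp[grp["kind"] == "sentence_on"].itertuples()}
        offs = {int(r.sentence_id): float(r.onset_s)
                for r in grp[grp["kind"] == "sentence_off"].itertuples()}
        sentences = [Sentence(sid, ons[sid][0], offs[sid], ons[sid][1])
                     for sid in sorted(ons)]
        out.append(SpeechAnnotation(str(trial_id), duration, words, phonemes,
                                    sentences))
    return out
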