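"""Synthetic quasi-regular lexicons and slot-based word encodings.

A lexicon is a set of monosyllabic word entries, each carrying

* a spelling, encoded over letter slots (one-hot within each slot, the
  first vowel letter anchored on a fixed slot),
* a pronunciation, encoded over phoneme slots (each occupied slot holds a
  binary phonological feature vector; onsets right-align against the
  vowel slot, codas left-align after it),
* a sparse binary semantic vector,
* a token frequency, and
* a context code (0 for unambiguous words; homophone-family members share
  spelling and pronunciation but carry distinct nonzero codes).

The generator builds rime families with controllable spelling-sound
consistency: words in a consistent family share one rime pronunciation,
while inconsistent families contain a minority of deviant members (the
*pint* among the *mint*/*hint* friends).  Psycholinguistic predictors --
word frequency (WF), orthographic neighbourhood size (ONS), rime
consistency (RC) and an imageability proxy (IMG) -- are computed over the
generated lexicon.

Slot indices are 1-based in documentation and error messages; vectors are
concatenations of slots in ascending order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import EncodingError, GenerationError, LexiconParseError

__all__ = [
    "PhonemeInventory",
    "EncodingSpec",
    "PsychFeatures",
    "WordEntry",
    "Lexicon",
    "LexiconParams",
    "encode_orthography",
    "encode_phonology",
    "orthography_slots",
    "phonology_slots",
    "orthographic_rime",
    "phonological_rime",
    "generate_lexicon",
    "compute_ons",
    "compute_rime_consistency",
    "compute_psych_features",
    "set_imageability",
    "read_lexicon",
    "write_lexicon",
    "read_inventory",
    "write_inventory",
]

VOWEL_LETTERS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

# ---------------------------------------------------------------------------
# Phoneme inventory
# ---------------------------------------------------------------------------

#: The 25 binary phonological features used by the default inventory.
FEATURE_NAMES: tuple[str, ...] = (
    "consonant", "vowel", "voiced", "nasal", "stop", "fricative",
    "affricate", "approximant", "lateral", "labial", "coronal", "dorsal",
    "glottal", "anterior", "strident", "high", "low", "front", "back",
    "round", "tense", "diphthong", "long", "rhotic", "syllabic",
)

# Feature assignments for a compact English-like segment inventory.  The
# exact phonetic fidelity matters less than that every phoneme has a
# distinct, non-empty feature vector and a consonant/vowel class.
_PHONEME_FEATURES: dict[str, tuple[str, ...]] = {
    # stops
    "p": ("consonant", "stop", "labial"),
    "b": ("consonant", "stop", "labial", "voiced"),
    "t": ("consonant", "stop", "coronal", "anterior"),
    "d": ("consonant", "stop", "coronal", "anterior", "voiced"),
    "k": ("consonant", "stop", "dorsal"),
    "g": ("consonant", "stop", "dorsal", "voiced"),
    # nasals
    "m": ("consonant", "nasal", "labial", "voiced"),
    "n": ("consonant", "nasal", "coronal", "anterior", "voiced"),
    "N": ("consonant", "nasal", "dorsal", "voiced"),
    # fricatives
    "f": ("consonant", "fricative", "labial", "strident"),
    "v": ("consonant", "fricative", "labial", "strident", "voiced"),
    "T": ("consonant", "fricative", "coronal", "anterior"),
    "D": ("consonant", "fricative", "coronal", "anterior", "voiced"),
    "s": ("consonant", "fricative", "coronal", "anterior", "strident"),
    "z": ("consonant", "fricative", "coronal", "anterior", "strident",
          "voiced"),
    "S": ("consonant", "fricative", "coronal", "strident", "high"),
    "Z": ("consonant", "fricative", "coronal", "strident", "high",
          "voiced"),
    "h": ("consonant", "fricative", "glottal"),
    # affricates
    "tS": ("consonant", "affricate", "coronal", "strident", "high"),
    "dZ": ("consonant", "affricate", "coronal", "strident", "high",
           "voiced"),
    # approximants
    "l": ("consonant", "approximant", "lateral", "coronal", "voiced"),
    "r": ("consonant", "approximant", "rhotic", "coronal", "voiced"),
    "w": ("consonant", "approximant", "labial", "dorsal", "voiced",
          "round"),
    "j": ("consonant", "approximant", "dorsal", "voiced", "front",
          "high"),
    # monophthongs
    "i": ("vowel", "syllabic", "voiced", "high", "front", "tense"),
    "I": ("vowel", "syllabic", "voiced", "high", "front"),
    "E": ("vowel", "syllabic", "voiced", "front"),
    "ae": ("vowel", "syllabic", "voiced", "low", "front"),
    "A": ("vowel", "syllabic", "voiced", "low", "back"),
    "V": ("vowel", "syllabic", "voiced", "back"),
    "O": ("vowel", "syllabic", "voiced", "back", "round"),
    "U": ("vowel", "syllabic", "voiced", "high", "back", "round"),
    "u": ("vowel", "syllabic", "voiced", "high", "back", "round",
          "tense"),
    "@": ("vowel", "syllabic", "voiced"),
    # diphthongs
    "eI": ("vowel", "syllabic", "voiced", "front", "tense", "diphthong"),
    "aI": ("vowel", "syllabic", "voiced", "low", "front", "tense",
           "diphthong"),
    "OI": ("vowel", "syllabic", "voiced", "back", "round", "diphthong"),
    "aU": ("vowel", "syllabic", "voiced", "low", "back", "diphthong"),
    "@U": ("vowel", "syllabic", "voiced", "back", "round", "tense",
           "diphthong"),
}


@dataclass(frozen=True)
class PhonemeInventory:
    """Phoneme labels and their binary feature vectors.

    Invariants (checked on construction): labels unique, all feature
    vectors of identical length, no two phonemes share a feature vector
    and no vector is all-zero.
    """

    labels: tuple[str, ...]
    features: np.ndarray  # (n_phonemes, F) of 0/1
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.int8)
        object.__setattr__(self, "features", feats)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("phoneme labels must be unique")
        if feats.ndim != 2 or feats.shape[0] != len(self.labels):
            raise ValueError("feature matrix must be (n_phonemes, F)")
        rows = {tuple(r) for r in feats.tolist()}
        if len(rows) != feats.shape[0]:
            raise ValueError("two phonemes share an identical feature vector")
        if (feats.sum(axis=1) == 0).any():
            raise ValueError("phoneme feature vectors must not be all-zero")

    @property
    def n_features(self) -> int:
        return int(self.features.shape[1])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise EncodingError(f"unknown phoneme label {label!r}") from None

    def vector(self, label: str) -> np.ndarray:
        return self.features[self.index(label)]

    def is_vowel(self, label: str) -> bool:
        if self.feature_names:
            vi = self.feature_names.index("vowel")
            return bool(self.features[self.index(label), vi])
        return bool(self.features[self.index(label), 1])

    @classmethod
    def default(cls) -> "PhonemeInventory":
        """The built-in 39-phoneme, 25-feature English-like inventory."""
        labels = tuple(_PHONEME_FEATURES)
        feats = np.zeros((len(labels), len(FEATURE_NAMES)), dtype=np.int8)
        for i, lab in enumerate(labels):
            for f in _PHONEME_FEATURES[lab]:
                feats[i, FEATURE_NAMES.index(f)] = 1
        return cls(labels=labels, features=feats, feature_names=FEATURE_NAMES)


# ---------------------------------------------------------------------------
# Encoding specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncodingSpec:
    """Slot template for orthographic and phonological vectors.

    Defaults follow the standard template: 14 letter slots of 26 units
    with the first vowel letter on slot 5; 8 phoneme slots (3 onset, 1
    vowel, 4 coda) of 25 feature units; 2,446 semantic units.  A smaller
    template for desk-scale experiments is available via :meth:`scaled`.
    """

    n_letter_slots: int = 14
    alphabet_size: int = 26
    first_vowel_slot: int = 5
    n_phoneme_slots: int = 8
    onset_slots: int = 3
    coda_slots: int = 4
    semantic_dim: int = 2446
    n_features: int = 25

    def __post_init__(self) -> None:
        if self.onset_slots + 1 + self.coda_slots != self.n_phoneme_slots:
            raise ValueError(
                "onset_slots + 1 + coda_slots must equal n_phoneme_slots"
            )
        if not 1 < self.first_vowel_slot <= self.n_letter_slots:
            raise ValueError("first_vowel_slot out of range")

    @property
    def ortho_len(self) -> int:
        return self.n_letter_slots * self.alphabet_size

    @property
    def phon_len(self) -> int:
        return self.n_phoneme_slots * self.n_features

    @property
    def vowel_slot(self) -> int:
        """1-based phoneme slot holding the vowel."""
        return self.onset_slots + 1

    @classmethod
    def default(cls) -> "EncodingSpec":
        return cls()

    @classmethod
    def scaled(cls, semantic_dim: int = 150) -> "EncodingSpec":
        """Compact template for desk-scale runs (10 letter slots, 5
        phoneme slots, configurable semantic dimension)."""
        return cls(
            n_letter_slots=10,
            first_vowel_slot=5,
            n_phoneme_slots=5,
            onset_slots=2,
            coda_slots=2,
            semantic_dim=semantic_dim,
        )


# ---------------------------------------------------------------------------
# Word entries
# ---------------------------------------------------------------------------


@dataclass
class PsychFeatures:
    """Psycholinguistic predictors for the reading-aloud analyses."""

    wf: float = float("nan")   # log-compressed frequency, scaled to [0, 1]
    ons: int = 0               # orthographic neighbourhood size
    rc: float = float("nan")   # rime consistency in [0, 1]
    img: float = float("nan")  # imageability proxy in [0, 1]


@dataclass
class WordEntry:
    word_id: str
    spelling: str
    pronunciation: tuple[str, ...]
    semantic_vector: np.ndarray
    frequency: float
    context_code: int = 0
    features: PsychFeatures = field(default_factory=PsychFeatures)
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pronunciation = tuple(self.pronunciation)
        self.semantic_vector = np.asarray(self.semantic_vector, dtype=np.int8)
        if not 0 <= self.context_code <= 4:
            raise ValueError("context_code must be in 0..4")
        if self.semantic_vector.sum() < 1:
            raise ValueError(
                f"{self.word_id}: semantic vector must have >=1 active feature"
            )

    @property
    def semantic_indices(self) -> np.ndarray:
        return np.flatnonzero(self.semantic_vector)

    def context_vector(self) -> np.ndarray:
        v = np.zeros(4, dtype=np.int8)
        if self.context_code > 0:
            v[self.context_code - 1] = 1
        return v


@dataclass
class Lexicon:
    entries: list[WordEntry]
    inventory: PhonemeInventory
    spec: EncodingSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.word_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("word_ids must be unique")
        for e in self.entries:
            for lab in e.pronunciation:
                self.inventory.index(lab)
            if len(e.semantic_vector) != self.spec.semantic_dim:
                raise ValueError(
                    f"{e.word_id}: semantic vector length "
                    f"{len(e.semantic_vector)} != {self.spec.semantic_dim}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> WordEntry:
        return self.entries[i]

    def by_id(self, word_id: str) -> WordEntry:
        for e in self.entries:
            if e.word_id == word_id:
                return e
        raise KeyError(word_id)

    def semantic_matrix(self) -> np.ndarray:
        return np.stack([e.semantic_vector for e in self.entries])


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------


def _first_vowel_index(spelling: str) -> int:
    for i, ch in enumerate(spelling):
        if ch in VOWEL_LETTERS:
            return i
    # words like "by": treat y as the vowel only when no aeiou is present
    for i, ch in enumerate(spelling):
        if ch == "y":
            return i
    raise EncodingError(f"{spelling!r}: no vowel letter")


def orthography_slots(spelling: str, spec: EncodingSpec | None = None
                      ) -> dict[int, str]:
    """Map a spelling to its 1-based letter-slot layout.

    The onset right-aligns against the vowel anchor slot; the first vowel
    letter occupies that slot; an immediately following vowel letter
    occupies the next slot; all remaining letters fill consecutive slots
    starting two slots after the anchor.
    """
    spec = spec or EncodingSpec.default()
    if not spelling or not spelling.isascii() or not spelling.isalpha() \
            or not spelling.islower():
        raise EncodingError(f"{spelling!r}: spelling must be lowercase letters")
    for ch in spelling:
        if _ALPHABET.index(ch) >= spec.alphabet_size:
            raise EncodingError(f"{spelling!r}: letter {ch!r} outside alphabet")
    vi = _first_vowel_index(spelling)
    anchor = spec.first_vowel_slot
    if vi > anchor - 1:
        raise EncodingError(
            f"{spelling!r}: {vi} onset letters overflow slots 1..{anchor - 1}"
        )
    slots: dict[int, str] = {}
    for k, ch in enumerate(spelling[:vi]):
        slots[anchor - vi + k] = ch
    slots[anchor] = spelling[vi]
    j = vi + 1
    if j < len(spelling) and spelling[j] in VOWEL_LETTERS:
        slots[anchor + 1] = spelling[j]
        j += 1
    pos = anchor + 2
    for ch in spelling[j:]:
        if pos > spec.n_letter_slots:
            raise EncodingError(
                f"{spelling!r}: trailing letters overflow slot "
                f"{spec.n_letter_slots}"
            )
        slots[pos] = ch
        pos += 1
    return slots


def encode_orthography(spelling: str, spec: EncodingSpec | None = None
                       ) -> np.ndarray:
    """Binary orthographic vector: one-hot letter within each occupied slot."""
    spec = spec or EncodingSpec.default()
    vec = np.zeros(spec.ortho_len, dtype=np.float64)
    for slot, ch in orthography_slots(spelling, spec).items():
        vec[(slot - 1) * spec.alphabet_size + _ALPHABET.index(ch)] = 1.0
    return vec


def phonology_slots(pronunciation, inventory: PhonemeInventory,
                    spec: EncodingSpec | None = None) -> dict[int, str]:
    """Map a phoneme sequence to its 1-based phoneme-slot layout."""
    spec = spec or EncodingSpec.default()
    pron = tuple(pronunciation)
    if not pron:
        raise EncodingError("empty pronunciation")
    vowel_flags = [inventory.is_vowel(p) for p in pron]
    if sum(vowel_flags) != 1:
        raise EncodingError(
            f"{'/'.join(pron)}: monosyllabic template requires exactly one "
            f"vowel phoneme, got {sum(vowel_flags)}"
        )
    vi = vowel_flags.index(True)
    onset, coda = pron[:vi], pron[vi + 1:]
    if len(onset) > spec.onset_slots:
        raise EncodingError(
            f"{'/'.join(pron)}: {len(onset)} onset phonemes overflow "
            f"{spec.onset_slots} onset slots"
        )
    if len(coda) > spec.coda_slots:
        raise EncodingError(
            f"{'/'.join(pron)}: {len(coda)} coda phonemes overflow "
            f"{spec.coda_slots} coda slots"
        )
    slots: dict[int, str] = {}
    for k, p in enumerate(onset):
        slots[spec.vowel_slot - len(onset) + k] = p
    slots[spec.vowel_slot] = pron[vi]
    for k, p in enumerate(coda):
        slots[spec.vowel_slot + 1 + k] = p
    return slots


def encode_phonology(pronunciation, inventory: PhonemeInventory,
                     spec: EncodingSpec | None = None) -> np.ndarray:
    """Phonological vector: each occupied slot holds the phoneme's feature
    vector; empty slots are all-zero."""
    spec = spec or EncodingSpec.default()
    F = inventory.n_features
    vec = np.zeros(spec.n_phoneme_slots * F, dtype=np.float64)
    for slot, lab in phonology_slots(pronunciation, inventory, spec).items():
        vec[(slot - 1) * F:slot * F] = inventory.vector(lab)
    return vec


def orthographic_rime(spelling: str) -> str:
    """Spelling from the first vowel letter to the end."""
    return spelling[_first_vowel_index(spelling):]


def phonological_rime(pronunciation, inventory: PhonemeInventory
                      ) -> tuple[str, ...]:
    """Phonemes from the vowel nucleus to the end."""
    pron = tuple(pronunciation)
    for i, p in enumerate(pron):
        if inventory.is_vowel(p):
            return pron[i:]
    raise EncodingError(f"{'/'.join(pron)}: no vowel phoneme")


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

# Grapheme-to-phoneme material for the synthetic quasi-regular mapping.
_ONSETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("", ()),
    ("b", ("b",)), ("d", ("d",)), ("f", ("f",)), ("g", ("g",)),
    ("h", ("h",)), ("j", ("dZ",)), ("k", ("k",)), ("l", ("l",)),
    ("m", ("m",)), ("n", ("n",)), ("p", ("p",)), ("r", ("r",)),
    ("s", ("s",)), ("t", ("t",)), ("v", ("v",)), ("w", ("w",)),
    ("y", ("j",)), ("z", ("z",)),
    ("sh", ("S",)), ("ch", ("tS",)), ("th", ("T",)), ("wh", ("w",)),
    ("bl", ("b", "l")), ("br", ("b", "r")), ("cl", ("k", "l")),
    ("cr", ("k", "r")), ("dr", ("d", "r")), ("fl", ("f", "l")),
    ("fr", ("f", "r")), ("gl", ("g", "l")), ("gr", ("g", "r")),
    ("pl", ("p", "l")), ("pr", ("p", "r")), ("sk", ("s", "k")),
    ("sl", ("s", "l")), ("sm", ("s", "m")), ("sn", ("s", "n")),
    ("sp", ("s", "p")), ("st", ("s", "t")), ("sw", ("s", "w")),
    ("tr", ("t", "r")), ("tw", ("t", "w")),
)

# vowel grapheme -> (canonical phoneme, alternate phonemes for deviants)
_VOWELS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("a", "ae", ("eI", "A")),
    ("e", "E", ("i",)),
    ("i", "I", ("aI",)),
    ("o", "A", ("@U",)),
    ("u", "V", ("U",)),
    ("ai", "eI", ("E",)),
    ("ea", "i", ("E",)),
    ("ee", "i", ("I",)),
    ("oa", "@U", ("O",)),
    ("oo", "u", ("U",)),
    ("ou", "aU", ("u",)),
    ("oi", "OI", ("i",)),
)

_CODAS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("", ()),
    ("b", ("b",)), ("d", ("d",)), ("g", ("g",)), ("k", ("k",)),
    ("ck", ("k",)), ("l", ("l",)), ("ll", ("l",)), ("m", ("m",)),
    ("n", ("n",)), ("p", ("p",)), ("s", ("s",)), ("ss", ("s",)),
    ("t", ("t",)), ("x", ("k", "s")), ("sh", ("S",)), ("ch", ("tS",)),
    ("th", ("T",)), ("ft", ("f", "t")), ("ld", ("l", "d")),
    ("lt", ("l", "t")), ("mp", ("m", "p")), ("nd", ("n", "d")),
    ("nt", ("n", "t")), ("sk", ("s", "k")), ("sp", ("s", "p")),
    ("st", ("s", "t")), ("nk", ("N", "k")), ("ng", ("N",)),
)


@dataclass(frozen=True)
class LexiconParams:
    """Generation parameters for a synthetic quasi-regular lexicon.

    Defaults describe the desk-scale study lexicon: 200 entries in rime
    families of 3-6 words, 30% of families inconsistent, sparse binary
    semantics (5-12 of 150 features active per word, the spread doubling
    as the imageability proxy), Zipfian token frequencies with exponent
    1 and 8 two-member homophone families disambiguated by the 4-unit
    context layer.
    """

    n_words: int = 200
    family_size_range: tuple[int, int] = (3, 6)
    prop_inconsistent: float = 0.3
    deviant_fraction: float = 0.34
    semantic_dim: int = 150
    n_active_range: tuple[int, int] = (5, 12)
    n_homophone_families: int = 8
    homophone_family_size: int = 2
    zipf_exponent: float = 1.0
    spec: EncodingSpec | None = None


def _validate_pools(spec: EncodingSpec) -> None:
    max_onset_letters = max(len(o) for o, _ in _ONSETS)
    max_onset_phon = max(len(p) for _, p in _ONSETS)
    max_coda_phon = max(len(p) for _, p in _CODAS)
    max_rime_letters = max(len(v) for v, _, _ in _VOWELS) + \
        max(len(c) for c, _ in _CODAS)
    if max_onset_letters > spec.first_vowel_slot - 1:
        raise GenerationError("onset letters exceed pre-vowel letter slots")
    if max_onset_phon > spec.onset_slots:
        raise GenerationError("onset phonemes exceed onset slots")
    if max_coda_phon > spec.coda_slots:
        raise GenerationError("coda phonemes exceed coda slots")
    # tail letters (beyond the first two vowel letters) start two slots
    # after the anchor
    if spec.first_vowel_slot + 2 + (max_rime_letters - 2) - 1 \
            > spec.n_letter_slots:
        raise GenerationError("rime letters exceed available letter slots")


def generate_lexicon(params: LexiconParams | None = None,
                     seed: int = 0) -> Lexicon:
    """Generate a synthetic lexicon; deterministic for a fixed seed.

    Raises
    ------
    GenerationError
        If the parameter combination is infeasible (family sizes beyond
        the onset pool, homophone families beyond the 4-unit context
        layer, semantic sparsity beyond the semantic dimension, or
        letter/phoneme material that cannot fit the slot template).
    """
    params = params or LexiconParams()
    spec = params.spec or EncodingSpec.scaled(params.semantic_dim)
    if spec.semantic_dim != params.semantic_dim:
        spec = replace(spec, semantic_dim=params.semantic_dim)
    inventory = PhonemeInventory.default()
    _validate_pools(spec)
    rng = np.random.default_rng(seed)

    lo, hi = params.family_size_range
    if not 1 <= lo <= hi:
        raise GenerationError("invalid family_size_range")
    if hi > len(_ONSETS):
        raise GenerationError(
            f"family size {hi} exceeds the {len(_ONSETS)}-onset pool"
        )
    if not 2 <= params.homophone_family_size <= 4:
        raise GenerationError(
            "homophone family size must be 2..4 (4-unit context layer)"
        )
    kmin, kmax = params.n_active_range
    if not 1 <= kmin <= kmax <= params.semantic_dim:
        raise GenerationError("n_active_range incompatible with semantic_dim")

    n_clones = params.n_homophone_families * \
        (params.homophone_family_size - 1)
    n_base = params.n_words - n_clones
    if n_base < max(2, params.n_homophone_families):
        raise GenerationError("n_words too small for the homophone plan")

    rime_pool = [(v, c) for v in range(len(_VOWELS))
                 for c in range(len(_CODAS))]
    rng.shuffle(rime_pool)
    max_families = n_base // lo + 2
    if max_families > len(rime_pool):
        raise GenerationError("not enough distinct rimes for the family plan")

    entries: list[WordEntry] = []
    fam_id = 0
    count = 0
    while count < n_base:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_base - count)
        vi, ci = rime_pool.pop()
        v_spell, v_canon, v_alts = _VOWELS[vi]
        c_spell, c_phon = _CODAS[ci]
        inconsistent = size >= 3 and rng.random() < params.prop_inconsistent
        onset_idx = rng.choice(len(_ONSETS), size=size, replace=False)
        deviants: set[int] = set()
        if inconsistent:
            k_dev = max(1, int(round(params.deviant_fraction * size)))
            k_dev = min(k_dev, (size - 1) // 2 if size >= 3 else 1)
            k_dev = max(k_dev, 1)
            deviants = set(
                rng.choice(size, size=k_dev, replace=False).tolist())
            v_dev = str(rng.choice(list(v_alts)))
        for m, oi in enumerate(onset_idx):
            o_spell, o_phon = _ONSETS[int(oi)]
            vowel_ph = v_dev if m in deviants else v_canon
            entries.append(WordEntry(
                word_id=f"w{len(entries):04d}",
                spelling=o_spell + v_spell + c_spell,
                pronunciation=o_phon + (vowel_ph,) + c_phon,
                semantic_vector=_placeholder_semantics(params.semantic_dim),
                frequency=1.0,
                tags={"rime_family": fam_id,
                      "consistent": not inconsistent,
                      "deviant": m in deviants},
            ))
            count += 1
        fam_id += 1

    # re-sample semantics globally to guarantee uniqueness across entries
    seen: set[frozenset] = set()
    for e in entries:
        e.semantic_vector = _sample_semantics(rng, params, seen)

    # homophone families: clone existing words with new meanings and
    # distinct nonzero context codes across the whole family
    base_pick = rng.choice(len(entries), size=params.n_homophone_families,
                           replace=False)
    hf_id = 0
    for bi in sorted(int(b) for b in base_pick):
        family = [entries[bi]]
        for _ in range(params.homophone_family_size - 1):
            clone = WordEntry(
                word_id=f"w{len(entries):04d}",
                spelling=entries[bi].spelling,
                pronunciation=entries[bi].pronunciation,
                semantic_vector=_sample_semantics(rng, params, seen),
                frequency=1.0,
                tags=dict(entries[bi].tags),
            )
            entries.append(clone)
            family.append(clone)
        codes = rng.choice(4, size=len(family), replace=False) + 1
        for e, code in zip(family, codes):
            e.context_code = int(code)
            e.tags["homophone_family"] = hf_id
        hf_id += 1

    # Zipfian token frequencies over a random rank assignment
    n = len(entries)
    ranks = rng.permutation(n) + 1
    freqs = ranks.astype(np.float64) ** (-params.zipf_exponent)
    for e, f in zip(entries, freqs):
        e.frequency = float(f)

    lex = Lexicon(entries=entries, inventory=inventory, spec=spec,
                  meta={"seed": int(seed), "params": _params_dict(params)})
    compute_psych_features(lex)
    _tag_factorial_cells(lex)
    # every spelling/pronunciation must fit the slot template
    for e in lex:
        orthography_slots(e.spelling, spec)
        phonology_slots(e.pronunciation, inventory, spec)
    return lex


def _placeholder_semantics(dim: int) -> np.ndarray:
    vec = np.zeros(dim, dtype=np.int8)
    vec[0] = 1
    return vec


def _sample_semantics(rng: np.random.Generator, params: LexiconParams,
                      seen: set[frozenset]) -> np.ndarray:
    kmin, kmax = params.n_active_range
    for _ in range(1000):
        k = int(rng.integers(kmin, kmax + 1))
        idx = rng.choice(params.semantic_dim, size=k, replace=False)
        key = frozenset(int(i) for i in idx)
        if key not in seen:
            seen.add(key)
            vec = np.zeros(params.semantic_dim, dtype=np.int8)
            vec[idx] = 1
            return vec
    raise GenerationError("could not sample distinct semantic vectors")


def _params_dict(params: LexiconParams) -> dict:
    d = {k: getattr(params, k) for k in (
        "n_words", "family_size_range", "prop_inconsistent",
        "deviant_fraction", "semantic_dim", "n_active_range",
        "n_homophone_families", "homophone_family_size", "zipf_exponent")}
    d["family_size_range"] = list(d["family_size_range"])
    d["n_active_range"] = list(d["n_active_range"])
    return d


# ---------------------------------------------------------------------------
# Psycholinguistic predictors
# ---------------------------------------------------------------------------


def compute_ons(entry: WordEntry, lexicon: Lexicon) -> int:
    """Orthographic neighbourhood size: other words of equal length whose
    spelling differs by exactly one letter substitution."""
    n = 0
    for other in lexicon:
        if other is entry or len(other.spelling) != len(entry.spelling):
            continue
        diffs = sum(a != b for a, b in zip(entry.spelling, other.spelling))
        if diffs == 1:
            n += 1
    return n


def compute_rime_consistency(entry: WordEntry, lexicon: Lexicon,
                             weighting: str = "token") -> float:
    """Rime consistency: the (frequency-weighted) proportion of words
    sharing the orthographic rime -- including the word itself -- whose
    rime pronunciation matches the entry's.

    ``weighting="token"`` (default) weights by token frequency;
    ``"type"`` counts words equally.  A word whose rime is unique in the
    lexicon has consistency 1.0 by the self-inclusion convention.
    """
    if weighting not in ("token", "type"):
        raise ValueError("weighting must be 'token' or 'type'")
    rime = orthographic_rime(entry.spelling)
    own = phonological_rime(entry.pronunciation, lexicon.inventory)
    friends = enemies = 0.0
    for other in lexicon:
        if orthographic_rime(other.spelling) != rime:
            continue
        w = other.frequency if weighting == "token" else 1.0
        if phonological_rime(other.pronunciation, lexicon.inventory) == own:
            friends += w
        else:
            enemies += w
    return friends / (friends + enemies)


def compute_psych_features(lexicon: Lexicon,
                           rc_weighting: str = "token") -> None:
    """Fill WF, ONS, RC and the IMG proxy for every entry, in place.

    WF is log-compressed token frequency min-max scaled to [0, 1]; IMG is
    the number of active semantic features min-max scaled to [0, 1]
    (richer semantics standing in for higher imageability).  Entries
    whose ``img`` was set externally (e.g. imported norms) keep it.
    """
    logf = np.log(np.array([e.frequency for e in lexicon], dtype=np.float64))
    span = logf.max() - logf.min()
    wf = (logf - logf.min()) / span if span > 0 else np.full(len(lexicon), .5)
    k = np.array([int(e.semantic_vector.sum()) for e in lexicon], float)
    kspan = k.max() - k.min()
    img = (k - k.min()) / kspan if kspan > 0 else np.full(len(lexicon), .5)
    for i, e in enumerate(lexicon):
        e.features.wf = float(wf[i])
        e.features.ons = compute_ons(e, lexicon)
        e.features.rc = compute_rime_consistency(e, lexicon, rc_weighting)
        if not np.isfinite(e.features.img):
            e.features.img = float(img[i])


def set_imageability(lexicon: Lexicon, norms: dict[str, float]) -> None:
    """Import external imageability norms (word_id -> value); values are
    min-max scaled to [0, 1] over the provided set."""
    vals = np.array(list(norms.values()), dtype=np.float64)
    lo, hi = vals.min(), vals.max()
    for e in lexicon:
        if e.word_id in norms:
            v = norms[e.word_id]
            e.features.img = float((v - lo) / (hi - lo)) if hi > lo else 0.5
    _tag_factorial_cells(lexicon)


def _tag_factorial_cells(lexicon: Lexicon) -> None:
    imgs = np.array([e.features.img for e in lexicon])
    if not np.isfinite(imgs).all():
        return
    med = float(np.median(imgs))
    for e in lexicon:
        hi = e.features.img >= med
        cons = bool(e.tags.get("consistent", e.features.rc >= 1.0))
        e.tags["img_high"] = bool(hi)
        e.tags["cell"] = (("high" if hi else "low") + "_img|"
                          + ("consistent" if cons else "inconsistent"))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("word_id", "spelling", "pronunciation", "semantics",
                "frequency", "context_code", "img")


def write_lexicon(lexicon: Lexicon, path) -> None:
    """Write a lexicon as TSV or JSON (dispatch on the file suffix)."""
    path = Path(path)
    if path.suffix == ".tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for e in lexicon:
            lines.append("\t".join([
                e.word_id, e.spelling, " ".join(e.pronunciation),
                ",".join(str(i) for i in e.semantic_indices),
                repr(e.frequency), str(e.context_code),
                repr(float(e.features.img)),
            ]))
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix == ".json":
        doc = {
            "spec": {k: getattr(lexicon.spec, k) for k in (
                "n_letter_slots", "alphabet_size", "first_vowel_slot",
                "n_phoneme_slots", "onset_slots", "coda_slots",
                "semantic_dim", "n_features")},
            "inventory": {
                "feature_names": list(lexicon.inventory.feature_names),
                "phonemes": [
                    {"label": lab,
                     "features": lexicon.inventory.features[i].tolist()}
                    for i, lab in enumerate(lexicon.inventory.labels)],
            },
            "meta": lexicon.meta,
            "entries": [
                {"word_id": e.word_id, "spelling": e.spelling,
                 "pronunciation": list(e.pronunciation),
                 "semantics": [int(i) for i in e.semantic_indices],
                 "frequency": e.frequency, "context_code": e.context_code,
                 "img": float(e.features.img),
                 "tags": _jsonable_tags(e.tags)}
                for e in lexicon],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unsupported lexicon format {path.suffix!r}")


def _jsonable_tags(tags: dict) -> dict:
    out = {}
    for k, v in tags.items():
        out[k] = bool(v) if isinstance(v, (bool, np.bool_)) else \
            int(v) if isinstance(v, (int, np.integer)) else v
    return out


def read_lexicon(path, inventory: PhonemeInventory | None = None,
                 spec: EncodingSpec | None = None) -> Lexicon:
    """Read a lexicon written by :func:`write_lexicon`.

    TSV files carry entries only; the inventory and encoding spec default
    to the built-in ones unless supplied.  Derived predictors (WF, ONS,
    RC) are recomputed; IMG is taken from the file.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        spec = EncodingSpec(**doc["spec"])
        inv = doc["inventory"]
        inventory = PhonemeInventory(
            labels=tuple(p["label"] for p in inv["phonemes"]),
            features=np.array([p["features"] for p in inv["phonemes"]],
                              dtype=np.int8),
            feature_names=tuple(inv["feature_names"]),
        )
        rows = [(e, e.get("tags", {})) for e in doc["entries"]]
        meta = doc.get("meta", {})
    elif path.suffix == ".tsv":
        inventory = inventory or PhonemeInventory.default()
        text = path.read_text().rstrip("\n").split("\n")
        header = text[0].split("\t")
        if tuple(header) != _TSV_COLUMNS:
            raise LexiconParseError(f"row 1: bad header {header}")
        rows = []
        for ln, line in enumerate(text[1:], start=2):
            f = line.split("\t")
            if len(f) != len(_TSV_COLUMNS):
                raise LexiconParseError(
                    f"row {ln}: expected {len(_TSV_COLUMNS)} fields, "
                    f"got {len(f)}")
            rows.append(({
                "word_id": f[0], "spelling": f[1],
                "pronunciation": f[2].split() if f[2] else [],
                "semantics": [int(x) for x in f[3].split(",")] if f[3]
                else [],
                "frequency": float(f[4]), "context_code": int(f[5]),
                "img": float(f[6]), "_row": ln}, {}))
        meta = {}
    else:
        raise ValueError(f"unsupported lexicon format {path.suffix!r}")

    if spec is None:
        spec = EncodingSpec.scaled() if rows else EncodingSpec.default()
        # infer semantic dimension from the largest feature index
        top = max((max(r[0]["semantics"], default=0) for r in rows),
                  default=0)
        if top >= spec.semantic_dim:
            spec = replace(spec, semantic_dim=top + 1)

    entries = []
    seen_ids: set[str] = set()
    for r, tags in rows:
        row = r.get("_row", r["word_id"])
        if not r["pronunciation"]:
            raise LexiconParseError(f"row {row}: missing pronunciation")
        for lab in r["pronunciation"]:
            if lab not in inventory.labels:
                raise LexiconParseError(
                    f"row {row}: unknown phoneme label {lab!r}")
        if r["word_id"] in seen_ids:
            raise LexiconParseError(
                f"row {row}: duplicate word_id {r['word_id']!r}")
        seen_ids.add(r["word_id"])
        vec = np.zeros(spec.semantic_dim, dtype=np.int8)
        vec[np.array(r["semantics"], dtype=int)] = 1
        e = WordEntry(word_id=r["word_id"], spelling=r["spelling"],
                      pronunciation=tuple(r["pronunciation"]),
                      semantic_vector=vec, frequency=r["frequency"],
                      context_code=r["context_code"], tags=dict(tags))
        e.features.img = float(r["img"])
        entries.append(e)
    lex = Lexicon(entries=entries, inventory=inventory, spec=spec, meta=meta)
    compute_psych_features(lex)
    _tag_factorial_cells(lex)
    return lex


def write_inventory(inventory: PhonemeInventory, path) -> None:
    """TSV of phoneme label plus one binary column per feature."""
    names = inventory.feature_names or tuple(
        f"f{i}" for i in range(inventory.n_features))
    lines = ["\t".join(("label",) + tuple(names))]
    for i, lab in enumerate(inventory.labels):
        lines.append("\t".join(
            [lab] + [str(int(x)) for x in inventory.features[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_inventory(path) -> PhonemeInventory:
    text = Path(path).read_text().rstrip("\n").split("\n")
    names = tuple(text[0].split("\t")[1:])
    labels, feats = [], []
    for ln, line in enumerate(text[1:], start=2):
        f = line.split("\t")
        if len(f) != len(names) + 1:
            raise LexiconParseError(f"row {ln}: expected {len(names) + 1} "
                                    f"fields, got {len(f)}")
        labels.append(f[0])
        feats.append([int(x) for x in f[1:]])
    return PhonemeInventory(labels=tuple(labels),
                            features=np.array(feats, dtype=np.int8),
                            feature_names=names)
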