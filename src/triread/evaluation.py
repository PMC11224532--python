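"""Scoring of trained models: SSE, nearest-pattern accuracy, polarity.

Reading-aloud performance is scored on the phonological output: the sum
of squared error against the target pattern (averaged over the trial's
error-injection window) serves as the latency proxy, and a response is
correct when the nearest inventory phoneme (Euclidean distance, with the
all-zero pattern as the empty-slot competitor) matches the target in
every phoneme slot.  Semantic accuracy is a nearest-neighbour search
over the semantic vectors of the whole training set.

Unit polarity measures how binarised an activation is,

    y = x log2 x + (1 - x) log2 (1 - x) + 1,

0 at x = 0.5 and 1 at x in {0, 1}; high mean polarity at the
phonological layer indicates refined output representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from . import netcore
from .lexicon import EncodingSpec, PhonemeInventory, phonology_slots

__all__ = [
    "PhonologyResult",
    "SemanticsResult",
    "PolarityScore",
    "phon_sse",
    "decode_phonology",
    "sem_accuracy",
    "unit_polarity",
    "polarity_profile",
    "mean_phon_polarity",
    "evaluate_reading",
]


@dataclass
class PhonologyResult:
    word_id: str | None
    sse: float
    decoded: tuple[str, ...]
    correct: bool


@dataclass
class SemanticsResult:
    word_id: str | None
    sse: float
    nearest_word_id: str
    correct: bool


def phon_sse(trace: netcore.ActivationTrace, target: np.ndarray,
             window: tuple[int, int], layer: str = "phonology") -> float:
    """Squared error summed over units, averaged over window timesteps."""
    t0, t1 = window
    a = trace[layer][t0:t1 + 1].astype(np.float64)
    y = np.asarray(target, dtype=np.float64)
    return float(((a - y) ** 2).sum(axis=1).mean())


def _slot_decode(mean_out: np.ndarray, inventory: PhonemeInventory,
                 spec: EncodingSpec) -> tuple[str, ...]:
    """Per slot, the inventory phoneme (or empty pattern) nearest to the
    output; ties go to the lowest inventory index."""
    F = inventory.n_features
    slots = mean_out.reshape(spec.n_phoneme_slots, F)
    cands = np.vstack([inventory.features.astype(np.float64),
                       np.zeros((1, F))])
    d2 = ((slots[:, None, :] - cands[None, :, :]) ** 2).sum(axis=2)
    picks = np.argmin(d2, axis=1)
    return tuple("" if p == len(inventory.labels) else inventory.labels[p]
                 for p in picks)


def decode_phonology(trace: netcore.ActivationTrace,
                     inventory: PhonemeInventory, spec: EncodingSpec,
                     window: tuple[int, int], *,
                     target=None, word_id: str | None = None
                     ) -> PhonologyResult:
    """Decode the mean phonological output over the window; when a
    target pronunciation is given, the response is correct iff actual
    and target phonemes match across all phoneme slots."""
    mean_out = trace.window_mean("phonology", window).astype(np.float64)
    decoded = _slot_decode(mean_out, inventory, spec)
    correct = False
    sse = float("nan")
    if target is not None:
        tslots = phonology_slots(target, inventory, spec)
        want = tuple(tslots.get(s + 1, "")
                     for s in range(spec.n_phoneme_slots))
        correct = decoded == want
        from .lexicon import encode_phonology
        sse = float(((mean_out - encode_phonology(target, inventory, spec))
                     ** 2).sum())
    return PhonologyResult(word_id=word_id, sse=sse, decoded=decoded,
                           correct=correct)


def sem_accuracy(trace: netcore.ActivationTrace, lexicon,
                 window: tuple[int, int], word_index: int
                 ) -> SemanticsResult:
    """Nearest-neighbour search of the mean semantic output over the
    semantic vectors of every word in the training set; correct iff the
    argmin is the target entry (ties to the lowest word_id)."""
    from .training import CompiledLexicon
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) else None
    sem = compiled.sem.astype(np.float64) if compiled is not None \
        else lexicon.semantic_matrix().astype(np.float64)
    entries = compiled.lexicon if compiled is not None else lexicon
    mean_out = trace.window_mean("semantics", window).astype(np.float64)
    d2 = ((sem - mean_out) ** 2).sum(axis=1)
    # argmin with ties resolved to the lowest word_id
    best = min(range(len(d2)), key=lambda i: (d2[i], entries[i].word_id))
    tgt = entries[word_index]
    return SemanticsResult(
        word_id=tgt.word_id,
        sse=float(((mean_out - sem[word_index]) ** 2).sum()),
        nearest_word_id=entries[best].word_id,
        correct=best == word_index)


def unit_polarity(x):
    """Binarisation index y = x log2 x + (1-x) log2 (1-x) + 1 with the
    0 log 0 = 0 convention; y(0.5) = 0, y(0) = y(1) = 1."""
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("unit activation must lie in [0, 1]")
    ln2 = np.log(2.0)
    y = (xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / ln2 + 1.0
    return float(y) if np.isscalar(x) else y


def evaluate_reading(weights: netcore.WeightSet, compiled,
                     index: int | None = None):
    """Run reading-aloud (OP) trials and return per-word phonological
    results for one word or the whole lexicon."""
    from .training import READING_TASKS
    task = READING_TASKS["OP"]
    idx = range(len(compiled)) if index is None else [index]
    out = []
    for i in idx:
        tr = netcore.forward_trial(weights, compiled.trial(i, task))
        res = decode_phonology(
            tr, compiled.lexicon.inventory, compiled.lexicon.spec,
            task.window, target=compiled.lexicon[i].pronunciation,
            word_id=compiled.lexicon[i].word_id)
        res.sse = phon_sse(tr, compiled.phon[i], task.window)
        out.append(res)
    return out[0] if index is not None else out


@dataclass
class PolarityScore:
    """Per-unit polarities for each word, their per-word means and the
    model-level mean."""

    per_unit: np.ndarray   # (n_words, n_phonological_units), in [0, 1]
    per_word: np.ndarray   # (n_words,)

    @property
    def mean(self) -> float:
        return float(self.per_word.mean())


def polarity_profile(weights: netcore.WeightSet, compiled) -> PolarityScore:
    """Unit polarity of the phonological output for every word: each
    word is read (O presented, network settles) and polarity is taken on
    the window-mean phonological pattern."""
    from .training import READING_TASKS
    task = READING_TASKS["OP"]
    rows = []
    for i in range(len(compiled)):
        tr = netcore.forward_trial(weights, compiled.trial(i, task))
        a = tr.window_mean("phonology", task.window)
        rows.append(unit_polarity(np.clip(a, 0.0, 1.0)))
    per_unit = np.stack(rows)
    return PolarityScore(per_unit=per_unit, per_word=per_unit.mean(axis=1))


def mean_phon_polarity(weights: netcore.WeightSet, compiled) -> float:
    """Model-level mean polarity: per-unit polarity averaged over the
    phonological units, then over all words in the training set."""
    return polarity_profile(weights, compiled).mean
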