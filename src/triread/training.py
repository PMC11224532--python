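"""Two-phase training curriculum and the three instructional regimens.

Phase 1 (oral language) interleaves four tasks on the phonology/semantics
side of the network: semantics-to-phonology (SP, a meaning-naming task),
phonology-to-semantics (PS, an oral-vocabulary task) and the two
attractor tasks (PP, SS) that teach the cleanup layers to restore their
own patterns, mixed 40/40/10/10 by default.  Phase 2 (reading) freezes
everything learned orally and trains the orthographic routes, choosing
print-to-sound (OP) or print-to-meaning (OS) per trial with
regimen-specific probabilities: 75/25 for phonology-focused instruction,
50/50 for balanced, 25/75 for meaning-focused.

Words are sampled by (log-compressed) token frequency.  The homophone
context pattern is clamped only on trials whose target is semantics;
it is all-zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import netcore
from .errors import ConfigurationError
from .lexicon import Lexicon, encode_orthography, encode_phonology
from .netcore import (ORAL_BIAS_LAYERS, ORAL_GROUPS, READING_BIAS_LAYERS,
                      READING_GROUPS, TrialSpec, WeightSet)

__all__ = [
    "TaskSpec",
    "RegimenSpec",
    "TrainingLog",
    "CompiledLexicon",
    "ORAL_MIXTURE",
    "sample_word",
    "sample_task",
    "make_regimens",
    "run_oral_phase",
    "run_reading_phase",
]


@dataclass(frozen=True)
class TaskSpec:
    """Clamp/target schedule for one task type."""

    name: str
    input_layer: str
    target_layer: str
    clamp_steps: int
    total_steps: int
    window: tuple[int, int]
    use_context: bool = False


#: Oral tasks: inputs presented for all 8 timesteps (SP/PS) or clamped
#: for 2 and cycled for 6 (attractors), error on the last 2 steps
#: (SP/PS) or the whole free-run (PP/SS).
ORAL_TASKS: dict[str, TaskSpec] = {
    "SP": TaskSpec("SP", "semantics", "phonology", 8, 8, (7, 8)),
    "PS": TaskSpec("PS", "phonology", "semantics", 8, 8, (7, 8),
                   use_context=True),
    "PP": TaskSpec("PP", "phonology", "phonology", 2, 8, (3, 8)),
    "SS": TaskSpec("SS", "semantics", "semantics", 2, 8, (3, 8)),
}

#: Reading tasks: print presented for all 12 timesteps, error on the
#: last 3.
READING_TASKS: dict[str, TaskSpec] = {
    "OP": TaskSpec("OP", "orthography", "phonology", 12, 12, (10, 12)),
    "OS": TaskSpec("OS", "orthography", "semantics", 12, 12, (10, 12),
                   use_context=True),
}

#: 40% SP, 40% PS, 10% PP, 10% SS.
ORAL_MIXTURE: dict[str, float] = {"SP": 0.4, "PS": 0.4, "PP": 0.1,
                                  "SS": 0.1}


@dataclass(frozen=True)
class RegimenSpec:
    """One instructional condition for one simulated individual."""

    name: str
    p_op: float
    p_os: float
    reading_trials: int = 1_000_000
    oral_trials: int = 2_000_000
    oral_mixture: tuple = tuple(ORAL_MIXTURE.items())
    seed: int = 0
    #: seed for the word/task sampling streams; defaults to ``seed``.
    #: Models sharing a stream_seed see identical trial sequences and
    #: differ only in initial weights (and, across regimens, in the
    #: exposure threshold applied to the same task coin).
    stream_seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.p_op + self.p_os - 1.0) > 1e-9:
            raise ValueError("p_OP + p_OS must equal 1")
        mix = dict(self.oral_mixture)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("oral task mixture must sum to 1")
        if any(p < 0 for p in mix.values()):
            raise ValueError("negative task probability")


REGIMEN_EXPOSURES = (
    ("OP-focused", 0.75, 0.25),
    ("OP-OS balanced", 0.50, 0.50),
    ("OS-focused", 0.25, 0.75),
)


def make_regimens(budgets: dict | None = None, seeds=range(40)
                  ) -> list[RegimenSpec]:
    """The three instructional regimens replicated across seeds
    (40 seeds x 3 regimens gives the full 120-model cohort)."""
    budgets = budgets or {}
    out = []
    for seed in seeds:
        for name, p_op, p_os in REGIMEN_EXPOSURES:
            out.append(RegimenSpec(
                name=name, p_op=p_op, p_os=p_os,
                reading_trials=budgets.get("reading_trials", 1_000_000),
                oral_trials=budgets.get("oral_trials", 2_000_000),
                seed=int(seed)))
    return out


@dataclass
class TrainingLog:
    """Per-checkpoint trial counts, running loss and probe accuracies."""

    phase: str = ""
    checkpoints: list = field(default_factory=list)
    task_counts: dict = field(default_factory=dict)

    def record(self, trial_count: int, mean_loss: float,
               phon_acc: float | None = None,
               sem_acc: float | None = None, note: str = "") -> None:
        if self.checkpoints and \
                trial_count <= self.checkpoints[-1]["trial_count"]:
            raise ValueError("checkpoint trial counts must increase")
        self.checkpoints.append({
            "trial_count": trial_count, "mean_loss": mean_loss,
            "phon_accuracy": phon_acc, "sem_accuracy": sem_acc,
            "note": note})


class CompiledLexicon:
    """Dense encoded patterns for every entry, plus sampling tables.

    Built once per (lexicon, dtype); training and evaluation index into
    its arrays instead of re-encoding words.
    """

    def __init__(self, lexicon: Lexicon, dtype=np.float32,
                 frequency_compression: str = "log"):
        self.lexicon = lexicon
        self.dtype = np.dtype(dtype)
        spec, inv = lexicon.spec, lexicon.inventory
        self.ortho = np.stack([
            encode_orthography(e.spelling, spec) for e in lexicon]) \
            .astype(dtype)
        self.phon = np.stack([
            encode_phonology(e.pronunciation, inv, spec) for e in lexicon]) \
            .astype(dtype)
        self.sem = lexicon.semantic_matrix().astype(dtype)
        self.ctx = np.stack([e.context_vector() for e in lexicon]) \
            .astype(dtype)
        self.is_homophone = np.array([e.context_code > 0 for e in lexicon])
        self.word_cdf = _frequency_cdf(lexicon, frequency_compression)

    def __len__(self) -> int:
        return len(self.lexicon)

    def sample_index(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self.word_cdf, rng.random(),
                                   side="right"))

    def trial(self, i: int, task: TaskSpec, criterion: str = "ce"
              ) -> TrialSpec:
        patterns = {"orthography": self.ortho, "phonology": self.phon,
                    "semantics": self.sem}
        clamps = [(task.input_layer, patterns[task.input_layer][i],
                   task.clamp_steps)]
        if task.use_context:
            clamps.append(("context", self.ctx[i], task.total_steps))
        return TrialSpec(clamps=clamps, timesteps=task.total_steps,
                         target_layer=task.target_layer,
                         target=patterns[task.target_layer][i],
                         window=task.window, criterion=criterion)


def _frequency_cdf(lexicon: Lexicon, frequency_compression: str
                   ) -> np.ndarray:
    freqs = np.array([e.frequency for e in lexicon], dtype=np.float64)
    if (freqs < 0).any():
        raise ValueError("negative word frequency")
    if freqs.sum() == 0:
        raise ValueError("cannot sample words: all frequencies are zero")
    if frequency_compression == "log":
        weights = np.log1p(freqs / freqs[freqs > 0].min())
    elif frequency_compression == "none":
        weights = freqs
    else:
        raise ValueError("frequency_compression must be 'log' or 'none'")
    return np.cumsum(weights / weights.sum())


def sample_word(lexicon: Lexicon, rng: np.random.Generator,
                frequency_compression: str = "log"):
    """Draw a word with probability proportional to its (optionally
    log-compressed) token frequency."""
    cache = getattr(lexicon, "_sampling_cache", None)
    if cache is None or cache[0] != frequency_compression:
        cdf = _frequency_cdf(lexicon, frequency_compression)
        lexicon._sampling_cache = cache = (frequency_compression, cdf)
    return lexicon[int(np.searchsorted(cache[1], rng.random(),
                                       side="right"))]


def sample_task(mixture, rng: np.random.Generator) -> str:
    """Categorical draw of a task name from a {name: prob} mixture."""
    mix = dict(mixture)
    names = list(mix)
    probs = np.array([mix[n] for n in names], dtype=np.float64)
    if (probs < 0).any():
        raise ValueError("negative task probability")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("task mixture must sum to 1")
    return names[int(np.searchsorted(np.cumsum(probs), rng.random(),
                                     side="right").clip(0, len(names) - 1))]


def _check_topology(weights: WeightSet, compiled: CompiledLexicon) -> None:
    sizes = weights.topology.layer_sizes
    want = {"orthography": compiled.ortho.shape[1],
            "phonology": compiled.phon.shape[1],
            "semantics": compiled.sem.shape[1], "context": 4}
    for layer, size in want.items():
        if sizes[layer] != size:
            raise ConfigurationError(
                f"layer {layer!r} has {sizes[layer]} units but the lexicon "
                f"encodes {size}")


def _probe_accuracy(weights: WeightSet, compiled: CompiledLexicon,
                    probe_idx, tasks: dict) -> tuple[float, float]:
    """Fraction of probe words produced correctly on the phonology- and
    semantics-target tasks of a phase."""
    from .evaluation import decode_phonology, sem_accuracy
    phon_task = next(t for t in tasks.values()
                     if t.target_layer == "phonology" and t.clamp_steps
                     == t.total_steps)
    sem_task = next(t for t in tasks.values()
                    if t.target_layer == "semantics")
    n_ok_p = n_ok_s = 0
    for i in probe_idx:
        tr = netcore.forward_trial(weights, compiled.trial(i, phon_task))
        res = decode_phonology(tr, compiled.lexicon.inventory,
                               compiled.lexicon.spec, phon_task.window,
                               target=compiled.lexicon[i].pronunciation)
        n_ok_p += res.correct
        tr = netcore.forward_trial(weights, compiled.trial(i, sem_task))
        n_ok_s += sem_accuracy(tr, compiled, sem_task.window, i).correct
    return n_ok_p / len(probe_idx), n_ok_s / len(probe_idx)


def _probe_indices(compiled: CompiledLexicon, seed: int = 0,
                   cap: int = 1000) -> np.ndarray:
    n = len(compiled)
    if n <= cap:
        return np.arange(n)
    return np.random.default_rng(seed).choice(n, size=cap, replace=False)


def run_oral_phase(weights: WeightSet, lexicon, regimen: RegimenSpec, *,
                   learning_rate: float = 0.05, log_interval: int = 10_000,
                   probe: bool = True
                   ) -> tuple[WeightSet, TrainingLog]:
    """Train the oral-language tasks; only phonology/semantics-side
    groups (oral mappings, attractors, context path) are trainable.

    Returns updated weights (a copy) and the phase log.  Deterministic
    for a fixed regimen seed and lexicon.
    """
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) \
        else CompiledLexicon(lexicon, dtype=weights.dtype)
    _check_topology(weights, compiled)
    ws = weights.copy()
    ws.set_trainable(set(ORAL_GROUPS), set(ORAL_BIAS_LAYERS))
    stream = regimen.stream_seed if regimen.stream_seed is not None \
        else regimen.seed
    rng_word = np.random.default_rng([stream, 11])
    rng_task = np.random.default_rng([stream, 13])
    mixture = dict(regimen.oral_mixture)
    names = list(mixture)
    task_cdf = np.cumsum([mixture[n] for n in names])
    log = TrainingLog(phase="oral",
                      task_counts={n: 0 for n in names})
    probe_idx = _probe_indices(compiled, seed=regimen.seed)
    loss_acc, loss_n = 0.0, 0
    for trial_i in range(regimen.oral_trials):
        wi = compiled.sample_index(rng_word)
        task = names[int(np.searchsorted(task_cdf, rng_task.random(),
                                         side="right")
                         .clip(0, len(names) - 1))]
        log.task_counts[task] += 1
        loss = netcore.train_step(ws, compiled.trial(wi, ORAL_TASKS[task]),
                                  learning_rate)
        loss_acc += loss
        loss_n += 1
        if (trial_i + 1) % log_interval == 0 \
                or trial_i + 1 == regimen.oral_trials:
            pa, sa = _probe_accuracy(ws, compiled, probe_idx, ORAL_TASKS) \
                if probe else (None, None)
            log.record(trial_i + 1, loss_acc / max(loss_n, 1), pa, sa)
            loss_acc, loss_n = 0.0, 0
    ws.meta.update({"phase": "oral",
                    "trial_count": regimen.oral_trials,
                    "oral_seed": regimen.seed})
    return ws, log


def run_reading_phase(oral_weights: WeightSet, lexicon,
                      regimen: RegimenSpec, *,
                      learning_rate: float = 0.05,
                      log_interval: int = 10_000, probe: bool = True
                      ) -> tuple[WeightSet, TrainingLog]:
    """Train the reading mappings on top of frozen oral weights.

    Per trial an OP or OS presentation is drawn with the regimen's
    exposure probabilities; only the orthography-originating groups are
    trainable, so every oral matrix (P<->S mappings, attractors, context
    path) is bit-identical before and after the phase.
    """
    if oral_weights.meta.get("phase") not in ("oral", "reading"):
        raise ConfigurationError(
            "reading phase requires oral-trained weights "
            "(run_oral_phase or a loaded oral checkpoint)")
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) \
        else CompiledLexicon(lexicon, dtype=oral_weights.dtype)
    _check_topology(oral_weights, compiled)
    ws = oral_weights.copy()
    ws.set_trainable(set(READING_GROUPS), set(READING_BIAS_LAYERS))
    # separate word/task streams: within a seed, regimens see the same
    # word sequence and coin sequence and differ only in the exposure
    # threshold applied to the coin (common random numbers)
    stream = regimen.stream_seed if regimen.stream_seed is not None \
        else regimen.seed
    rng_word = np.random.default_rng([stream, 17])
    rng_task = np.random.default_rng([stream, 19])
    log = TrainingLog(phase="reading", task_counts={"OP": 0, "OS": 0})
    probe_idx = _probe_indices(compiled, seed=regimen.seed)
    loss_acc, loss_n = 0.0, 0
    for trial_i in range(regimen.reading_trials):
        wi = compiled.sample_index(rng_word)
        task = "OP" if rng_task.random() < regimen.p_op else "OS"
        log.task_counts[task] += 1
        loss = netcore.train_step(
            ws, compiled.trial(wi, READING_TASKS[task]), learning_rate)
        loss_acc += loss
        loss_n += 1
        if (trial_i + 1) % log_interval == 0 \
                or trial_i + 1 == regimen.reading_trials:
            pa, sa = _probe_accuracy(ws, compiled, probe_idx,
                                     READING_TASKS) if probe \
                else (None, None)
            log.record(trial_i + 1, loss_acc / max(loss_n, 1), pa, sa)
            loss_acc, loss_n = 0.0, 0
    ws.meta.update({"phase": "reading", "regimen": regimen.name,
                    "trial_count": oral_weights.meta.get("trial_count", 0)
                    + regimen.reading_trials,
                    "reading_seed": regimen.seed})
    return ws, log
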