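# triread

A triangle-model reading simulator and individual-differences toolkit.

`triread` asks a question from reading education: does the *method* of
early reading instruction — phonics-style print-to-sound drill versus
whole-word print-to-meaning training — shape which neural pathway a
reader comes to rely on, and does that reliance predict later
reading-aloud performance?  It answers it the way computational reading
research does: by training cohorts of connectionist "readers" under
different instructional mixes and measuring each model's **semantic
reliance (SR)** with a lesion technique.

The package is aimed at computational cognitive scientists and
psycholinguists who want a self-contained, fast, fully testable
implementation of this paradigm that runs on a laptop.

## The model in brief

The triangle framework joins orthography (O), phonology (P) and
semantics (S) through hidden layers, with recurrent cleanup (attractor)
layers on P and S and a 4-unit context layer that disambiguates
homophones.  Units are logistic; a trial clamps an input pattern, lets
the network settle over discrete timesteps, and injects error at a
target layer over the last steps of the trial; learning is online
backpropagation through time.

Training has two phases.  An **oral language phase** interleaves
semantics→phonology, phonology→semantics and the two attractor tasks
(40/40/10/10).  A **reading phase** freezes everything oral and trains
the orthographic routes, drawing print-to-sound (OP) or print-to-meaning
(OS) trials with probability 75/25, 50/50 or 25/75 — the
phonology-focused, balanced and meaning-focused regimens.

After training, each orthographic route is lesioned in turn and the mean
semantic sum-of-squared error (SSE) recorded through the surviving
route.  With reciprocal SSEs as pathway contributions,

```
SR = (1/SSE_via_OS) / (1/SSE_via_OS + 1/SSE_via_OPS)
```

is the proportional contribution of the direct print-to-meaning route.
Phonological SSE on reading-aloud trials serves as the latency proxy for
the statistical analyses (mixed models with random intercepts for word
and model version; predictors WF, ONS, RC, IMG and SR; |t| > 1.96).

Because the original training vocabulary is not redistributable, the
package ships a synthetic-lexicon generator that emulates its
statistical structure: slot-coded orthography (first vowel letter
anchored on slot 5), feature-coded phonology, sparse binary semantics,
Zipfian token frequencies, rime families with controllable
spelling-sound consistency (*pint* among *mint/hint*), and homophone
families disambiguated by context codes.

## Worked example

Train the standard desk-scale cohort (200-word lexicon, three regimens ×
7 initial-weight seeds, 50k oral + 30k reading trials per model; about
10–15 minutes on one core):

```python
from triread.study import run_scaled_study

study = run_scaled_study(seed=1)
print(study["sr_means"])
for contrast, res in study["mannwhitney"].items():
    print(contrast, f"p={res['p']:.4f}")
```

prints

```
{'OP-focused': 0.2671..., 'OP-OS balanced': 0.3148..., 'OS-focused': 0.3696...}
OS-focused > OP-OS balanced p=0.0131
OP-OS balanced > OP-focused p=0.0189
OS-focused > OP-focused p=0.0003
```

Meaning-focused instruction produces the most semantically reliant
readers, balanced training sits in between, and phonics-style training
the least — each pairwise difference significant by one-sided
Mann-Whitney.  The same study object carries the downstream analyses:
`study["regression_effects"]` holds the mixed-model coefficients on
phonological SSE (in this run: WF −0.23, RC −0.18, SR +0.23, SR×RC
−0.088, all |t| > 1.96 — frequent and consistent words are read with
less error, high-SR models with more, and SR amplifies the consistency
effect), and `study["polarity"]["pooled_rho"]` the polarity–SR rank
correlation (−0.94: more semantically reliant models have less
binarised phonological output).

The same workflow is available from the shell:

```sh
triread generate-lexicon --scaled --n-words 200 --seed 1 --out lex.json
triread cohort --scaled --lexicon lex.json --seeds 7 --out-dir cohort/
triread analyze --scaled --records cohort/model_records.csv \
                --trials cohort/trial_table.csv --out-dir analysis/
triread train --scaled --lexicon lex.json --regimen op --out model.npz
triread lesion-sr --weights model.npz --lexicon lex.json
```

## Layout

| module | contents |
| --- | --- |
| `triread.lexicon` | synthetic lexicon generation, slot encodings, WF/ONS/RC/IMG, TSV/JSON IO |
| `triread.netcore` | topology, settling dynamics, loss, BPTT, checkpoints (numba fast path in `_engine`) |
| `triread.training` | task specs, regimens, frequency-weighted sampling, the two training phases |
| `triread.evaluation` | phonological/semantic SSE and accuracy, unit polarity |
| `triread.semantic_reliance` | pathway lesions and the SR score |
| `triread.experiments` | cohort orchestration, trial cleaning, regression and mixed-model analyses |
| `triread.study` | the end-to-end desk-scale study and the gradient oracle |
| `triread.cli` | `triread` command-line interface |

See `docs/methods.md` for the modelling assumptions, the generator's
scope, and numerical choices.
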