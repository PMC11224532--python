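# Methods

## The model

`triread` implements the triangle framework of reading as a discrete-time
recurrent network over three coding layers — orthography (O), phonology
(P) and semantics (S) — joined through hidden layers.  Print can reach
sound directly (O → hidden → P) or through meaning (O → … → S → hidden →
P), and meaning can be reached directly (O → hidden → S) or through sound
(the OPS route, O → … → P → hidden → S).  Each of P and S carries a small
recurrent cleanup ("attractor") layer trained to restore its own
patterns, and a 4-unit context layer reaches S through a 10-unit hidden
layer to disambiguate homophones.  At full scale the layers hold 364 O /
200 P / 2,446 S units with 500-unit orthographic and 300-unit oral hidden
layers and 50-unit attractors.

Units are logistic.  One trial presents an input pattern clamped on an
input layer for a clamp window, lets the network settle for T synchronous
timesteps (net input at t is the weighted sum of source activations at
t−1 plus bias), and injects error at the target layer over an error
window: the last 2 of 8 steps for the oral tasks, steps 3–8 for the
attractor tasks (target = the pattern presented during the 2-step clamp),
and the last 3 of 12 steps for reading.  Training is online
backpropagation through time with cross-entropy loss (activations clipped
at 1e−7 inside the logs; summed squared error is available as an
alternative criterion).  Gradients are exact through the unrolled trial —
including the cooperative flow by which, say, phonological error reaches
the print-to-meaning weights through the semantic loop; this
cross-pathway gradient is what lets a division of labour emerge.  The
BPTT implementation is validated against central finite differences on
random small recurrent networks (max relative error < 1e−4).

Layers with incoming connections rest at activation 0.5; input layers
(no incoming connections) rest at 0 unless clamped.  Biases of receiving
layers initialise at −1 so units rest near off; weights initialise
i.i.d. uniform in ±0.1.  Continuous-time (time-averaged) unit
integration, as used in some connectionist simulators, is not used: one
model timestep is one synchronous update.

## Curriculum

Phase 1 (oral language, default 2M trials; 50k at desk scale) interleaves
four tasks at 40/40/10/10: semantics→phonology (SP), phonology→semantics
(PS, with the word's context pattern clamped when it is a homophone), and
the two attractor tasks (PP, SS).  Phase 2 (reading, default 1M trials;
30k at desk scale) freezes every oral weight and trains only the
orthographic routes; each trial is print-to-sound (OP) or print-to-meaning
(OS) with regimen-specific probabilities — 75/25 (phonology-focused
instruction), 50/50 (balanced), 25/75 (meaning-focused).  Words are drawn
by token frequency, log-compressed by default (the compression used by
the original corpus sampling is not documented; the raw-frequency variant
is a config switch).  The context layer is clamped only on
semantics-target trials and is all-zero otherwise.

Learning rate is 0.05 at full scale.  At desk scale online updates at
0.05 oscillate (loss climbs after an initial descent and weights
saturate), so the scaled preset uses 0.02, which converges the oral phase
to ~98% SP and ~90% PS accuracy — the profile the full-scale model shows.

## Semantic reliance

A trained model's reliance on the direct meaning route is measured by
lesioning: every matrix on one orthographic route is set to zero (the
attractors and context path stay intact), the whole lexicon is read for
the standard 12-step trial, and the mean semantic SSE at the evaluation
window is recorded.  With the OPS route cut this yields SSE_via_OS; with
the OS route cut, SSE_via_OPS.  Reciprocals act as contributions and

    SR = (1/SSE_via_OS) / (1/SSE_via_OS + 1/SSE_via_OPS).

SSEs are averaged over words before the reciprocal (model-level SR); a
per-word variant is available and tracks the model-level score closely.
SSEs are floored at 1e−6 before inversion.  Note that even with the OPS
route cut, print still reaches phonology indirectly through semantics
(and vice versa); the lesion severs the direct projection, not every
causal path — which is the point of the division-of-labour logic.

Evaluation conventions: phonological output is decoded per slot to the
nearest inventory phoneme (or the all-zero empty-slot pattern) by
Euclidean distance on the window-mean activation, ties to the lowest
inventory index; a word is read correctly when all slots match.  Semantic
accuracy is a nearest-neighbour search over the training set's semantic
vectors, with the word's context clamped so a homophone is correct only
for its context-specific meaning.  Unit polarity y = x·log₂x +
(1−x)·log₂(1−x) + 1 is computed on the window-mean phonological pattern
and averaged over units, then words.

## The synthetic lexicon

The generator emulates the statistical structure of a monosyllabic
English vocabulary without reproducing any real corpus:

* **Slot encodings.**  14 letter slots × 26 units, first vowel letter
  anchored on slot 5 (onsets right-align before it, an adjacent second
  vowel letter takes slot 6, remaining letters fill from slot 7); 8
  phoneme slots × 25 binary phonological features (3 onset slots
  right-aligned against the vowel slot, 4 coda slots).  A built-in
  39-phoneme inventory supplies the feature vectors.  The desk-scale
  template is 10 letter slots and 5 phoneme slots (2 onset / 2 coda),
  which the generator's onset/rime material fits exactly.
* **Quasi-regularity.**  Words are built as onset + rime from a fixed
  grapheme-to-phoneme table; rime families share a rime spelling, and a
  configurable fraction of families (default 30%) contains a minority of
  deviant members whose vowel takes an alternative pronunciation — the
  *pint* among the *mint/hint* friends.
* **Semantics.**  Sparse binary vectors, independent of orthography
  (arbitrary print-to-meaning mapping): 5–12 of 150 features at desk
  scale (~3–8% density, emulating sparse lexical-semantic feature norms);
  uniqueness across entries enforced.  The imageability proxy IMG is the
  number of active features min–max scaled — richer semantics stand in
  for higher imageability; an import hook accepts external norms instead.
* **Homophones.**  8 families of 2 by default: same spelling and
  pronunciation, different semantic vectors, distinct nonzero codes on
  the 4-unit context layer (family size is capped at 4 by that layer).
* **Frequencies.**  Zipfian over a random rank assignment (exponent 1).
* **Predictors.**  WF = log-compressed frequency scaled to [0,1]; ONS =
  same-length one-substitution neighbours; RC = token-frequency-weighted
  proportion of rime-spelling mates (self included) sharing the rime
  pronunciation — so a unique rime scores 1.0; high/low IMG ×
  consistent/inconsistent factorial cells are tagged at generation
  (median IMG split; consistency at the rime-family level).

What the generator does **not** emulate: real English grapheme-phoneme
statistics beyond the one-table mapping, morphology, age-of-acquisition
structure, correlated semantics (synonym clusters), or norm-based
imageability.  Tests passing on this lexicon show that the machinery
reproduces the qualitative phenomena under controlled quasi-regular
structure, not that it reproduces any particular English dataset.

## The desk-scale study

`triread.study.run_scaled_study` trains the standard cohort: a 200-word
lexicon, the scaled network (O 260 / P 125 / S 150; hidden 100/100/60/60;
10-unit attractors), 50k oral + 30k reading trials, learning rate 0.02,
three regimens × 7 initial-weight seeds (21 models, ~10–14 min on one
CPU core; the network core is float32 with numba-compiled loops).

Cohort design: model versions differ **only in their initial weights**.
All models share one word-sampling stream and one task-coin stream
(common random numbers); within a seed the three regimens see identical
trial sequences and differ only in the exposure threshold applied to the
same coin, and the oral phase is shared across regimens within a seed.
This isolates the instruction manipulation from sampling noise, which at
desk scale would otherwise swamp the regimen effect on SR.

Analyses: reading-aloud trials (phonological SSE as the latency proxy)
are cleaned by dropping misread words, rows with missing predictors and
SSEs more than 3 SD above the mean of the pre-cleaning correct trials
(discarded fraction is logged; a warning fires above 20%).  SR is
regressed on dummy-coded regimen (R², adjusted R², pairwise contrasts);
the factorial and continuous-predictor analyses are linear mixed models
with random intercepts for word and for model version (fitted as
variance components; random slopes are not included), all variables
z-scored, significance at |t| > 1.96.  On non-convergence the engine
falls back to OLS with standard errors clustered by model version and
flags the result.  Regimen ordering of SR is tested by one-sided
Mann-Whitney on the per-model scores.

Two details of the consistency check: the factorial mixed model uses the
family-level consistency factor (balanced cells), while the per-model
direction check ("exception words are read with more error in every
model") compares deviant family members — the *pint*-type items that the
behavioural consistency effect is about — against consistent-family
words on cleaned trials.

## Numerical and degenerate-input choices

* Activation clipping 1e−7 inside cross-entropy; SSE floor 1e−6 before
  reciprocals; nearest-phoneme ties to the lowest inventory index,
  nearest-word ties to the lowest word id.
* Non-finite activations raise an error naming layer and timestep;
  all-zero frequency tables, degenerate (zero-variance) predictors,
  empty trial tables after cleaning, unknown lesion pathways, and
  reading-before-oral all raise typed errors.
* Checkpoints store weights, biases, topology, trainable masks and
  phase/trial-count metadata at full precision; loading against a
  mismatched topology is an error.

## Known limitations

* Desk-scale SR values (~0.25–0.45) sit higher than full-scale ones
  (~0.02–0.23): with 200 words the direct print-to-meaning mapping is
  relatively easier than with a 6,229-word vocabulary, so the direct
  route contributes more.  The regimen *ordering* and every effect
  direction are the replicated phenomena; absolute SR levels are
  scale-dependent.
* The mixed models use random intercepts only; with 21 models the
  factorial three-way interaction is underpowered and its significance
  is not asserted anywhere.
* One synchronous update per timestep (no time-averaged integration);
  settling dynamics are therefore slightly more discrete than in
  continuous-time implementations.
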