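# Methods

`adspeech` implements a domain-knowledge pipeline for detecting Alzheimer's
disease (AD) from picture-description speech: participants describe the
Cookie Theft picture, their speech is transcribed in CHAT format, and a
battery of 509 engineered features over the transcript and the audio feeds
conventional classifiers (AD vs non-AD) and regressors (MMSE score,
0–30).  This note documents the models, the fixed numerical choices, and
what the bundled synthetic cohorts do and do not demonstrate.

## The feature battery

The battery is frozen in a registry (`adspeech/data/registry.csv`,
cross-checked against the code at test time): 297 lexico-syntactic, 187
acoustic/temporal and 25 picture-content semantic features, split into 24
families with fixed sizes.  Where the feature-engineering literature fixes
a family's *size* but not the identity of its members, the registry makes
an explicit choice and keeps it stable:

* **Lexical richness (6)** — type-token ratio `V/N`, moving-average TTR
  (window 10), Brunet's index `W = N^(V^-0.165)` (lower = richer),
  Honoré's statistic `R = 100·ln N / (1 − V1/V)` with `V1` the hapax
  count, Guiraud's `V/√N`, and Herdan's `C = ln V / ln N`.  When every
  type is a hapax (`V1 = V`) the Honoré denominator is replaced by
  `ε = 10⁻³`, a documented cap that preserves ordering.
* **Local coherence (15)** — mean/min/max/median/SD of {cosine similarity
  at lag 1, cosine distance at lag 1, cosine distance at lag 2} between
  consecutive utterance embeddings.  **Utterance distances (5)** —
  fraction of utterance pairs with similarity below 0.5, 0.3 and 0
  (read literally: negative cosine), plus average and minimum pairwise
  cosine distance.
* **Speech graph (13)** — a directed multigraph with one node per word
  type and one edge per within-utterance bigram: node/edge counts,
  repeated-edge count, self-loops (L1), 2-cycles (L2), directed 3-cycles
  (L3, on the simple digraph), largest weakly/strongly connected
  component, density, diameter and average shortest path (undirected view
  of the largest component; 0 for single-node graphs), mean total degree
  and transitivity.
* **Lexical norms (12)** — {imageability, age of acquisition,
  familiarity} × {all tokens, nouns, verbs, unique types};
  **sentiment norms (9)** — {valence, arousal, dominance} × {all, nouns,
  verbs}.  Norm means are taken over the words found in the lexicon; a
  norm with no covered word is missing.
* **Syntactic complexity (36)** — utterance-length and parse-tree
  depth/size statistics plus clause/T-unit measures in the style of
  syntactic-complexity analyzers (clauses per T-unit, dependent clauses
  per clause, verb phrases and complex nominals per utterance, etc.).
* **MFCC (168)** — 42 coefficients = 14 static (including the 0th/energy
  coefficient) + Δ + ΔΔ, each summarised by mean, population variance,
  skewness and *excess* kurtosis across frames.  Skewness/kurtosis of a
  constant per-frame series are 0 by convention.
* **Picture-content (25)** — a unit is "mentioned" when any synonym's
  lemma occurs in the participant's lemmatized tokens; the word-frequency
  family holds the distinct-mentioned:total ratios (overall, objects,
  actions) and the relative frequency of 7 designated content lemmas.
  Global coherence measures cosine distances between utterance embeddings
  and content-unit anchor embeddings under two embedding inventories
  (overall mean/min/max + per-category means, plus a nearest-anchor mean).

**Missing values.** A feature that is undefined on an input (pairwise
statistics with one utterance, F0 with no voiced frame, rates without
audio) is imputed to 0 in the emitted vector; a per-feature `defined` mask
is returned alongside so analyses can distinguish imputation from true
zeros.  Selection and modeling operate on the imputed matrix.

## Front ends

* **CHAT parsing** covers the main-tier subset used by picture-description
  corpora: `@` headers (`@ID` metadata), `*PAR:`/`*INV:` tiers, retracing
  `[/]`/`[//]` (retraced material excised, tallied separately), events
  `&=...`, fillers `&-um`/`&-uh` (counted, kept out of the lexical token
  stream), pauses `(.)`/`(..)`/`(...)`, and `xxx`.  Other bracket codes
  are stripped with their scoped material kept.  Only participant tiers
  enter the battery.
* **Tagging and parsing are pluggable.**  Any object implementing the
  `Tagger`/`Parser` protocols can be injected; the defaults are a
  deterministic closed-class-lexicon + suffix-rule tagger (Penn-Treebank
  fine tags, universal coarse tags, lemmas) and a regular NP/VP/PP chunk
  grammar.  These are English-only approximations that are exact on the
  controlled vocabulary of the synthetic cohorts; for naturalistic text a
  model-based tagger should be injected.  Test fixtures use gold tags and
  bracketed trees, so no correctness claim rests on the heuristics.
* **Embeddings** default to deterministic pseudo-random unit vectors keyed
  by `md5(word, seed)` — reproducible everywhere with no downloads; a
  word2vec-text-format loader is provided for real vectors.  Utterance
  vectors are means over non-stopword tokens (falling back to all tokens),
  so utterance similarity reflects content overlap rather than shared
  function words.  Two inventories (different seeds) mirror the use of two
  embedding spaces for the content-distance features.
* **Audio** front end: 25 ms Hann windows, 10 ms hop.  Clips are
  peak-normalized first, making all acoustic features invariant to global
  amplitude scaling (the data this pipeline targets are volume-normalized
  upstream).  Mel filterbank: 26 triangular filters, 0–Nyquist.  F0 by
  normalized autocorrelation peak in 75–500 Hz with parabolic lag
  interpolation, voiced when the peak exceeds 0.5 and frame energy is
  above the silence floor.  Silence segmentation declares a pause where
  frame log-energy falls 20 dB below the clip median for ≥ 150 ms; pauses
  ≥ 1.0 s are long, [0.15, 1.0) s short.  These thresholds are package
  constants, configurable via `FrameSpec` and module-level settings.
  Fillers are counted from the transcript, which is authoritative.

## Models and evaluation

Feature selection is a univariate top-k filter: one-way ANOVA F between
the class-conditional distributions for classification, and
`F = r²/(1−r²)·(n−2)` from the Pearson correlation with MMSE for
regression.  Ties break by ascending feature index; constant features
score 0; a feature with zero within-class variance but distinct class
means ranks above every finite score.  Selection, standardization and the
predictor are refit inside every CV training fold — nothing fitted ever
sees a held-out subject.

Tuned configurations (defaults): SVM with RBF kernel (γ = 0.001, C = 100,
k = 10), neural network (two hidden layers of 10 ReLU units, Adam,
learning rate 10⁻³, 200 epochs, full-batch, k = 10), random forest (200
trees, min-split 2, min-leaf 2, bootstrap, k = 50), Gaussian naive Bayes
(balanced priors, variance smoothing 10⁻¹⁰, k = 80); linear regression
(k = 15/20) and ridge (k = 25, α = 10; also k = 35, α = 12 and the
full-battery k = 509, α = 12).  SVM/NN/regressors take z-scored features
(training statistics); RF/NB take raw features.  Regression predictions
are clipped to [0, 30].  Only RF and NN consume the random seed; fixing
it fixes their predictions exactly.

Evaluation follows the study protocol: leave-one-subject-out CV and
stratified 10-fold CV at transcript level, metrics averaged across three
seeds (defaults 1, 2, 3); held-out-test predictions by majority vote of
three seeded models (odd voter count enforced).  Metrics: accuracy,
precision, recall, specificity, F1 (positive class = AD) and
rank-statistic AUROC (decision scores when the model provides them).
Model comparison uses the tie-corrected Kruskal–Wallis H over per-run
accuracies.

Feature differentiation uses Welch's unequal-variance t-test per feature
(the robust default for "independent t-tests"), flagged at α and at the
Bonferroni level α/m with m the number of features actually tested
(0.05/509 ≈ 9.8×10⁻⁵; the threshold used is recorded in the report).
Features with zero variance in both groups get t = 0, p = 1.  The MMSE
weight report averages each feature's ridge coefficient across LOSO folds
(0 when unselected) and pairs it with its Pearson correlation and a
Bonferroni significance flag; the five most positive and most negative
mean weights are reported.

## The synthetic cohort generator

The clinical picture-description corpora this pipeline targets are
access-restricted, so the
generator builds cohorts on which every pipeline stage is exercised with
known ground truth.  It emulates the matched design: balanced groups
(default 54 + 54), identical (age-band, sex) pairs across groups in
5-year bands from 50 to 80 following the train-set pattern, MMSE in
[0, 30] linked to the planted effects.

Transcripts are drawn from a template grammar over the content-unit
lexicon.  Per-subject generation parameters (mention probability per unit
category, pronoun substitution, long-word rate, pseudo-word insertion,
adverb insertion, filler/pause rates, utterance repetition) are drawn
around group means and those means are **calibrated** so the extracted
feature means land on the reference group differences: distinct
content-unit ratio 0.27 (AD) vs 0.45 (non-AD), object 0.28/0.47, action
0.15/0.30, pronoun:(pronoun+noun) 0.35/0.23, average word length
3.57/3.78 letters, non-dictionary proportion 0.11/0.08, adverb proportion
0.06/0.04.  These are the planted means the acceptance checks hold to
±0.05.  Utterance-repetition and mention effects also push the coherence
and content-distance features in the right *direction* (AD lower pairwise
utterance distance, larger distance to content anchors), but their
absolute level is a property of the hash-embedding geometry rather than a
generator target, so only the direction is asserted.  Pseudo-words
average ~3.8 letters — deliberately length-neutral, so the invalid-word
effect does not confound the planted word-length effect.

MMSE is a weighted linear function of the realized latents (content
mentions and word length weighted 2, pronoun/invalid/adverb rates
weighted 1, signs as planted), scaled to span ≈14–29 across groups, plus
Gaussian noise (SD 2), rounded and clipped to [0, 30].  Because several
features carry the same latent (e.g. three pronoun proportions), ridge
splits weight among collinear carriers; sign recovery is therefore
assessed on the *group-summed* weight per latent.

Audio is schematic: each word is a short tone (150–240 Hz, 0.18–0.28 s)
with 5 ms ramps; transcript pause marks insert matching silences (0.35 s
short, 1.25 s long) and utterances are separated by 0.35 s gaps.  This
exercises the MFCC/ZCR/F0/pause code paths with checkable ground truth;
it does not mimic speech spectra, so nothing about real-audio acoustic
discriminability follows from synthetic results.  One global seed drives
everything through per-subject counter-derived substreams; identical
configurations produce byte-identical cohorts.

**What passing tests show** — that the implementation computes the
declared quantities correctly (brute-force oracle equivalence), that the
evaluation protocol is leak-free, and that planted, calibrated effects of
the reported magnitude are recoverable end-to-end at the study's sample
size.  **What they do not show** — classifier accuracy or regression
error on real speech; the synthetic cohorts are much easier than real
data (controlled vocabulary, exact tagging, planted effects in many
correlated features), which is why synthetic CV accuracies (~0.9) exceed
what should be expected on clinical recordings.

## Problem sizes and runtime choices

Default test and acceptance runs use three replicate cohorts of 108
subjects with full audio (~50 s per subject at 8 kHz), a 20-replicate
numeric power simulation at the study dimensions (13 features shifted by
1.5 pooled SD, n = 54/group, m = 509), and 100-instance oracle batches
for the equivalence checks.  These sizes keep the whole suite and the
acceptance script in the low minutes on a single CPU while leaving the
statistical assertions well-powered.

## Known limitations

* The rule tagger/chunker and the vowel-group syllable counter are
  approximations; on naturalistic transcripts a model-based tagger and
  parser should be injected (the interfaces accept them).
* The packaged norm table is synthetic (real norm inventories are
  licensed); norm features on real data require the user to supply a norm
  CSV.
* MFCC composition (14 + Δ + ΔΔ), pause thresholds and the identities of
  the under-specified feature families are registry decisions; other
  implementations of the same battery may differ in those members while
  matching the family counts.
* BERT-style transfer learning and attention analysis are out of scope;
  so is t-SNE visualization.
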