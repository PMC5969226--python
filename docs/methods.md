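# Methods

This note documents the models, the generative conventions of the
synthetic experiment, the numerical choices, and what the simulations
do and do not establish.

## The MDL segmentation model

A corpus of word types with token counts is encoded in two parts. The
lexicon part spells out each distinct morph letter by letter plus one
end-of-morph marker, under a character model estimated by maximum
likelihood over the lexicon entries themselves; with character counts
C(c) and total T this cost is `T·log₂T − Σ_c C(c)·log₂C(c)` bits. The
corpus part rewrites every word token as pointers to morphs; with morph
token counts n(m) and total N it costs `N·log₂N − Σ_m n(m)·log₂n(m)`
bits (N times the entropy of the morph token distribution). Both parts
admit O(1) incremental updates, which is what makes the greedy search
cheap.

**Search.** Every word type starts unsegmented. An epoch visits word
types in a seeded shuffled order; each word's morphs are removed and
the word is re-segmented by recursive binary splitting: keeping the
string whole is compared against every split point, a split must
strictly lower the total cost, and accepted halves are refined
recursively. Training stops when an epoch improves the cost by less
than `epsilon_bits` (default 0.1) or after `max_epochs` (default 20).
Ties prefer no split, then the earliest split point — determinism over
elegance.

**Count dampening.** The search runs, by default, on type-dampened
counts (each word type weighted 1; `count_dampening` also accepts
`"log"` and `"tokens"`). The reason is structural: under raw token
weights, the unsegmented state is a strict local optimum on small and
medium corpora — the first split of any word buys one extra pointer per
token (≈ log₂ of the lexicon size, bits) but saves only one spelled-out
entry, so no single-word move is ever accepted, even when the fully
split configuration is globally cheaper. Type weighting removes the
pointer-mass barrier; it is also the weighting under which baseline MDL
segmenters have typically been run on word lists. After the search
phase, further epochs refine the segmentation under the true token
counts, and the final lexicon counts — hence all surprisals and the
reported total cost — are token-weighted.

**Decoding.** `segment` minimizes the summed substring costs over all
2^(L−1) segmentations by dynamic programming. A lexicon morph costs its
pointer surprisal −log₂(n(m)/N); any other substring costs its
character-model spell-out (fallback available during decoding only,
never during training). Ties prefer fewer morphs, then a longer first
morph. Surprisal is therefore defined for every string over the model's
alphabet; characters outside it are an error, not a guess.

**Oracle.** `exhaustive_optimum` enumerates the joint segmentation
space (product over words of per-word segmentations) and is the
ground-truth check for the greedy search; it refuses joint spaces above
10⁶ configurations. The greedy cost is required (and tested) to come
within 5% of the optimum on corpora small enough to enumerate; equality
is not guaranteed — greedy search with sequential acceptance is a local
method.

## Predictors

- **Length** is the raw letter count; under a uniform letter model the
  word surprisal is proportional to it and the constant is absorbed by
  standardization downstream.
- **Open bigrams** are all ordered letter pairs at any distance
  ("take" → TA, TK, TE, AK, AE, KE). The corpus bigram table is
  token-weighted by default (type weighting is a flag; which weighting
  a given frequency norm uses is rarely stated, so both exist). A
  string's value is −log₂ of the mean per-million frequency of its
  bigrams, floored at ε = 0.01 per million; the floor (a max, not an
  addition) keeps seen-bigram values exact while bounding all-unseen
  strings.
- **Image complexity (gif-index)** renders the string with an
  in-package 5×7 dot-matrix font into one cell per letter, centered on
  a fixed canvas of 16 cells (the maximum stimulus length), encodes the
  image as GIF, and reports compressed bytes ÷ raw pixel-buffer bytes.
  A fixed canvas rather than a string-width image is deliberate:
  stimuli share one screen, and with per-string widths the constant GIF
  format overhead divided by a growing raw size makes the ratio fall
  with length, inverting the complexity–length relation the measure is
  supposed to capture (measured Spearman ρ ≈ −0.97 per-string vs
  ≈ +0.98 on the fixed canvas). The repetition-compressibility property
  (a repeated letter compresses better than distinct letters) holds in
  expectation, not per draw, because individual comparisons confound
  repetition with per-glyph ink mass. No system font is used:
  deterministic rendering across machines beats typographic fidelity
  here, and only ordinal behavior of the index is ever asserted.
- **Surface and lemma surprisal** are −log₂ probabilities from the
  corpus table and the root-family table; real words absent from the
  corpus raise rather than smooth — a missing stimulus word is a data
  error. **TPL** (surface ÷ lemma frequency) stays on the probability
  scale; a log variant exists but is off by default.
- Pseudowords carry only the four predictors that need no attested
  frequency: image complexity, length, bigram surprisal, MDL surprisal.

## The synthetic experiment

**Corpus generator.** Word tokens are root + one suffix per slot; root
identities are Zipf-distributed (exponent 1.0 by default), suffixes
drawn independently per token with the empty suffix allowed. The
default study grammar uses 300 consonant-vowel alternating roots of
3–12 letters and two suffix slots (case-like and clitic-like), giving a
lexicon dense across lengths 4–16, from which 360-item stimulus sets
with mean length 10.3 (SD 2.8) are sampled by per-length quotas under a
discretized normal. Pseudowords come from an order-3, additive-0.1
character n-gram model (both configuration values, not claims), length-
matched by rejection sampling with a 10,000-retry cap.

**Response generator.** For each component,
`amplitude(i,s,c) = gain_sc · (baseline_c + Σ_j β_cj·x_ij + ε_isc) + offset_sc`
with participant gain ~ lognormal(0, 0.2) and offset ~ normal(0, 1 nAm)
— conventions chosen to make the within-participant z-scoring stage do
real work, not measured quantities (per-participant amplitude variance
is not something item-level reports publish). Trial noise can be given
directly or calibrated analytically: for standardized predictors with
correlation matrix R and coefficients β, the residual SD that yields a
model R² of ρ² is `sqrt(βᵀRβ·(1−ρ²)/ρ²)`, multiplied by √n_participants
when ρ² refers (as published R² values do) to the item-level fit after
cross-participant averaging. Default windows: 80–120, 140–200, 300–700,
300–700 ms within a −200..800 ms epoch at 1000 samples/s. Time-resolved
traces are Gaussian bumps at each component's peak latency scaled so
the window mean equals the window amplitude exactly; the default bump
SD is 40 ms, at which less than 1% of the bump's area falls outside the
widest default window (at 60 ms that figure would be ~4.8%, which is
why 40 is the default).

**Behavior.** RT = baseline (852 ms) + 95 ms per unit of the
standardized linear predictor + participant offset + trial noise,
truncated at 1 ms; accuracy is Bernoulli with per-participant rates
drawn around 0.92 (SD 0.04) and is predictor-independent by default (a
logistic link exists but is off — the default analysis models none).
Trials are valid iff correct and 350 ≤ RT ≤ 1500 ms; participants with
fewer than 290-of-360 valid word trials (the ratio is scaled when the
word set is smaller) are excluded.

**Default effect sizes.** The package ships a default configuration
(`defaults.py`, `data/components.yaml`): pairwise predictor
correlations for the word stimuli, standardized betas and total R² per
component and for RT, and the behavioral summary levels. A useful
consequence, exploited by the consistency simulations: for y generated
from standardized X with coefficients β and noise calibrated to R², the
implied simple correlation of predictor j with y is `(Rβ)_j /
sqrt(βᵀRβ/R²)`. With the shipped defaults this gives 0.62 for MDL
surprisal vs RT, 0.35 for surface surprisal vs the left-temporal
window, and 0.30 for length vs the occipital window — the values the
simulations are expected to reproduce to ±0.05.

## Analysis stage

Window averages are start-inclusive, end-exclusive means. Z-scoring is
per participant × component over items with the n−1 SD; it is exactly
invariant under positive-gain affine corruption, which is its purpose;
zero-variance columns are an error naming the offender. Item averages
ignore missing trials (never zero-fill) and record per-cell n. Simple
correlations report Pearson r with F = r²(n−2)/(1−r²) on (1, n−2) df;
stars reproduce the two conventional levels (p < .05, p < .001) with no
multiple-testing correction, matching how such tables are reported.
Stepwise selection is forward-only with a partial-F entry test at
α = .05 (entry statistic and direction are a documented choice — such
procedures are rarely fully specified in print); predictors and
response are z-scored internally so coefficients are standardized; ties
break by column order; a collinear selected set (condition number
> 10⁸) is an error. Tertile binning takes the bottom, top, and
median-centered `bin_size` items (default 60) with ties broken by item
order. Predictors are standardized after cross-participant averaging,
not before.

## Problem sizes

The test suite and the reproduction script run on deliberately modest
sizes: planted-morphology corpora of 90 types, study corpora of
50k–200k tokens and a few thousand types, 360-item predictor matrices,
100 replicates for consistency/recovery means and 200 for the stepwise
null — sizes at which every check completes in seconds while Monte-
Carlo error stays well inside the asserted tolerances.

## What the simulations show — and what they do not

All quantitative checks are internal-consistency and recovery results:
they demonstrate that the generator, the calibration algebra, and the
analysis stage are mutually coherent (planted coefficients come back
unbiased; implied correlations re-emerge; the stepwise null holds its
error rate). They do not validate the default effect sizes against new
human data, and the synthetic corpus lacks real-language properties —
no vowel harmony or stem alternation, no homography, no semantic
structure, suffix slots independent of the root. The MDL model is the
baseline variant: no category structure, no semi-supervision, no
prior-weighted likelihood annealing; numeric parity with any particular
historical segmentation tool is not claimed. Sensor-level MEG
processing, dipole modeling, and source localization are entirely out
of scope — "occipital" and "temporal" name simulated components, not
cortical claims.
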