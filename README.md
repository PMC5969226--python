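# morphsurprisal

Information-theoretic modeling of visual word recognition: an MDL morph
segmentation model, seven item-level surprisal predictors, a synthetic
lexical-decision MEG experiment, and the item-level regression analysis
that links predictors to evoked-response amplitudes and reaction times.

## Who this is for

Researchers in computational psycholinguistics and neurolinguistics who
want a fully synthetic, seeded test bed for item-level "predictor →
brain response / RT" analyses: to develop analysis code against data
with known ground truth, to check what effect sizes survive
within-participant normalization and trial filtering, or to study how a
minimum-description-length model of morphology behaves on corpora with
planted structure.

## The model

**Surprisal.** Every predictor is (or is monotone in) a self-information
value *I*(ω) = −log₂ *P*(ω), in bits. Predictors target different levels
of representation:

| predictor | level | definition |
|---|---|---|
| image complexity | visual | GIF(LZW)-compressed / raw byte size of the rendered string |
| length *N* | visual | −log₂ *P*(letter)^*N* ∝ *N* under a uniform letter model |
| open-bigram surprisal | orthographic | −log₂ mean per-million frequency of all ordered letter pairs |
| MDL word surprisal | morphological | summed pointer costs of the word's morphs (below) |
| lemma surprisal | morphological | −log₂ probability of the root family |
| TPL | morphological | surface frequency ÷ lemma frequency (a conditional probability) |
| surface surprisal | lexical | −log₂ probability of the exact word form |

**MDL segmentation.** A morph lexicon *M* and a pointer message *X* are
chosen to minimize the two-part code length

```
L(M, X) = Σ_morphs Σ_chars −log₂ p(char)        (spell out the lexicon)
        + Σ_m −n(m) · log₂( n(m) / N_tok )      (rewrite the corpus as pointers)
```

Training greedily re-segments word types by recursive binary splitting
until an epoch no longer lowers the cost; decoding of arbitrary strings
is exact Viterbi with a character-model fallback for unseen substrings,
so pseudowords receive finite surprisals that measure word-likeness.
A word's surprisal is the sum of its morphs' surprisals.

**The simulated experiment.** Four evoked components (occipital
80–120 ms, occipito-temporal 140–200 ms, left/right temporal
300–700 ms) have window amplitudes linear in standardized predictors
with per-participant lognormal gain, normal offset, and Gaussian trial
noise; reaction times follow the same linear form in milliseconds.
Trials are kept if correct and 350 ≤ RT ≤ 1500 ms; participants need
290-of-360(-scaled) valid word trials. The analysis z-scores window
amplitudes within participant, averages across participants per item,
and runs simple correlations (F on (1, n−2) df) plus forward stepwise
regression with a partial-F entry test at α = .05.

## Worked example

```python
from morphsurprisal import mdl
from morphsurprisal.pipeline import build_study_corpus

freq, gold = build_study_corpus(seed=1, n_tokens=50_000, n_roots=120)
model = mdl.train(freq, seed=0)
for word in ["obikkin", "batibatisula"]:
    seg = mdl.segment(model, word)
    print(word, "->", " + ".join(seg.morphs), f"{seg.word_surprisal_bits:.2f} bits")
```

prints

```
obikkin -> obik + kin 8.58 bits
batibatisula -> batibatisula 53.08 bits
```

`obikkin` is an attested root+clitic form: both parts are frequent
morphs, so two cheap pointers suffice (8.6 bits). `batibatisula` was
never seen; no pointer exists, and the character-model fallback prices
it at 53 bits — high surprisal marks a string with little in common
with the lexicon. The `examples/` directory has one narrative script
per capability (corpus + stimuli, segmentation, predictors, experiment
simulation, item-level analysis, internal consistency), each printing
the numbers it computes.

A thin CLI mirrors the pipeline stages:

```bash
morphsurprisal simulate-corpus --out-dir corpus --seed 3
morphsurprisal train --wordlist corpus/wordlist.tsv --out model.json --seed 1
morphsurprisal score --model model.json --items stimuli.tsv --out scores.tsv
morphsurprisal predictors --items stimuli.tsv --model model.json \
    --wordlist corpus/wordlist.tsv --gold corpus/gold.tsv --out predictors.tsv
morphsurprisal simulate-responses --predictors predictors.tsv --seed 5 --out-dir resp
morphsurprisal analyze --predictors predictors.tsv \
    --amplitudes resp/amplitudes.tsv --trials resp/trials.tsv --out-dir analysis
```

## Layout

- `src/morphsurprisal/corpus_stimuli.py` — synthetic corpora, n-gram pseudowords, stimulus sampling
- `src/morphsurprisal/mdl.py` — two-part code, greedy training, Viterbi decoding, brute-force oracle
- `src/morphsurprisal/predictors.py` — the seven predictors and the predictor matrix
- `src/morphsurprisal/synth_responses.py` — evoked amplitudes, RT/accuracy, validity filters
- `src/morphsurprisal/item_analysis.py` — z-scoring, item averaging, correlations, stepwise regression
- `src/morphsurprisal/simulations.py` — seeded internal-consistency and recovery simulations
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices, limitations
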