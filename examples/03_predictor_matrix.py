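"""Compute the seven item-level predictors for a small stimulus set.

Words receive all seven predictors; pseudowords only the four that do
not require an attested frequency (image complexity, length, open-bigram
surprisal, MDL surprisal) — the rest are reported NA.
"""

from morphsurprisal import mdl
from morphsurprisal.corpus_stimuli import (
    StimulusItem,
    generate_pseudowords,
    lemma_table,
    sample_stimulus_set,
    train_ngram,
)
from morphsurprisal.pipeline import build_study_corpus
from morphsurprisal.predictors import build_bigram_table, build_predictor_matrix

freq, gold = build_study_corpus(seed=1, n_tokens=50_000, n_roots=120)
model = mdl.train(freq, seed=0)

words = sample_stimulus_set(freq, 6, (4, 16), seed=4)
ngram = train_ngram(freq, order=3, smoothing=0.1)
pseudo = generate_pseudowords(ngram, [8, 10], 2, seed=5,
                              exclude=set(freq.counts))

matrix = build_predictor_matrix(
    words + pseudo,
    model=model,
    freq=freq,
    lemma_map={a.word: a.lemma for a in gold},
    lemma_freqs=lemma_table(gold, freq),
    bigram_table=build_bigram_table(freq),
)
print(matrix.values.round(3).to_string())
print("\ncolumns fully available:", matrix.available_columns())
# Surprisal columns are in bits; tpl is the conditional probability of
# the word form given its root family (1 means the root occurs in no
# other form); image_complexity is the GIF-compressed to raw byte ratio
# of the rendered string.
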