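"""Train the MDL morph segmenter and score words and pseudowords.

The model minimizes a two-part code: bits to spell out a lexicon of
morphs plus bits to rewrite the corpus as pointers into it. A word's
surprisal is the summed pointer cost (-log2 n(m)/N) of its morphs;
strings containing unseen substrings fall back to a character-level
spell-out cost, so pseudowords always receive a finite score.
"""

from morphsurprisal import mdl
from morphsurprisal.pipeline import build_study_corpus

freq, gold = build_study_corpus(seed=1, n_tokens=50_000, n_roots=120)
model = mdl.train(freq, seed=0)

print(f"lexicon: {len(model.lexicon.morph_counts)} morphs "
      f"(from {len(freq)} word types)")
print(f"total code length: {model.total_cost_bits:,.0f} bits "
      f"(corpus {mdl.corpus_cost(model):,.0f} + "
      f"lexicon {mdl.lexicon_cost(model.lexicon):,.0f})")

precision, recall, f1 = mdl.evaluate_boundaries(model, gold)
print(f"gold boundary recovery: P={precision:.2f} R={recall:.2f} F1={f1:.2f}")

print("\nsegmentations and surprisals (bits):")
for word in list(freq.counts)[:4] + ["batibatisula"]:
    seg = mdl.segment(model, word)
    tag = "word" if word in freq.counts else "novel string"
    print(f"  {word:14s} -> {' + '.join(seg.morphs):24s} "
          f"{seg.word_surprisal_bits:7.2f}  ({tag})")
# Frequent words decompose into high-count morphs and get low surprisal;
# the novel string is priced partly through the character model, which
# is what makes the measure a word-likeness score for pseudowords.
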