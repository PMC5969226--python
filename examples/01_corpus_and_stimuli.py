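"""Build a synthetic morphological corpus and sample a stimulus set.

The generator concatenates Zipf-distributed roots with per-slot suffixes
(empty suffix allowed), so every word type carries a gold segmentation
and lemma. A 360-item stimulus set is then sampled to match the length
statistics of a lexical-decision experiment, and length-matched
pseudowords are drawn from a character trigram model of the corpus.
"""

import numpy as np

from morphsurprisal.corpus_stimuli import (
    generate_pseudowords,
    sample_stimulus_set,
    train_ngram,
)
from morphsurprisal.pipeline import build_study_corpus

freq, gold = build_study_corpus(seed=1, n_tokens=200_000)
print(f"corpus: {len(freq)} word types, {freq.total_tokens} tokens")
print(f"example gold entries: "
      f"{[(a.word, a.segmentation) for a in gold[:3]]}")

items = sample_stimulus_set(freq, 360, (4, 16), seed=2,
                            target_mean=10.3, target_sd=2.8)
lengths = np.array([it.length_N for it in items])
print(f"stimulus set: n={len(items)}, "
      f"length mean {lengths.mean():.2f} (target 10.3), "
      f"SD {lengths.std(ddof=1):.2f} (target 2.8)")

ngram = train_ngram(freq, order=3, smoothing=0.1)
pseudo = generate_pseudowords(ngram, lengths.tolist(), 360, seed=3,
                              exclude=set(freq.counts))
overlap = {p.string for p in pseudo} & set(freq.counts)
print(f"pseudowords: n={len(pseudo)}, overlap with real words: {len(overlap)}")
print(f"examples: {[p.string for p in pseudo[:5]]}")
# The pseudowords obey the corpus' letter statistics (pronounceable,
# word-like) but none of them is an attested word, and their length
# multiset matches the word set exactly.
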