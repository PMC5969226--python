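"""Shared fixtures: small synthetic corpora with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from morphsurprisal.corpus_stimuli import FrequencyTable, GoldAnnotation
from morphsurprisal import mdl

_VOWELS = "aeiou"
_CONSONANTS = "bcdfghklmnprstv"


def make_roots(n: int, seed: int = 7, min_len: int = 3, max_len: int = 6) -> list[str]:
    """Deterministic pronounceable CV-alternating root strings."""
    rng = np.random.default_rng(seed)
    roots: list[str] = []
    seen: set[str] = set()
    while len(roots) < n:
        L = int(rng.integers(min_len, max_len + 1))
        w = "".join(
            (_CONSONANTS if k % 2 == 0 else _VOWELS)[
                rng.integers(len(_CONSONANTS if k % 2 == 0 else _VOWELS))
            ]
            for k in range(L)
        )
        if w not in seen:
            seen.add(w)
            roots.append(w)
    return roots


@pytest.fixture(scope="session")
def planted_corpus():
    """30 roots x {bare, -er, -s}, 10 tokens per type, with gold."""
    roots = make_roots(30)
    counts = {r + s: 10 for r in roots for s in ["", "er", "s"]}
    gold = [
        GoldAnnotation(r + s, (r, s) if s else (r,), r)
        for r in roots
        for s in ["", "er", "s"]
    ]
    return FrequencyTable(counts), gold


@pytest.fixture(scope="session")
def planted_model(planted_corpus):
    freq, _ = planted_corpus
    return mdl.train(freq, seed=0)
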