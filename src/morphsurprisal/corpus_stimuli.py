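"""Synthetic morphological corpora and lexical-decision stimulus sets.

This module generates the raw material that the rest of the pipeline
consumes: a Zipfian-frequency lexicon of root+suffix concatenations with
gold segmentations and lemma assignments, a character n-gram model for
pseudoword generation, and stimulus sampling that targets the length
statistics of a lexical-decision experiment (360 words, 4-16 letters).

The corpus stands in for a large natural-language text corpus: word types
are concatenations of a root (drawn from a Zipf distribution over root
identities) and one suffix per slot (drawn independently per token from
per-slot categorical weights, with the empty suffix allowed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MorphGrammar",
    "FrequencyTable",
    "GoldAnnotation",
    "NGramModel",
    "StimulusItem",
    "generate_corpus",
    "lemma_table",
    "train_ngram",
    "generate_pseudowords",
    "sample_stimulus_set",
    "derive_seed",
]

#: End-of-word symbol used by the n-gram model; never a stimulus letter.
END = "#"


class ConfigurationError(ValueError):
    """Raised when a generator is configured inconsistently."""


def derive_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage sub-seed from one global seed.

    Keeps independent pipeline stages decoupled: changing how many random
    draws one stage makes does not perturb another stage's stream.
    """
    h = np.uint32(seed & 0x7FFFFFFF)
    for ch in stage:
        h = np.uint32((int(h) * 31 + ord(ch)) & 0x7FFFFFFF)
    return int(h)


@dataclass(frozen=True)
class MorphGrammar:
    """Generative ground truth for morphologically complex words.

    Each word token is a root followed by one suffix drawn from each
    suffix slot in order (the empty string suffix yields a bare form).
    """

    roots: tuple[str, ...]
    suffix_slots: tuple[tuple[str, ...], ...]
    root_zipf_exponent: float = 1.0
    suffix_probabilities: tuple[tuple[float, ...], ...] | None = None
    alphabet: frozenset[str] = frozenset("abcdefghijklmnopqrstuvwxyz")

    def __post_init__(self) -> None:
        if not self.roots or not self.suffix_slots:
            raise ConfigurationError("grammar needs at least 1 root and 1 suffix slot")
        if self.root_zipf_exponent <= 0:
            raise ConfigurationError("root_zipf_exponent must be positive")
        for s in self.roots:
            if not s or not set(s) <= self.alphabet:
                raise ConfigurationError(f"root {s!r} not drawn from alphabet")
        for slot in self.suffix_slots:
            for s in slot:
                if not set(s) <= self.alphabet:
                    raise ConfigurationError(f"suffix {s!r} not drawn from alphabet")
        probs = self.slot_probabilities()
        for slot, p in zip(self.suffix_slots, probs):
            if len(p) != len(slot):
                raise ConfigurationError("suffix_probabilities shape mismatch")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigurationError("slot probabilities must sum to 1")

    def slot_probabilities(self) -> tuple[tuple[float, ...], ...]:
        if self.suffix_probabilities is not None:
            return self.suffix_probabilities
        return tuple(tuple(1.0 / len(slot) for _ in slot) for slot in self.suffix_slots)

    def root_probabilities(self) -> np.ndarray:
        """Zipf weights over roots in listed order: p(rank k) ∝ k^-a."""
        ranks = np.arange(1, len(self.roots) + 1, dtype=float)
        w = ranks ** (-self.root_zipf_exponent)
        return w / w.sum()


class FrequencyTable:
    """Word → token-count mapping with totals and per-million conversion.

    The shared corpus view used by every frequency-based predictor.
    """

    def __init__(self, counts: Mapping[str, int]):
        bad = [w for w, c in counts.items() if c < 1 or c != int(c)]
        if bad:
            raise ValueError(f"counts must be positive integers; offending: {bad[:5]}")
        self.counts: dict[str, int] = {w: int(c) for w, c in counts.items()}
        self.total_tokens: int = sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, word: str) -> bool:
        return word in self.counts

    def __getitem__(self, word: str) -> int:
        return self.counts[word]

    def words(self) -> list[str]:
        return list(self.counts)

    def per_million(self, word: str) -> float:
        return self.counts[word] / self.total_tokens * 1e6

    def probability(self, word: str) -> float:
        return self.counts[word] / self.total_tokens

    # -- wordlist I/O: UTF-8, one "count<TAB>word" per line, no header --

    def to_wordlist(self, path: str | Path) -> None:
        lines = (f"{c}\t{w}" for w, c in sorted(self.counts.items()))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_wordlist(cls, path: str | Path) -> "FrequencyTable":
        counts: dict[str, int] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip():
                continue
            c, w = ln.split("\t")
            counts[w] = counts.get(w, 0) + int(c)
        return cls(counts)


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold segmentation and lemma for one word type."""

    word: str
    segmentation: tuple[str, ...]
    lemma: str

    def __post_init__(self) -> None:
        if "".join(self.segmentation) != self.word:
            raise ValueError(f"segmentation does not concatenate to {self.word!r}")
        first = next(m for m in self.segmentation if m)
        if self.lemma != first:
            raise ValueError("lemma must equal the first (root) morph")


def annotations_to_tsv(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    """Write "word<TAB>morph1 morph2 ...<TAB>lemma" lines."""
    lines = [
        f"{a.word}\t{' '.join(m for m in a.segmentation if m)}\t{a.lemma}"
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def annotations_from_tsv(path: str | Path) -> list[GoldAnnotation]:
    out = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        word, seg, lemma = ln.split("\t")
        out.append(GoldAnnotation(word, tuple(seg.split(" ")), lemma))
    return out


@dataclass(frozen=True)
class StimulusItem:
    """One lexical-decision stimulus: a letter string, word or pseudoword.

    Noise-masked and symbol-string stimulus categories exist only as the
    ``category`` label; no images are rendered here.
    """

    string: str
    is_word: bool
    gold: GoldAnnotation | None = None
    category: str = ""

    def __post_init__(self) -> None:
        if self.is_word is False and self.gold is not None:
            raise ValueError("pseudowords carry no gold annotation")

    @property
    def length_N(self) -> int:
        return len(self.string)


# ---------------------------------------------------------------------------
# corpus generation


def generate_corpus(
    grammar: MorphGrammar, n_tokens: int, seed: int
) -> tuple[FrequencyTable, list[GoldAnnotation]]:
    """Sample ``n_tokens`` word tokens from the grammar.

    Root identities are Zipf-distributed with the grammar's exponent;
    each suffix slot is sampled independently per token. Every generated
    word type carries a gold segmentation (root + non-empty suffixes) and
    a lemma (the root). Deterministic given ``seed``.
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "corpus"))
    root_p = grammar.root_probabilities()
    slot_p = [np.asarray(p) for p in grammar.slot_probabilities()]

    root_idx = rng.choice(len(grammar.roots), size=n_tokens, p=root_p)
    slot_idx = [
        rng.choice(len(slot), size=n_tokens, p=p)
        for slot, p in zip(grammar.suffix_slots, slot_p)
    ]

    counts: Counter[str] = Counter()
    gold: dict[str, GoldAnnotation] = {}
    for t in range(n_tokens):
        root = grammar.roots[root_idx[t]]
        suffixes = [
            grammar.suffix_slots[j][slot_idx[j][t]]
            for j in range(len(grammar.suffix_slots))
        ]
        word = root + "".join(suffixes)
        counts[word] += 1
        if word not in gold:
            seg = (root, *[s for s in suffixes if s])
            gold[word] = GoldAnnotation(word, seg, root)
    return FrequencyTable(counts), [gold[w] for w in sorted(gold)]


def lemma_table(
    annotations: Sequence[GoldAnnotation], freq: FrequencyTable
) -> FrequencyTable:
    """Aggregate word counts into lemma counts (total frequency of the
    words sharing a root). The lemma total equals the word total."""
    counts: Counter[str] = Counter()
    seen = set()
    for a in annotations:
        if a.word not in freq:
            raise KeyError(f"annotated word {a.word!r} missing from frequency table")
        if a.word in seen:
            continue
        seen.add(a.word)
        counts[a.lemma] += freq[a.word]
    missing = set(freq.counts) - seen
    if missing:
        raise KeyError(f"words without annotation: {sorted(missing)[:5]}")
    return FrequencyTable(counts)


# ---------------------------------------------------------------------------
# character n-gram model


class NGramModel:
    """Additively smoothed character n-gram model with start/end padding.

    Histories are the last ``order - 1`` characters (start-padded with
    ``^``); the end-of-word symbol ``#`` is part of every conditional
    distribution so that sampled words terminate.
    """

    START = "^"

    def __init__(
        self,
        order: int,
        probs: Mapping[str, Mapping[str, float]],
        smoothing: float,
        alphabet: Sequence[str],
    ):
        if order < 2:
            raise ValueError("order must be >= 2")
        self.order = order
        self.smoothing = smoothing
        self.alphabet = tuple(alphabet)  # letters only, END excluded
        self.probs = {h: dict(d) for h, d in probs.items()}
        for h, d in self.probs.items():
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"conditional for history {h!r} does not sum to 1")

    def conditional(self, history: str) -> dict[str, float]:
        h = (self.START * (self.order - 1) + history)[-(self.order - 1):]
        if h in self.probs:
            return self.probs[h]
        # unseen history: smoothing-only (uniform) distribution
        support = list(self.alphabet) + [END]
        return {c: 1.0 / len(support) for c in support}

    def logprob(self, word: str) -> float:
        """Natural-log probability of the word including termination."""
        lp = 0.0
        hist = ""
        for ch in word + END:
            p = self.conditional(hist).get(ch, 0.0)
            if p == 0.0:
                return -math.inf
            lp += math.log(p)
            hist += ch
        return lp

    def sample_word(self, rng: np.random.Generator, max_len: int = 64) -> str:
        out = []
        hist = ""
        for _ in range(max_len):
            d = self.conditional(hist)
            symbols = sorted(d)
            p = np.array([d[s] for s in symbols])
            ch = symbols[rng.choice(len(symbols), p=p / p.sum())]
            if ch == END:
                break
            out.append(ch)
            hist += ch
        return "".join(out)


def train_ngram(freq: FrequencyTable, order: int = 3, smoothing: float = 0.1) -> NGramModel:
    """Token-weighted character n-gram counts with additive smoothing.

    Each word contributes its token count to every transition along
    ``^..^ w1 .. wL #``. Smoothing adds ``smoothing`` pseudo-counts for
    every letter of the observed alphabet plus the end symbol.
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if len(freq) == 0:
        raise ValueError("empty frequency table")
    alphabet = sorted({ch for w in freq.counts for ch in w})
    trans: dict[str, Counter[str]] = {}
    pad = NGramModel.START * (order - 1)
    for word, c in freq.counts.items():
        s = pad + word + END
        for i in range(order - 1, len(s)):
            h = s[i - order + 1 : i]
            trans.setdefault(h, Counter())[s[i]] += c
    support = alphabet + [END]
    probs: dict[str, dict[str, float]] = {}
    for h, counter in trans.items():
        denom = sum(counter.values()) + smoothing * len(support)
        probs[h] = {c: (counter.get(c, 0) + smoothing) / denom for c in support}
        if smoothing == 0:
            probs[h] = {c: p for c, p in probs[h].items() if p > 0}
    return NGramModel(order, probs, smoothing, alphabet)


def generate_pseudowords(
    model: NGramModel,
    length_targets: Sequence[int],
    n: int,
    seed: int,
    exclude: set[str] | frozenset[str] = frozenset(),
    max_retries: int = 10_000,
) -> list[StimulusItem]:
    """Sample unique pseudowords whose lengths exactly match the targets.

    The n-gram model does not condition on length, so each target length
    is hit by rejection sampling with a per-item retry cap. Outputs never
    collide with ``exclude`` (the real-word set) or with each other.
    """
    if n != len(length_targets):
        raise ValueError("n must equal the number of length targets")
    rng = np.random.default_rng(derive_seed(seed, "pseudowords"))
    out: list[StimulusItem] = []
    used: set[str] = set(exclude)
    for target in length_targets:
        ok = None
        for _ in range(max_retries):
            w = model.sample_word(rng, max_len=target + 1)
            if len(w) == target and w not in used:
                ok = w
                break
        if ok is None:
            raise RuntimeError(
                f"could not generate a pseudoword of length {target} "
                f"within {max_retries} retries"
            )
        used.add(ok)
        out.append(StimulusItem(ok, is_word=False, category="pseudoword"))
    return out


# ---------------------------------------------------------------------------
# stimulus sampling


def sample_stimulus_set(
    freq: FrequencyTable,
    n_items: int,
    length_range: tuple[int, int] = (4, 16),
    seed: int = 0,
    target_mean: float = 10.3,
    target_sd: float = 2.8,
    gold: Mapping[str, GoldAnnotation] | None = None,
) -> list[StimulusItem]:
    """Sample words without replacement, stratified by length so that the
    sample's length mean/SD approximate the configured targets.

    Per-length quotas follow a discretized normal over the admissible
    length range; shortfalls at one length spill over to the nearest
    available lengths. Within a length, words are sampled uniformly
    without replacement.
    """
    lo, hi = length_range
    pool: dict[int, list[str]] = {}
    for w in sorted(freq.counts):
        if lo <= len(w) <= hi:
            pool.setdefault(len(w), []).append(w)
    n_avail = sum(len(v) for v in pool.values())
    if n_avail < n_items:
        raise ValueError(
            f"only {n_avail} words available in length range {length_range}, "
            f"need {n_items}"
        )
    lengths = np.arange(lo, hi + 1)
    if not (lengths.min() <= target_mean <= lengths.max()):
        raise ValueError(
            f"target mean {target_mean} outside achievable range [{lo}, {hi}]"
        )
    # discretized normal quota, renormalized over available lengths
    weights = np.exp(-0.5 * ((lengths - target_mean) / target_sd) ** 2)
    avail = np.array([len(pool.get(int(L), [])) for L in lengths], dtype=float)
    weights = weights * (avail > 0)
    if weights.sum() == 0:
        raise ValueError("no words available near the target length distribution")
    weights /= weights.sum()
    quota = np.floor(weights * n_items).astype(int)
    # distribute the remainder by largest fractional part
    frac = weights * n_items - quota
    for idx in np.argsort(-frac):
        if quota.sum() >= n_items:
            break
        quota[idx] += 1
    # cap by availability, spill shortfall to nearest lengths
    quota = np.minimum(quota, avail.astype(int))
    shortfall = n_items - int(quota.sum())
    order = np.argsort(np.abs(lengths - target_mean), kind="stable")
    while shortfall > 0:
        progressed = False
        for idx in order:
            room = int(avail[idx]) - int(quota[idx])
            if room > 0 and shortfall > 0:
                take = min(room, shortfall)
                quota[idx] += take
                shortfall -= take
                progressed = True
        if not progressed:  # pragma: no cover - guarded by n_avail check
            raise ValueError("cannot satisfy n_items within the length range")

    rng = np.random.default_rng(derive_seed(seed, "stimuli"))
    items: list[StimulusItem] = []
    for L, q in zip(lengths, quota):
        if q == 0:
            continue
        words = pool[int(L)]
        pick = rng.choice(len(words), size=int(q), replace=False)
        for i in sorted(pick):
            w = words[i]
            items.append(
                StimulusItem(
                    w,
                    is_word=True,
                    gold=gold.get(w) if gold else None,
                    category="word",
                )
            )
    return items


def stimuli_to_tsv(items: Sequence[StimulusItem], path: str | Path) -> None:
    """Write stimulus sets as TSV with columns item, string, is_word, length."""
    lines = ["item\tstring\tis_word\tlength"]
    for i, it in enumerate(items):
        lines.append(f"{i}\t{it.string}\t{int(it.is_word)}\t{it.length_N}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
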