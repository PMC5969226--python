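"""Minimum-description-length morph segmentation.

A two-part code is minimized: the *lexicon cost* prices the inventory of
morphs (each distinct morph spelled out letter by letter, plus an
end-of-morph marker, under a maximum-likelihood character model estimated
over the lexicon entries), and the *corpus cost* prices the corpus
rewritten as pointers into that lexicon,

    corpus_cost = -sum_m n(m) * log2(n(m) / N_tok),

with n(m) the token-weighted count of morph m and N_tok their sum.
Training greedily re-segments word types by recursive binary splitting
until an epoch no longer improves the total cost. Decoding of arbitrary
strings is exact Viterbi over split points, with a character-model
fallback pricing substrings that are not in the lexicon, so pseudowords
receive finite surprisals that reflect their word-likeness.

A word's surprisal (in bits) is the sum of its morphs' surprisals
-log2(n(m)/N_tok) — the pointer cost of expressing the word.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_stimuli import END, FrequencyTable, GoldAnnotation, derive_seed

import numpy as np

__all__ = [
    "MorphLexicon",
    "SegmentationModel",
    "Segmentation",
    "corpus_cost",
    "lexicon_cost",
    "train",
    "exhaustive_optimum",
    "segment",
    "evaluate_boundaries",
]

_LOG2 = math.log(2.0)


def _xlog2x(n: float) -> float:
    return 0.0 if n <= 0 else n * math.log2(n)


@dataclass
class MorphLexicon:
    """Morph inventory with token counts and a lexicon character model.

    ``char_model`` assigns probabilities to letters plus the end-of-morph
    marker ``#``, estimated by maximum likelihood over the characters of
    the distinct lexicon entries (one end marker per entry).
    """

    morph_counts: dict[str, int]
    char_model: dict[str, float]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.morph_counts.values()):
            raise ValueError("all morph counts must be >= 1")
        s = sum(self.char_model.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("character model must sum to 1")

    @property
    def total_morph_tokens(self) -> int:
        return sum(self.morph_counts.values())

    def morph_surprisal(self, morph: str) -> float:
        """Pointer cost -log2 n(m)/N_tok in bits; KeyError if absent."""
        return -math.log2(self.morph_counts[morph] / self.total_morph_tokens)

    def char_cost(self, s: str) -> float:
        """Character-model spell-out cost of ``s`` plus one end marker."""
        bits = 0.0
        for ch in s + END:
            p = self.char_model.get(ch)
            if p is None or p <= 0:
                raise KeyError(f"character {ch!r} outside the character model")
            bits -= math.log2(p)
        return bits

    @classmethod
    def from_counts(cls, morph_counts: Mapping[str, int]) -> "MorphLexicon":
        chars: Counter[str] = Counter()
        for m in morph_counts:
            chars.update(m)
            chars[END] += 1
        total = sum(chars.values())
        model = {c: k / total for c, k in chars.items()}
        return cls(dict(morph_counts), model)


@dataclass
class SegmentationModel:
    """An MDL segmentation of a corpus: lexicon plus per-word pointers."""

    lexicon: MorphLexicon
    word_segmentations: dict[str, tuple[str, ...]]
    total_cost_bits: float

    def __post_init__(self) -> None:
        for w, seg in self.word_segmentations.items():
            if "".join(seg) != w:
                raise ValueError(f"segmentation of {w!r} does not concatenate")
            for m in seg:
                if m not in self.lexicon.morph_counts:
                    raise ValueError(f"morph {m!r} of {w!r} missing from lexicon")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "morph_counts": self.lexicon.morph_counts,
            "char_model": self.lexicon.char_model,
            "word_segmentations": {
                w: list(s) for w, s in self.word_segmentations.items()
            },
            "total_cost_bits": self.total_cost_bits,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SegmentationModel":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        lex = MorphLexicon(payload["morph_counts"], payload["char_model"])
        segs = {w: tuple(s) for w, s in payload["word_segmentations"].items()}
        return cls(lex, segs, payload["total_cost_bits"])


@dataclass(frozen=True)
class Segmentation:
    """Viterbi decoding result for one string."""

    word: str
    morphs: tuple[str, ...]
    morph_surprisals_bits: tuple[float, ...]

    def __post_init__(self) -> None:
        if "".join(self.morphs) != self.word:
            raise ValueError("morphs do not concatenate to the word")

    @property
    def word_surprisal_bits(self) -> float:
        return float(sum(self.morph_surprisals_bits))


# ---------------------------------------------------------------------------
# the two-part code


def corpus_cost(model: SegmentationModel) -> float:
    """Pointer-message cost: N_tok times the entropy of the morph
    token distribution, in bits."""
    return _corpus_cost_from_counts(model.lexicon.morph_counts)


def _corpus_cost_from_counts(morph_counts: Mapping[str, int]) -> float:
    n_tok = sum(morph_counts.values())
    if n_tok == 0:
        raise ValueError("empty model")
    return _xlog2x(n_tok) - sum(_xlog2x(c) for c in morph_counts.values())


def lexicon_cost(lexicon: MorphLexicon) -> float:
    """Spell-out cost of the distinct morphs under the lexicon's own
    ML character model (one end marker per morph), in bits.

    With character counts C(c) over all entries and total T this equals
    T*log2 T - sum_c C(c)*log2 C(c).
    """
    chars: Counter[str] = Counter()
    for m in lexicon.morph_counts:
        chars.update(m)
        chars[END] += 1
    total = sum(chars.values())
    return _xlog2x(total) - sum(_xlog2x(k) for k in chars.values())


def total_cost(morph_counts: Mapping[str, int]) -> float:
    """Two-part code length of a lexicon/pointer configuration."""
    lex = MorphLexicon.from_counts(morph_counts)
    return lexicon_cost(lex) + _corpus_cost_from_counts(morph_counts)


# ---------------------------------------------------------------------------
# training workspace with O(1) incremental cost updates


class _Workspace:
    """Mutable morph counts with running sufficient statistics.

    corpus cost  = N*log2 N - S_n   where S_n = sum n(m) log2 n(m)
    lexicon cost = T*log2 T - S_c   where S_c = sum C(ch) log2 C(ch)
    """

    def __init__(self) -> None:
        self.morph_counts: Counter[str] = Counter()
        self.char_counts: Counter[str] = Counter()
        self.n_tok = 0
        self.t_chars = 0
        self._s_n = 0.0
        self._s_c = 0.0

    def _bump_char(self, ch: str, delta: int) -> None:
        old = self.char_counts[ch]
        new = old + delta
        self._s_c += _xlog2x(new) - _xlog2x(old)
        self.t_chars += delta
        if new:
            self.char_counts[ch] = new
        else:
            del self.char_counts[ch]

    def add(self, morph: str, count: int) -> None:
        old = self.morph_counts[morph]
        new = old + count
        self._s_n += _xlog2x(new) - _xlog2x(old)
        self.n_tok += count
        self.morph_counts[morph] = new
        if old == 0:  # new lexicon entry: spell it out
            for ch in morph:
                self._bump_char(ch, 1)
            self._bump_char(END, 1)

    def remove(self, morph: str, count: int) -> None:
        old = self.morph_counts[morph]
        if old < count - 1e-9:
            raise ValueError(f"removing {count} of {morph!r} but only {old} present")
        new = old - count
        if abs(new) < 1e-9:  # snap float residue from non-integer weights
            new = 0
        self._s_n += _xlog2x(new) - _xlog2x(old)
        self.n_tok -= count
        if new:
            self.morph_counts[morph] = new
        else:
            del self.morph_counts[morph]
            for ch in morph:
                self._bump_char(ch, -1)
            self._bump_char(END, -1)

    def cost(self) -> float:
        return (
            _xlog2x(self.n_tok) - self._s_n + _xlog2x(self.t_chars) - self._s_c
        )


def _resegment(ws: _Workspace, s: str, count: int) -> list[str]:
    """Greedy recursive binary splitting of one word type.

    The string (count tokens) must not currently be in the workspace.
    Compares keeping ``s`` whole against every binary split; a split must
    strictly lower the total cost. Chosen halves are refined recursively.
    Ties prefer no split, then the earliest split point.
    """
    ws.add(s, count)
    best_cost = ws.cost()
    ws.remove(s, count)
    best_i = None
    for i in range(1, len(s)):
        left, right = s[:i], s[i:]
        ws.add(left, count)
        ws.add(right, count)
        cand = ws.cost()
        ws.remove(left, count)
        ws.remove(right, count)
        if cand < best_cost - 1e-12:
            best_cost = cand
            best_i = i
    if best_i is None:
        ws.add(s, count)
        return [s]
    morphs = _resegment(ws, s[:best_i], count)
    morphs += _resegment(ws, s[best_i:], count)
    return morphs


def _greedy_epochs(
    words: list[str],
    weights: Mapping[str, float],
    segs: dict[str, list[str]],
    rng: np.random.Generator,
    epsilon_bits: float,
    max_epochs: int,
) -> list[float]:
    """Run shuffled re-segmentation epochs in place; return epoch costs."""
    ws = _Workspace()
    for w in words:
        for m in segs[w]:
            ws.add(m, weights[w])
    cost = ws.cost()
    epoch_costs = [cost]
    for _ in range(max_epochs):
        order = rng.permutation(len(words))
        for idx in order:
            w = words[idx]
            c = weights[w]
            for m in segs[w]:
                ws.remove(m, c)
            segs[w] = _resegment(ws, w, c)
        new_cost = ws.cost()
        epoch_costs.append(new_cost)
        improved = cost - new_cost
        cost = new_cost
        if improved < epsilon_bits:
            break
    return epoch_costs


def train(
    freq: FrequencyTable,
    seed: int = 0,
    epsilon_bits: float = 0.1,
    max_epochs: int = 20,
    count_dampening: str = "types",
) -> SegmentationModel:
    """Fit the MDL segmentation model by greedy recursive splitting.

    Every word type starts as a single morph. Each epoch visits word
    types in a seeded shuffled order, removes the word's current morphs,
    and re-segments it from scratch by recursive binary splitting;
    training stops when an epoch improves the total cost by less than
    ``epsilon_bits`` or after ``max_epochs`` epochs.

    ``count_dampening`` sets the word weights of the *search* phase:
    "types" (each word type counted once — the weighting under which
    shared affixes are discoverable on modest corpora, and the standard
    choice for baseline MDL segmentation), "log" (log2(count)+1), or
    "tokens" (raw token counts). After the search phase the token-weighted
    cost is refined by further epochs under the true counts, so the
    final lexicon counts — and hence all surprisals — are token
    frequencies regardless of the dampening. The returned cost never
    exceeds the unsegmented baseline.
    """
    if len(freq) == 0:
        raise ValueError("empty frequency table")
    if count_dampening not in ("types", "log", "tokens"):
        raise ValueError(f"unknown count_dampening {count_dampening!r}")
    rng = np.random.default_rng(derive_seed(seed, "mdl-train"))
    words = sorted(freq.counts)
    segs: dict[str, list[str]] = {w: [w] for w in words}
    token_w = {w: float(freq[w]) for w in words}
    if count_dampening != "tokens":
        if count_dampening == "types":
            damp = {w: 1.0 for w in words}
        else:
            damp = {w: math.log2(freq[w]) + 1.0 for w in words}
        _greedy_epochs(words, damp, segs, rng, epsilon_bits, max_epochs)
    epoch_costs = _greedy_epochs(
        words, token_w, segs, rng, epsilon_bits, max_epochs
    )
    cost = epoch_costs[-1]
    baseline = total_cost({w: freq[w] for w in words})
    if cost > baseline:  # pragma: no cover - defensive; greedy can only
        # beat or match the unsegmented state it can always fall back to
        segs = {w: [w] for w in words}
        cost = baseline
        epoch_costs = [baseline]
    counts: Counter[str] = Counter()
    for w in words:
        for m in segs[w]:
            counts[m] += freq[w]
    lexicon = MorphLexicon.from_counts(counts)
    model = SegmentationModel(
        lexicon, {w: tuple(segs[w]) for w in words}, total_cost_bits=cost
    )
    model.epoch_costs = epoch_costs  # token-phase log; monotone non-increasing
    return model


# ---------------------------------------------------------------------------
# brute-force oracle


def _all_segmentations(word: str) -> list[tuple[str, ...]]:
    out = []
    for mask in range(2 ** (len(word) - 1)):
        cuts = [i + 1 for i in range(len(word) - 1) if mask >> i & 1]
        bounds = [0, *cuts, len(word)]
        out.append(tuple(word[a:b] for a, b in zip(bounds, bounds[1:])))
    return out


def exhaustive_optimum(freq: FrequencyTable, max_joint: int = 1_000_000) -> SegmentationModel:
    """Global MDL optimum by enumerating every joint segmentation.

    Only feasible on tiny corpora; the joint search space (product of the
    per-word segmentation counts) must not exceed ``max_joint``.
    """
    words = sorted(freq.counts)
    per_word = [_all_segmentations(w) for w in words]
    joint = 1
    for options in per_word:
        joint *= len(options)
        if joint > max_joint:
            raise ValueError("search-space bound exceeded")
    best = None
    best_cost = math.inf
    for combo in itertools.product(*per_word):
        counts: Counter[str] = Counter()
        for w, seg in zip(words, combo):
            for m in seg:
                counts[m] += freq[w]
        c = total_cost(counts)
        if c < best_cost - 1e-12:
            best_cost = c
            best = combo
    lexicon_counts: Counter[str] = Counter()
    for w, seg in zip(words, best):
        for m in seg:
            lexicon_counts[m] += freq[w]
    lexicon = MorphLexicon.from_counts(lexicon_counts)
    return SegmentationModel(
        lexicon, dict(zip(words, best)), total_cost_bits=best_cost
    )


# ---------------------------------------------------------------------------
# Viterbi decoding with character-model fallback


def _substring_cost(model: SegmentationModel, s: str) -> float:
    lex = model.lexicon
    if s in lex.morph_counts:
        return lex.morph_surprisal(s)
    return lex.char_cost(s)


def segment(model: SegmentationModel, string: str) -> Segmentation:
    """Minimal-cost segmentation of an arbitrary letter string.

    Dynamic programming over split points; lexicon morphs cost their
    pointer surprisal, any other substring costs its character-model
    spell-out (so pseudowords and unseen words are always decodable).
    Ties prefer fewer morphs, then a longer first morph.
    """
    if not string:
        raise ValueError("empty string")
    for ch in string:
        if ch not in model.lexicon.char_model:
            raise KeyError(f"character {ch!r} outside the model's alphabet")
    L = len(string)
    # cost of every substring [i, j)
    sub = {}
    for i in range(L):
        for j in range(i + 1, L + 1):
            sub[i, j] = _substring_cost(model, string[i:j])
    # best[j] = (cost, n_morphs, neg_first_splits, splits ending at j)
    best: list[tuple] = [(0.0, 0, (), ())] + [None] * L
    for j in range(1, L + 1):
        cands = []
        for i in range(j):
            c, n, _, splits = best[i]
            new_splits = splits + ((i,) if i > 0 else ())
            cands.append(
                (c + sub[i, j], n + 1, tuple(-p for p in new_splits), new_splits)
            )
        best[j] = min(cands, key=lambda t: (t[0], t[1], t[2]))
    cost, _, _, splits = best[L]
    bounds = [0, *splits, L]
    morphs = tuple(string[a:b] for a, b in zip(bounds, bounds[1:]))
    surps = tuple(_substring_cost(model, m) for m in morphs)
    return Segmentation(string, morphs, surps)


def word_surprisal(model: SegmentationModel, string: str) -> float:
    """Convenience: total surprisal in bits of the Viterbi segmentation."""
    return segment(model, string).word_surprisal_bits


# ---------------------------------------------------------------------------
# boundary evaluation against gold segmentations


def _boundaries(seg: Sequence[str]) -> set[int]:
    pos, cuts = 0, set()
    for m in seg[:-1]:
        pos += len(m)
        cuts.add(pos)
    return cuts


def evaluate_boundaries(
    model: SegmentationModel, gold: Sequence[GoldAnnotation]
) -> tuple[float, float, float]:
    """Micro-averaged precision/recall/F1 on internal morph boundaries."""
    tp = fp = fn = 0
    for a in gold:
        pred = _boundaries(segment(model, a.word).morphs)
        true = _boundaries([m for m in a.segmentation if m])
        tp += len(pred & true)
        fp += len(pred - true)
        fn += len(true - pred)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1
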