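"""Item-level predictor variables for letter-string stimuli.

Seven predictors, each a surprisal-style quantity tied to a different
level of representation:

- ``length``            — letter count; surprisal of a uniform-letter model
                          is proportional to it, so the raw count is used
                          (the constant is absorbed by standardization).
- ``image_complexity``  — gif-index: compressed (GIF/LZW) byte size of the
                          rendered string divided by the raw pixel-buffer
                          byte size.
- ``bigram_surprisal``  — -log2 of the mean per-million frequency of the
                          string's open bigrams (ordered letter pairs at
                          any distance).
- ``mdl_surprisal``     — word surprisal under the MDL morph model.
- ``lemma_surprisal``   — -log2 probability of the word's lemma (summed
                          frequency of the forms sharing its root).
- ``tpl``               — transition probability from lemma: surface
                          frequency / lemma frequency, on the raw
                          probability scale.
- ``surface_surprisal`` — -log2 probability of the exact word form.

Pseudowords support only the first four (no lemma, no surface frequency).
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .corpus_stimuli import FrequencyTable, StimulusItem
from .mdl import SegmentationModel, segment

__all__ = [
    "PredictorMatrix",
    "RenderConfig",
    "PREDICTOR_COLUMNS",
    "PSEUDOWORD_COLUMNS",
    "length_surprisal",
    "open_bigrams",
    "build_bigram_table",
    "bigram_surprisal",
    "render_string",
    "gif_index",
    "surface_surprisal",
    "lemma_surprisal",
    "tpl",
    "build_predictor_matrix",
]

#: Fixed column order of the predictor matrix.
PREDICTOR_COLUMNS = (
    "image_complexity",
    "length",
    "bigram_surprisal_bits",
    "tpl",
    "mdl_surprisal_bits",
    "lemma_surprisal_bits",
    "surface_surprisal_bits",
)

#: Columns available for pseudowords (no lemma/surface statistics exist).
PSEUDOWORD_COLUMNS = (
    "image_complexity",
    "length",
    "bigram_surprisal_bits",
    "mdl_surprisal_bits",
)

#: Default smoothing floor for bigram means, in occurrences per million.
BIGRAM_EPSILON_PM = 0.01


def length_surprisal(item: StimulusItem | str) -> int:
    """Letter count N; the uniform-letter surprisal is proportional to it."""
    s = item.string if isinstance(item, StimulusItem) else item
    return len(s)


# ---------------------------------------------------------------------------
# open bigrams


def open_bigrams(string: str) -> list[str]:
    """All ordered letter pairs (i, j), i < j, at any distance.

    Order is preserved and duplicates retained: "take" yields
    TA, TK, TE, AK, AE, KE; a string of N letters yields N(N-1)/2 pairs.
    """
    if len(string) < 2:
        raise ValueError("open bigrams require at least 2 letters")
    return [
        string[i] + string[j]
        for i in range(len(string) - 1)
        for j in range(i + 1, len(string))
    ]


def build_bigram_table(
    freq: FrequencyTable, token_weighted: bool = True
) -> FrequencyTable:
    """Open-bigram frequency table over a corpus.

    Each word contributes every one of its open bigrams, weighted by its
    token count (set ``token_weighted=False`` for type counts).
    """
    counts: Counter[str] = Counter()
    for w, c in freq.counts.items():
        if len(w) < 2:
            continue
        weight = c if token_weighted else 1
        for bg in open_bigrams(w):
            counts[bg] += weight
    if not counts:
        raise ValueError("no open bigrams in corpus (all words shorter than 2)")
    return FrequencyTable(counts)


def bigram_surprisal(
    string: str,
    bigram_freqs: FrequencyTable,
    epsilon_pm: float = BIGRAM_EPSILON_PM,
) -> float:
    """-log2 of the string's mean open-bigram per-million frequency.

    The mean (over the string's open bigrams, unseen ones counting 0) is
    floored at ``epsilon_pm`` per million before taking the logarithm.
    """
    if len(bigram_freqs) == 0:
        raise ValueError("empty bigram table")
    pms = [
        bigram_freqs.per_million(bg) if bg in bigram_freqs else 0.0
        for bg in open_bigrams(string)
    ]
    mean_pm = max(float(np.mean(pms)), epsilon_pm)
    return -math.log2(mean_pm / 1e6)


# ---------------------------------------------------------------------------
# gif-index image complexity

# 5x7 dot-matrix glyphs, one row-major bit pattern per letter (row = 5 bits,
# MSB leftmost). Case-insensitive; an in-package font keeps rendering
# deterministic across platforms.
_GLYPHS_5x7: dict[str, tuple[int, ...]] = {
    "a": (0b01110, 0b10001, 0b10001, 0b11111, 0b10001, 0b10001, 0b10001),
    "b": (0b11110, 0b10001, 0b10001, 0b11110, 0b10001, 0b10001, 0b11110),
    "c": (0b01110, 0b10001, 0b10000, 0b10000, 0b10000, 0b10001, 0b01110),
    "d": (0b11100, 0b10010, 0b10001, 0b10001, 0b10001, 0b10010, 0b11100),
    "e": (0b11111, 0b10000, 0b10000, 0b11110, 0b10000, 0b10000, 0b11111),
    "f": (0b11111, 0b10000, 0b10000, 0b11110, 0b10000, 0b10000, 0b10000),
    "g": (0b01110, 0b10001, 0b10000, 0b10111, 0b10001, 0b10001, 0b01111),
    "h": (0b10001, 0b10001, 0b10001, 0b11111, 0b10001, 0b10001, 0b10001),
    "i": (0b01110, 0b00100, 0b00100, 0b00100, 0b00100, 0b00100, 0b01110),
    "j": (0b00111, 0b00010, 0b00010, 0b00010, 0b00010, 0b10010, 0b01100),
    "k": (0b10001, 0b10010, 0b10100, 0b11000, 0b10100, 0b10010, 0b10001),
    "l": (0b10000, 0b10000, 0b10000, 0b10000, 0b10000, 0b10000, 0b11111),
    "m": (0b10001, 0b11011, 0b10101, 0b10101, 0b10001, 0b10001, 0b10001),
    "n": (0b10001, 0b11001, 0b10101, 0b10011, 0b10001, 0b10001, 0b10001),
    "o": (0b01110, 0b10001, 0b10001, 0b10001, 0b10001, 0b10001, 0b01110),
    "p": (0b11110, 0b10001, 0b10001, 0b11110, 0b10000, 0b10000, 0b10000),
    "q": (0b01110, 0b10001, 0b10001, 0b10001, 0b10101, 0b10010, 0b01101),
    "r": (0b11110, 0b10001, 0b10001, 0b11110, 0b10100, 0b10010, 0b10001),
    "s": (0b01111, 0b10000, 0b10000, 0b01110, 0b00001, 0b00001, 0b11110),
    "t": (0b11111, 0b00100, 0b00100, 0b00100, 0b00100, 0b00100, 0b00100),
    "u": (0b10001, 0b10001, 0b10001, 0b10001, 0b10001, 0b10001, 0b01110),
    "v": (0b10001, 0b10001, 0b10001, 0b10001, 0b10001, 0b01010, 0b00100),
    "w": (0b10001, 0b10001, 0b10001, 0b10101, 0b10101, 0b10101, 0b01010),
    "x": (0b10001, 0b01010, 0b00100, 0b00100, 0b00100, 0b01010, 0b10001),
    "y": (0b10001, 0b01010, 0b00100, 0b00100, 0b00100, 0b00100, 0b00100),
    "z": (0b11111, 0b00001, 0b00010, 0b00100, 0b01000, 0b10000, 0b11111),
    " ": (0, 0, 0, 0, 0, 0, 0),
}


@dataclass(frozen=True)
class RenderConfig:
    """Monospaced rendering of a letter string into a grayscale bitmap.

    Dark glyphs on a mid-gray background, one fixed-width cell per
    letter, centered on a fixed-size canvas of ``canvas_letters`` cells
    (the stimuli of a lexical-decision experiment share one screen, so
    complexity is compared on a common canvas; with ``canvas_letters``
    None the image is cut to the string, width ``cell_width * N``).
    """

    cell_width: int = 12
    cell_height: int = 16
    foreground: int = 0
    background: int = 192
    bit_depth: int = 8
    canvas_letters: int | None = 16

    def __post_init__(self) -> None:
        if self.foreground == self.background:
            raise ValueError("foreground and background gray levels must differ")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit grayscale rendering is supported")


def render_string(string: str, config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Render a string as a uint8 grayscale pixel array (H x W)."""
    if not string:
        raise ValueError("empty string")
    w, h = config.cell_width, config.cell_height
    n_cells = config.canvas_letters or len(string)
    if len(string) > n_cells:
        raise ValueError(
            f"string of {len(string)} letters exceeds the "
            f"{n_cells}-cell canvas"
        )
    # dot size: biggest integer block of 5x7 dots fitting the cell
    dot = max(1, min((w - 2) // 5, (h - 2) // 7))
    x0 = (w - 5 * dot) // 2
    y0 = (h - 7 * dot) // 2
    img = np.full((h, w * n_cells), config.background, dtype=np.uint8)
    left = (n_cells - len(string)) // 2  # center the string on the canvas
    for k, ch in enumerate(string):
        k = k + left
        glyph = _GLYPHS_5x7.get(ch.lower())
        if glyph is None:
            raise KeyError(f"unrenderable character {ch!r}")
        for r, rowbits in enumerate(glyph):
            for c in range(5):
                if rowbits >> (4 - c) & 1:
                    y = y0 + r * dot
                    x = k * w + x0 + c * dot
                    img[y : y + dot, x : x + dot] = config.foreground
    return img


def gif_index(string: str, config: RenderConfig = RenderConfig()) -> float:
    """Compressed-to-uncompressed byte-size ratio of the rendered string.

    The string is rendered with the in-package dot-matrix font and
    encoded as a GIF (LZW); the ratio is the full encoded-file length
    divided by the raw pixel-buffer size (width x height x 1 byte).
    Deterministic for a fixed config; higher values mean the image is
    harder to compress, i.e. visually more complex.
    """
    pixels = render_string(string, config)
    image = Image.fromarray(pixels, mode="L")
    buf = io.BytesIO()
    image.save(buf, format="GIF")
    raw_bytes = pixels.size  # 8-bit grayscale: 1 byte per pixel
    return len(buf.getvalue()) / raw_bytes


# ---------------------------------------------------------------------------
# frequency-based surprisals


def surface_surprisal(word: str, freq: FrequencyTable) -> float:
    """-log2 probability of the exact word form. No smoothing: a real
    word missing from the corpus is a data error, not a rare event."""
    if word not in freq:
        raise KeyError(f"word {word!r} not in frequency table")
    return -math.log2(freq.probability(word))


def lemma_surprisal(
    word: str,
    lemma_map: Mapping[str, str],
    lemma_freqs: FrequencyTable,
) -> float:
    """-log2 probability of the word's lemma (root family frequency)."""
    lemma = lemma_map.get(word)
    if lemma is None:
        raise KeyError(f"word {word!r} has no lemma assignment")
    return -math.log2(lemma_freqs.probability(lemma))


def tpl(
    word: str,
    freq: FrequencyTable,
    lemma_map: Mapping[str, str],
    lemma_freqs: FrequencyTable,
) -> float:
    """Transition probability from lemma: surface count / lemma count.

    The conditional probability of the full form given its stem; in
    (0, 1], equal to 1 when the word is its lemma's only attested form.
    """
    lemma = lemma_map.get(word)
    if lemma is None:
        raise KeyError(f"word {word!r} has no lemma assignment")
    surface = freq[word]
    total = lemma_freqs[lemma]
    if total < surface:
        raise ValueError(
            f"lemma frequency {total} < surface frequency {surface} for {word!r}"
        )
    return surface / total


# ---------------------------------------------------------------------------
# assembled predictor matrix


class PredictorMatrix:
    """Items x predictors with a per-cell availability mask.

    ``values`` is a DataFrame in the fixed :data:`PREDICTOR_COLUMNS`
    order; unavailable cells (e.g. lemma statistics of pseudowords) are
    NaN in ``values`` and False in ``available``. Available cells are
    guaranteed finite.
    """

    def __init__(self, values: pd.DataFrame, available: pd.DataFrame):
        if list(values.columns) != list(PREDICTOR_COLUMNS):
            values = values.reindex(columns=list(PREDICTOR_COLUMNS))
            available = available.reindex(
                columns=list(PREDICTOR_COLUMNS), fill_value=False
            )
        if values.shape != available.shape:
            raise ValueError("values and availability mask shapes differ")
        masked = values.where(available)
        if not np.isfinite(masked.to_numpy()[available.to_numpy()]).all():
            raise ValueError("available cells must be finite")
        self.values = masked
        self.available = available.astype(bool)

    def __len__(self) -> int:
        return len(self.values)

    def column(self, name: str) -> pd.Series:
        return self.values[name]

    def available_columns(self) -> list[str]:
        """Columns available for every item (fully observed)."""
        return [c for c in self.values.columns if self.available[c].all()]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="item")

    @classmethod
    def from_tsv(cls, path) -> "PredictorMatrix":
        values = pd.read_csv(path, sep="\t", index_col="item")
        return cls(values, values.notna())


def build_predictor_matrix(
    items: Sequence[StimulusItem],
    model: SegmentationModel,
    freq: FrequencyTable,
    lemma_map: Mapping[str, str],
    lemma_freqs: FrequencyTable,
    bigram_table: FrequencyTable,
    render_config: RenderConfig = RenderConfig(),
) -> PredictorMatrix:
    """Compute all predictors for a stimulus set.

    Words get all seven columns; pseudowords get only image complexity,
    length, bigram surprisal, and MDL surprisal. Any missing resource
    raises an error naming the item and column.
    """
    rows, avail = [], []
    for it in items:
        row = {c: np.nan for c in PREDICTOR_COLUMNS}
        ok = {c: False for c in PREDICTOR_COLUMNS}
        try:
            row["image_complexity"] = gif_index(it.string, render_config)
        except KeyError as e:
            raise KeyError(f"item {it.string!r}, column image_complexity: {e}")
        row["length"] = length_surprisal(it)
        row["bigram_surprisal_bits"] = bigram_surprisal(it.string, bigram_table)
        row["mdl_surprisal_bits"] = segment(model, it.string).word_surprisal_bits
        for c in PSEUDOWORD_COLUMNS:
            ok[c] = True
        if it.is_word:
            try:
                row["surface_surprisal_bits"] = surface_surprisal(it.string, freq)
                row["lemma_surprisal_bits"] = lemma_surprisal(
                    it.string, lemma_map, lemma_freqs
                )
                row["tpl"] = tpl(it.string, freq, lemma_map, lemma_freqs)
            except KeyError as e:
                raise KeyError(f"item {it.string!r}: {e}")
            ok["surface_surprisal_bits"] = True
            ok["lemma_surprisal_bits"] = True
            ok["tpl"] = True
        rows.append(row)
        avail.append(ok)
    index = [it.string for it in items]
    values = pd.DataFrame(rows, index=index, columns=list(PREDICTOR_COLUMNS))
    mask = pd.DataFrame(avail, index=index, columns=list(PREDICTOR_COLUMNS))
    return PredictorMatrix(values, mask)
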