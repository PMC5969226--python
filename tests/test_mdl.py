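"""Two-part code arithmetic, greedy training, Viterbi decoding."""

import itertools
import math

import numpy as np
import pytest

from morphsurprisal import mdl
from morphsurprisal.corpus_stimuli import FrequencyTable, GoldAnnotation


def brute_force_min_cost(model, s):
    """Exhaustive minimum decode cost over all 2^(L-1) segmentations."""
    best = math.inf
    for mask in range(2 ** (len(s) - 1)):
        cuts = [i + 1 for i in range(len(s) - 1) if mask >> i & 1]
        bounds = [0, *cuts, len(s)]
        cost = sum(
            mdl._substring_cost(model, s[a:b]) for a, b in zip(bounds, bounds[1:])
        )
        best = min(best, cost)
    return best


class TestCosts:
    def test_single_morph_corpus_cost_is_zero(self):
        assert mdl._corpus_cost_from_counts({"ab": 37}) == pytest.approx(0.0)

    def test_two_equal_morphs_cost_two_bits(self):
        assert mdl._corpus_cost_from_counts({"a": 1, "b": 1}) == pytest.approx(2.0)

    def test_corpus_cost_is_count_times_entropy(self):
        # {5,3,2}: 10 * H(0.5, 0.3, 0.2)
        h = -sum(p * math.log2(p) for p in (0.5, 0.3, 0.2))
        got = mdl._corpus_cost_from_counts({"x": 5, "y": 3, "z": 2})
        assert got == pytest.approx(10 * h)
        assert got == pytest.approx(14.855, abs=1e-3)

    def test_lexicon_cost_single_letter(self):
        # chars a,# each probability 0.5 -> 1 bit each
        lex = mdl.MorphLexicon.from_counts({"a": 5})
        assert mdl.lexicon_cost(lex) == pytest.approx(2.0)

    def test_lexicon_cost_two_letter(self):
        # a, b, # uniform at 1/3
        lex = mdl.MorphLexicon.from_counts({"ab": 1})
        assert mdl.lexicon_cost(lex) == pytest.approx(3 * math.log2(3))

    def test_adding_morph_types_grows_lexicon_cost(self):
        # with the re-estimated char model, verified over random lexica
        rng = np.random.default_rng(0)
        letters = "abcdef"
        for _ in range(100):
            n = rng.integers(1, 6)
            morphs = {
                "".join(rng.choice(list(letters), size=rng.integers(1, 5))): 1
                for _ in range(n)
            }
            extra = "".join(rng.choice(list(letters), size=rng.integers(1, 5)))
            if extra in morphs:
                continue
            before = mdl.lexicon_cost(mdl.MorphLexicon.from_counts(morphs))
            after = mdl.lexicon_cost(
                mdl.MorphLexicon.from_counts({**morphs, extra: 1})
            )
            assert after > before


class TestTrain:
    def test_single_word_stays_whole(self):
        m = mdl.train(FrequencyTable({"ab": 100}), seed=0)
        assert m.word_segmentations == {"ab": ("ab",)}
        # exhaustive check over both candidate segmentations
        split_cost = mdl.total_cost({"a": 100, "b": 100})
        assert m.total_cost_bits <= split_cost

    def test_epoch_costs_monotone_nonincreasing(self, planted_corpus):
        freq, _ = planted_corpus
        m = mdl.train(freq, seed=1)
        costs = m.epoch_costs
        assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))

    def test_cost_not_above_unsegmented_baseline(self, planted_corpus):
        freq, _ = planted_corpus
        m = mdl.train(freq, seed=2)
        baseline = mdl.total_cost(dict(freq.counts))
        assert m.total_cost_bits <= baseline + 1e-9

    def test_deterministic_given_seed(self, planted_corpus):
        freq, _ = planted_corpus
        a = mdl.train(freq, seed=5)
        b = mdl.train(freq, seed=5)
        assert a.word_segmentations == b.word_segmentations
        assert a.total_cost_bits == pytest.approx(b.total_cost_bits)

    def test_total_cost_recomputes_from_scratch(self, planted_model):
        recomputed = mdl.corpus_cost(planted_model) + mdl.lexicon_cost(
            planted_model.lexicon
        )
        assert planted_model.total_cost_bits == pytest.approx(
            recomputed, abs=1e-6
        )

    def test_json_round_trip_lossless(self, planted_model, tmp_path):
        path = tmp_path / "model.json"
        planted_model.to_json(path)
        loaded = mdl.SegmentationModel.from_json(path)
        assert loaded.lexicon.morph_counts == planted_model.lexicon.morph_counts
        assert loaded.lexicon.char_model == planted_model.lexicon.char_model
        assert loaded.word_segmentations == planted_model.word_segmentations
        assert loaded.total_cost_bits == planted_model.total_cost_bits


class TestExhaustiveOptimum:
    def test_matches_train_on_single_word(self):
        freq = FrequencyTable({"ab": 10})
        assert (
            mdl.exhaustive_optimum(freq).total_cost_bits
            == mdl.train(freq, seed=0).total_cost_bits
        )

    def test_invariant_under_word_order(self):
        c1 = mdl.exhaustive_optimum(
            FrequencyTable({"aba": 10, "ab": 5, "ba": 5})
        ).total_cost_bits
        c2 = mdl.exhaustive_optimum(
            FrequencyTable({"ba": 5, "aba": 10, "ab": 5})
        ).total_cost_bits
        assert c1 == pytest.approx(c2)

    def test_bound_enforced(self):
        words = {f"abcabcabcabc{c}": 1 for c in "abcdefgh"}
        with pytest.raises(ValueError, match="search-space bound"):
            mdl.exhaustive_optimum(FrequencyTable(words), max_joint=1000)


class TestSegment:
    def test_known_morphs_recombine(self, planted_model, planted_corpus):
        # a novel root+er+s combination, never seen in training, decodes
        # into pointers to the learned root and suffix morphs
        _, gold = planted_corpus
        root = gold[0].lemma
        seg = mdl.segment(planted_model, root + "ers")
        assert seg.morphs == (root, "er", "s")
        assert seg.word_surprisal_bits == pytest.approx(
            sum(
                planted_model.lexicon.morph_surprisal(m)
                for m in (root, "er", "s")
            )
        )

    def test_single_morph_model_zero_surprisal(self):
        m = mdl.train(FrequencyTable({"ab": 100}), seed=0)
        seg = mdl.segment(m, "ab")
        assert seg.morphs == ("ab",)
        assert seg.word_surprisal_bits == pytest.approx(0.0)

    def test_surprisal_additivity(self, planted_model, planted_corpus):
        freq, _ = planted_corpus
        for w in list(freq.counts)[:20]:
            seg = mdl.segment(planted_model, w)
            assert seg.word_surprisal_bits == pytest.approx(
                sum(seg.morph_surprisals_bits), abs=1e-9
            )

    def test_viterbi_equals_exhaustive_minimum(self, planted_model):
        rng = np.random.default_rng(13)
        alphabet = sorted(
            c for c in planted_model.lexicon.char_model if c.isalpha()
        )
        for _ in range(60):
            s = "".join(rng.choice(alphabet, size=rng.integers(2, 9)))
            viterbi = mdl.segment(planted_model, s).word_surprisal_bits
            assert viterbi == pytest.approx(
                brute_force_min_cost(planted_model, s), abs=1e-9
            )

    def test_viterbi_not_above_training_segmentation(self, planted_model):
        lex = planted_model.lexicon
        for w, seg in list(planted_model.word_segmentations.items())[:30]:
            stored = sum(lex.morph_surprisal(m) for m in seg)
            assert (
                mdl.segment(planted_model, w).word_surprisal_bits
                <= stored + 1e-9
            )

    def test_appending_letter_never_decreases_cost(self, planted_model):
        rng = np.random.default_rng(5)
        alphabet = sorted(
            c for c in planted_model.lexicon.char_model if c.isalpha()
        )
        for _ in range(30):
            s = "".join(rng.choice(alphabet, size=rng.integers(2, 7)))
            base = mdl.segment(planted_model, s).word_surprisal_bits
            longer = mdl.segment(
                planted_model, s + str(rng.choice(alphabet))
            ).word_surprisal_bits
            assert longer >= base - 1e-9

    def test_unknown_character_rejected(self, planted_model):
        with pytest.raises(KeyError):
            mdl.segment(planted_model, "abcß")


class TestEvaluateBoundaries:
    def test_perfect_prediction(self):
        freq = FrequencyTable({"ab": 100})
        m = mdl.train(freq, seed=0)
        gold = [GoldAnnotation("ab", ("ab",), "ab")]
        assert mdl.evaluate_boundaries(m, gold) == (1.0, 1.0, 1.0)

    def test_never_splitting_gives_zero_recall(self):
        freq = FrequencyTable({"abcd": 1, "efgh": 1})
        m = mdl.train(freq, seed=0, max_epochs=0)
        gold = [
            GoldAnnotation("abcd", ("ab", "cd"), "ab"),
            GoldAnnotation("efgh", ("ef", "gh"), "ef"),
        ]
        p, r, f1 = mdl.evaluate_boundaries(m, gold)
        assert r == 0.0
        assert f1 == 0.0

    def test_matches_independent_set_intersection(
        self, planted_model, planted_corpus
    ):
        _, gold = planted_corpus
        p, r, f1 = mdl.evaluate_boundaries(planted_model, gold)
        # independent oracle: recompute from scratch with plain set ops
        tp = fp = fn = 0
        for a in gold:
            pred_morphs = mdl.segment(planted_model, a.word).morphs
            pred = set(itertools.accumulate(len(m) for m in pred_morphs[:-1]))
            true = set(
                itertools.accumulate(len(m) for m in a.segmentation[:-1])
            )
            tp += len(pred & true)
            fp += len(pred - true)
            fn += len(true - pred)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        assert p == pytest.approx(prec)
        assert r == pytest.approx(rec)
        assert f1 == pytest.approx(2 * prec * rec / (prec + rec))
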