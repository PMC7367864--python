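"""Metric suite: validity, Levenshtein similarity (vs DP oracle),
threshold accuracies, adapted BLEU, confusion ledger, distributions."""

import math
import random
from collections import Counter

import pytest

from synthactions import (
    PairedSample,
    SampleSource,
    action_distribution,
    adapted_bleu,
    confusion_ledger,
    evaluate_predictions,
    levenshtein_similarity,
    parse,
    threshold_accuracies,
    validity,
)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent brute-force edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def random_string(rng, max_len=30):
    alphabet = "abcdef °C%();"
    return "".join(rng.choice(alphabet) for _ in range(rng.randrange(0, max_len)))


class TestLevenshteinSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("Stir for 2 h", "Stir for 2 h", 1.0),
            ("abc", "abd", 2 / 3),
            ("", "abc", 0.0),
            ("", "", 1.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert levenshtein_similarity(a, b) == pytest.approx(expected)

    def test_against_dp_oracle(self):
        rng = random.Random(17)
        for _ in range(300):
            a, b = random_string(rng), random_string(rng)
            expected = (
                1.0
                if not a and not b
                else 1.0 - dp_levenshtein(a, b) / max(len(a), len(b), 1)
            )
            assert levenshtein_similarity(a, b) == pytest.approx(expected)

    def test_symmetry_range_and_identity(self):
        rng = random.Random(23)
        for _ in range(200):
            a, b = random_string(rng), random_string(rng)
            s = levenshtein_similarity(a, b)
            assert s == pytest.approx(levenshtein_similarity(b, a))
            assert 0.0 <= s <= 1.0
            assert (s == 1.0) == (a == b)


class TestThresholdAccuracies:
    def test_example(self):
        assert threshold_accuracies([1.0, 0.95, 0.80, 0.50]) == (0.25, 0.50, 0.75)

    def test_degenerate(self):
        assert threshold_accuracies([1.0, 1.0]) == (1.0, 1.0, 1.0)
        assert threshold_accuracies([0.0, 0.0]) == (0.0, 0.0, 0.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            threshold_accuracies([])

    def test_monotone_invariant(self):
        rng = random.Random(5)
        sims = [rng.random() for _ in range(500)]
        a100, a90, a75 = threshold_accuracies(sims)
        assert a100 <= a90 <= a75


class TestValidity:
    def test_examples(self):
        assert validity(["Concentrate", "garbage!!"]) == 0.5
        assert validity(["Stir for 2 h", "Add water; Concentrate"]) == 1.0

    def test_against_per_string_loop(self, small_corpus):
        from synthactions import try_parse

        strings = [s.action_string for s in small_corpus[:100]]
        strings += ["not an action", "Blorbify now", ""]
        expected = sum(1 for s in strings if try_parse(s).ok) / len(strings)
        assert validity(strings) == pytest.approx(expected)


def textbook_bleu(preds, refs):
    """Independent standard corpus BLEU (uniform 4-gram weights)."""
    matches, totals = [0] * 4, [0] * 4
    plen = rlen = 0
    for p, r in zip(preds, refs):
        pt, rt = p.split(), r.split()
        plen += len(pt)
        rlen += len(rt)
        for n in range(1, 5):
            pn = Counter(tuple(pt[i : i + n]) for i in range(len(pt) - n + 1))
            rn = Counter(tuple(rt[i : i + n]) for i in range(len(rt) - n + 1))
            totals[n - 1] += max(len(pt) - n + 1, 0)
            matches[n - 1] += sum(min(c, rn[g]) for g, c in pn.items())
    if any(m == 0 for m in matches):
        return 0.0
    log_p = sum(math.log(m / t) for m, t in zip(matches, totals)) / 4
    bp = 1.0 if plen >= rlen else math.exp(1 - rlen / plen)
    return bp * math.exp(log_p)


class TestAdaptedBleu:
    def test_identical_corpora(self, small_corpus):
        refs = [s.action_string for s in small_corpus[:50]]
        assert adapted_bleu(refs, refs) == pytest.approx(1.0)

    def test_single_word_exact_pair_not_penalized(self):
        assert adapted_bleu(["Concentrate"], ["Concentrate"]) == pytest.approx(1.0)

    def test_disjoint_vocabulary(self):
        assert adapted_bleu(["aa bb cc dd"], ["xx yy zz ww"]) == 0.0

    def test_reduces_to_standard_bleu_on_long_pairs(self):
        preds = [
            "Add water and stir the mixture well",
            "Filter keep filtrate then concentrate in vacuo",
            "Wash with brine and dry over sodium sulfate",
        ]
        refs = [
            "Add water and stir the flask well",
            "Filter keep filtrate then concentrate in vacuo",
            "Wash twice with brine and dry over magnesium sulfate",
        ]
        assert all(len(s.split()) >= 4 for s in preds + refs)
        assert adapted_bleu(preds, refs) == pytest.approx(textbook_bleu(preds, refs))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            adapted_bleu(["a"], ["a", "b"])


class TestConfusionLedger:
    def test_identical_sequences_full_match(self):
        seqs = [parse("Add water; Stir for 2 h")]
        ledger = confusion_ledger(seqs, seqs)
        assert ledger.per_type["Add"].type_match == 1
        assert ledger.per_type["Add"].full_match == 1
        assert ledger.per_type["Stir"].full_match == 1
        assert not ledger.substitutions

    def test_missing_prediction_counts_ground_truth_only(self):
        ledger = confusion_ledger([parse("Add water")], [parse("Add water; Stir for 2 h")])
        assert ledger.per_type["Stir"].only_in_ground_truth == 1

    def test_substitution_recorded(self):
        ledger = confusion_ledger([parse("Wait 2 h")], [parse("Stir for 2 h")])
        assert ledger.substitutions[("Stir", "Wait")] == 1

    def test_type_match_without_full_match(self):
        ledger = confusion_ledger([parse("Add water")], [parse("Add brine")])
        assert ledger.per_type["Add"].type_match == 1
        assert ledger.per_type["Add"].full_match == 0

    def test_conservation_invariant(self, small_corpus):
        rng = random.Random(11)
        refs = [s.actions for s in small_corpus[:60]]
        preds = [s.actions for s in small_corpus[10:70]]  # shifted: imperfect
        ledger = confusion_ledger(preds, refs)
        total_ref = sum(len(r) for r in refs)
        accounted = sum(
            c.type_match + c.only_in_ground_truth for c in ledger.per_type.values()
        ) + sum(ledger.substitutions.values())
        assert accounted == total_ref
        for counts in ledger.per_type.values():
            assert counts.full_match <= counts.type_match


class TestActionDistribution:
    def test_single_sample(self):
        corpus = [
            PairedSample(
                sentence="Add water. Add brine.",
                actions=parse("Add water; Add brine"),
                source=SampleSource.SYNTHETIC,
            )
        ]
        dist = action_distribution(corpus)
        assert dist.type_frequencies == {"Add": 2}
        assert dist.actions_per_sentence == [2]

    def test_empty_corpus(self):
        dist = action_distribution([])
        assert dist.type_frequencies == {}
        assert dist.most_common_type is None

    def test_counts_match_naive_tally(self, small_corpus):
        dist = action_distribution(small_corpus)
        naive = Counter()
        for s in small_corpus:
            for a in s.actions:
                naive[a.type.value] += 1
        assert dist.type_frequencies == dict(naive)


def test_evaluate_predictions_report(small_corpus):
    refs = [s.action_string for s in small_corpus[:40]]
    report = evaluate_predictions(refs, refs)
    assert report.validity == 1.0
    assert report.bleu == pytest.approx(1.0)
    assert report.acc100 == report.acc90 == report.acc75 == 1.0
    assert report.n == 40
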