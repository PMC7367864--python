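"""Corpus construction: legacy adapter, source combination, filtering,
splitting, hard-sentence selection, I/O round trips."""

import pytest

from synthactions import (
    ActionType,
    LegacyActionRecord,
    PairedSample,
    SampleSource,
    adapt_legacy,
    combine_sources,
    filter_pretraining,
    parse,
    read_jsonl,
    read_tsv,
    select_hard_sentences,
    serialize,
    split_dataset,
    write_jsonl,
    write_tsv,
)


class TestAdaptLegacy:
    def test_heat_with_temperature_becomes_add_then_settemperature(self):
        records = [
            LegacyActionRecord(
                action_name="Heat",
                compounds=(("X1-ol", ("5 g",)),),
                temperature="50 °C",
            )
        ]
        assert serialize(adapt_legacy(records)) == "Add X1-ol (5 g); SetTemperature 50 °C"

    def test_empty_records(self):
        assert len(adapt_legacy([])) == 0

    def test_heat_with_duration_becomes_add_then_stir(self):
        records = [
            LegacyActionRecord(
                action_name="Heat", compounds=(("X1-ol", ()),), duration="2 h"
            )
        ]
        assert serialize(adapt_legacy(records)) == "Add X1-ol; Stir for 2 h"

    def test_unmappable_record_becomes_invalid_action(self):
        seq = adapt_legacy([LegacyActionRecord(action_name="Centrifuge")])
        assert seq.types() == [ActionType.INVALID_ACTION]

    def test_properties_filtered_per_type(self):
        # legacy records share one property schema; disallowed fields drop
        records = [
            LegacyActionRecord(action_name="Concentrate", temperature="50 °C")
        ]
        assert serialize(adapt_legacy(records)) == "Concentrate"


class TestCombineSources:
    def test_appends_legacy_yield(self):
        nlp = parse("Quench with water; Concentrate")
        legacy = parse("Yield X1-ol (5 g)")
        assert (
            serialize(combine_sources(nlp, legacy))
            == "Quench with water; Concentrate; Yield X1-ol (5 g)"
        )

    def test_no_yield_in_legacy_leaves_unchanged(self):
        nlp = parse("Stir for 2 h")
        legacy = parse("Add water; Concentrate")
        assert combine_sources(nlp, legacy) == nlp

    def test_duplicate_yield_not_appended(self):
        nlp = parse("Concentrate; Yield X1-ol (5 g)")
        legacy = parse("Yield X1-ol (5 g)")
        assert combine_sources(nlp, legacy) == nlp

    def test_nlp_sequence_is_prefix(self):
        nlp = parse("Stir for 2 h")
        legacy = parse("Yield P1 (1 g); Yield P2 (2 g)")
        combined = combine_sources(nlp, legacy)
        assert list(combined)[: len(nlp)] == list(nlp)


def _sample(sentence, actions, source=SampleSource.SYNTHETIC):
    return PairedSample(sentence=sentence, actions=parse(actions), source=source)


class TestFilterPretraining:
    def test_invalid_action_samples_removed(self):
        samples = [
            _sample("The mixture was blorbified.", "InvalidAction"),
            _sample("Add water.", "Add water"),
        ]
        out = filter_pretraining(samples)
        assert [s.sentence for s in out] == ["Add water."]

    def test_short_noaction_kept(self):
        samples = [_sample("A white solid formed.", "NoAction")]  # 21 chars
        assert filter_pretraining(samples) == samples

    def test_long_noaction_with_analysis_keyword_kept(self):
        sentence = "The NMR spectrum showed the expected aromatic signals here."
        assert len(sentence) > 30
        samples = [_sample(sentence, "NoAction")]
        assert filter_pretraining(samples) == samples

    def test_long_noaction_without_keyword_dropped(self):
        sentence = "The product looked like a nice crystalline material overall."
        samples = [_sample(sentence, "NoAction")]
        assert filter_pretraining(samples) == []

    def test_duplicate_sentences_removed_keeping_first(self):
        samples = [
            _sample("Add water.", "Add water"),
            _sample("Add  water.", "Concentrate"),  # same after ws-normalization
        ]
        out = filter_pretraining(samples)
        assert len(out) == 1
        assert serialize(out[0].actions) == "Add water"

    def test_never_increases_and_idempotent(self, small_corpus):
        once = filter_pretraining(small_corpus)
        assert len(once) <= len(small_corpus)
        assert filter_pretraining(once) == once


class TestSplitDataset:
    def _samples(self, n):
        return [_sample(f"Add compound-{i}.", "Add water") for i in range(n)]

    def test_exact_fraction_sizes(self):
        train, valid, test = split_dataset(self._samples(100), (0.8, 0.1, 0.1), seed=7)
        assert (len(train), len(valid), len(test)) == (80, 10, 10)

    def test_determinism(self):
        samples = self._samples(100)
        a = split_dataset(samples, (0.8, 0.1, 0.1), seed=7)
        b = split_dataset(samples, (0.8, 0.1, 0.1), seed=7)
        assert a == b

    def test_partition_property(self):
        samples = self._samples(101)
        train, valid, test = split_dataset(samples, (0.785, 0.107, 0.108), seed=3)
        key = lambda part: sorted(s.sentence for s in part)
        union = key(train) + key(valid) + key(test)
        assert sorted(union) == sorted(s.sentence for s in samples)
        assert not (set(key(train)) & set(key(valid)))
        assert not (set(key(train)) & set(key(test)))
        assert not (set(key(valid)) & set(key(test)))

    def test_published_ratio_on_round_corpus(self):
        # published split sizes 2.16M : 0.27M : 0.27M = 0.8 / 0.1 / 0.1
        n = 1000
        train, valid, test = split_dataset(self._samples(n), (0.8, 0.1, 0.1), seed=0)
        assert len(train) / len(valid) == pytest.approx(2.16 / 0.27)
        assert len(train) / len(test) == pytest.approx(2.16 / 0.27)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._samples(10), (0.5, 0.2, 0.2), seed=0)

    def test_empty_input(self):
        assert split_dataset([], (0.8, 0.1, 0.1), seed=0) == ([], [], [])

    def test_sentence_level_grouping(self):
        samples = self._samples(30) + self._samples(30)  # every sentence twice
        train, valid, test = split_dataset(samples, (0.5, 0.25, 0.25), seed=1)
        for part_a, part_b in ((train, valid), (train, test), (valid, test)):
            overlap = {s.sentence for s in part_a} & {s.sentence for s in part_b}
            assert not overlap


class TestSelectHardSentences:
    def test_followed_by_selected(self):
        s = _sample("The mixture was washed, followed by drying.", "Wash with water")
        assert select_hard_sentences([s]) == [s]

    def test_plain_add_not_selected(self):
        s = _sample("Add water.", "Add water")
        assert select_hard_sentences([s]) == []

    def test_repeated_compound_selected(self):
        s = _sample(
            "Ethyl acetate was added and the mixture was washed.",
            "Add ethyl acetate; Wash with ethyl acetate",
        )
        assert select_hard_sentences([s]) == [s]

    def test_context_dependent_verb_selected(self):
        s = _sample("The mixture was heated to 50 °C.", "SetTemperature 50 °C")
        assert select_hard_sentences([s]) == [s]


def test_tsv_and_jsonl_round_trip(tmp_path, small_corpus):
    samples = small_corpus[:40]
    tsv = tmp_path / "c.tsv"
    jsonl = tmp_path / "c.jsonl"
    write_tsv(samples, str(tsv))
    write_jsonl(samples, str(jsonl))
    from_tsv = read_tsv(str(tsv))
    from_jsonl = read_jsonl(str(jsonl))
    assert [s.sentence for s in from_tsv] == [s.sentence for s in samples]
    assert [s.actions for s in from_tsv] == [s.actions for s in samples]
    assert [(s.sentence, s.actions, s.source) for s in from_jsonl] == [
        (s.sentence, s.actions, s.source) for s in samples
    ]
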