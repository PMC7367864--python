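"""Sentence splitting, entity tagging, compound relationships."""

import pytest

from synthactions import (
    EXAMPLE_PROCEDURE,
    EntityLabel,
    compound_relationships,
    normalize_text,
    split_sentences,
    tag_entities,
)


class TestSplitSentences:
    def test_example_procedure_manual_segmentation(self):
        # manual segmentation of the worked-example paragraph: four
        # terminal periods ("...at 0 °C.", "...was added.", "...in vacuo.",
        # "...92%).")
        spans = split_sentences(EXAMPLE_PROCEDURE)
        assert len(spans) == 4
        assert spans[0].text.endswith("0 °C.")
        assert spans[1].text == (
            "After 30 min, sodium acetoxyborohydride (18.7 g, 88.2 mmol) was added."
        )

    def test_empty_input(self):
        assert split_sentences("") == []

    def test_two_terminal_periods(self):
        assert len(split_sentences("A. Then B.")) == 2

    def test_abbreviations_and_decimals_do_not_split(self):
        assert len(split_sentences("The aq. layer contained 1.5 g of salt.")) == 1
        assert len(split_sentences("Washed with conc. HCl. Then dried.")) == 2

    def test_degree_period_before_lowercase_does_not_split(self):
        s = "A solution in EtOH at 30 °C. was treated with acid."
        assert len(split_sentences(s)) == 1

    def test_idempotent_on_single_sentences(self, small_corpus):
        for sample in small_corpus[:80]:
            spans = split_sentences(sample.sentence)
            assert len(spans) == 1
            assert spans[0].text == normalize_text(sample.sentence)

    def test_concatenation_reconstructs_modulo_whitespace(self):
        spans = split_sentences(EXAMPLE_PROCEDURE)
        rebuilt = " ".join(s.text for s in spans)
        assert rebuilt == normalize_text(EXAMPLE_PROCEDURE)


class TestTagEntities:
    def test_addition_with_quantities_and_temperature(self):
        s = "acetaldehyde (4.95 mL, 88.2 mmol) at 0 °C"
        tags = tag_entities(s)
        by_label = {}
        for t in tags:
            by_label.setdefault(t.label, []).append(t)
        assert [t.value for t in by_label[EntityLabel.COMPOUND]] == ["acetaldehyde"]
        assert [t.value for t in by_label[EntityLabel.QUANTITY]] == [
            "4.95 mL",
            "88.2 mmol",
        ]
        assert [t.value for t in by_label[EntityLabel.TEMPERATURE]] == ["0 °C"]

    def test_ph_value(self):
        tags = tag_entities("adjusting to pH 1.5")
        assert any(t.label is EntityLabel.PH_VALUE and t.value == "1.5" for t in tags)

    def test_no_entities(self):
        assert tag_entities("xyzzy plugh") == []

    def test_spans_reproduce_surface_text(self, small_corpus):
        for sample in small_corpus[:100]:
            s = normalize_text(sample.sentence)
            for tag in tag_entities(s):
                assert 0 <= tag.start < tag.end <= len(s)

    def test_same_label_spans_do_not_overlap(self, small_corpus):
        for sample in small_corpus[:100]:
            tags = tag_entities(sample.sentence)
            by_label = {}
            for t in tags:
                by_label.setdefault(t.label, []).append((t.start, t.end))
            for spans in by_label.values():
                spans.sort()
                for (a, b), (c, d) in zip(spans, spans[1:]):
                    assert b <= c

    def test_duration_and_atmosphere(self):
        tags = tag_entities("stirred for 2 h under nitrogen overnight")
        labels = [(t.label, t.value) for t in tags]
        assert (EntityLabel.DURATION, "2 h") in labels
        assert (EntityLabel.ATMOSPHERE, "nitrogen") in labels
        assert (EntityLabel.DURATION, "overnight") in labels


class TestCompoundRelationships:
    def test_solution_of_x_in_z_added_to_solution_of_y_in_z(self):
        rels = compound_relationships(
            "A solution of X1-ol in Z1-ol is added to a solution of Y1-ol in Z1-ol"
        )
        assert ("X1-ol", "SOLUTE_IN", "Z1-ol") in rels
        assert ("Y1-ol", "SOLUTE_IN", "Z1-ol") in rels
        assert ("X1-ol", "ADDED_TO", "Y1-ol") in rels

    def test_addition_order_equivalence(self):
        a = compound_relationships("To water was added hydrochloric acid.")
        b = compound_relationships("Hydrochloric acid was added to water.")
        assert a == b == [("hydrochloric acid", "ADDED_TO", "water")]

    def test_single_compound_sentence_yields_nothing(self):
        assert compound_relationships("The water was stirred.") == []
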