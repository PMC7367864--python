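"""Rule-based extractor: worked sentences, classification fallbacks,
implicit actions, totality."""

import random

import pytest

from synthactions import (
    ActionType,
    EXAMPLE_ACTION_STRING,
    EXAMPLE_PROCEDURE,
    GeneratorConfig,
    disambiguate_verb,
    extract_procedure,
    extract_sentence,
    generate_corpus,
    insert_implicit_actions,
    parse,
    serialize,
    try_parse,
    validate_sequence,
)
from synthactions.extractor import DEFAULT_LEXICON, UnsupportedVerbError
from conftest import random_noise_string


@pytest.mark.parametrize(
    "sentence, expected",
    [
        (
            "The organic layer was dried over sodium sulfate",
            "CollectLayer organic; DrySolution over sodium sulfate",
        ),
        (
            "23 g of aluminum chloride in 30 mL of dichloroethane was heated to 50 °C.",
            "MakeSolution with aluminum chloride (23 g) and dichloroethane (30 mL); "
            "Add SLN; SetTemperature 50 °C",
        ),
        (
            "3-Bromo-2-fluoroaniline (10 g, 52.63 mmol) was dissolved in DCM "
            "(100 mL) under nitrogen atmosphere.",
            "Add 3-Bromo-2-fluoroaniline (10 g, 52.63 mmol); Add DCM (100 mL) under nitrogen",
        ),
        ("", ""),
        ("Add water.", "Add water"),
        (
            "The title compound was prepared as described in Example 5.",
            "FollowOtherProcedure",
        ),
        ("Das Gemisch wurde zwei Stunden gerührt.", "OtherLanguage"),
        ("1H NMR (400 MHz, CDCl3): δ 7.2-7.4 (m, 5H).", "NoAction"),
        ("The mixture was blorbified for 2 h.", "InvalidAction"),
    ],
)
def test_worked_sentences(sentence, expected):
    assert serialize(extract_sentence(sentence)) == expected


def test_aluminum_chloride_sentence_types():
    seq = extract_sentence(
        "23 g of aluminum chloride in 30 mL of dichloroethane was heated to 50 °C."
    )
    assert seq.types() == [
        ActionType.MAKE_SOLUTION,
        ActionType.ADD,
        ActionType.SET_TEMPERATURE,
    ]


def test_ph_sentence_yields_ph_action_with_value():
    seq = extract_sentence(
        "After adjusting to pH 1.5 with 10% hydrochloric acid, the ethyl acetate "
        "solution was separated, washed with a saturated aqueous sodium chloride "
        "and then dried over anhydrous magnesium sulfate."
    )
    ph_actions = [a for a in seq if a.type is ActionType.PH]
    assert len(ph_actions) == 1
    assert ph_actions[0].condition.ph_value == 1.5
    assert ph_actions[0].materials[0].name == "10% hydrochloric acid"
    # the work-up chain after the pH adjustment
    assert serialize(seq) == (
        "PH with 10% hydrochloric acid to pH 1.5; PhaseSeparation; "
        "CollectLayer organic; Wash with saturated aqueous sodium chloride; "
        "DrySolution over anhydrous magnesium sulfate"
    )


def test_flagship_procedure_matches_reference():
    seq = extract_procedure(EXAMPLE_PROCEDURE)
    assert len(seq) == 16
    assert serialize(seq) == EXAMPLE_ACTION_STRING


def test_paraphrase_equivalence_of_addition_order():
    a = extract_sentence("To water was added hydrochloric acid.")
    b = extract_sentence("Hydrochloric acid was added to water.")
    assert serialize(a) == serialize(b) == "Add water; Add hydrochloric acid"


def test_filter_phase_filled_across_sentences():
    seq = extract_procedure("The solution mixture is filtered. It is then concentrated.")
    assert serialize(seq) == "Filter keep filtrate; Concentrate"
    # single sentence: extract_procedure equals extract_sentence
    one = "The mixture was stirred for 2 h at 0 °C."
    assert extract_procedure(one) == extract_sentence(one)


@pytest.mark.parametrize(
    "lemma, context, expected",
    [
        ("heat", "was heated to 50 °C.", ActionType.SET_TEMPERATURE),
        ("heat", "heated at 80 °C for 2 h", ActionType.STIR),
        ("heat", "heated to reflux for 2 h", ActionType.REFLUX),
        ("remove", "the solvent was removed", ActionType.CONCENTRATE),
        ("remove", "removed by filtration", ActionType.FILTER),
        ("dry", "dried over magnesium sulfate", ActionType.DRY_SOLUTION),
        ("dry", "dried at 50 °C", ActionType.DRY_SOLID),
    ],
)
def test_disambiguate_verb(lemma, context, expected):
    assert disambiguate_verb(lemma, context) is expected


def test_disambiguate_unknown_lemma_signals_unsupported():
    with pytest.raises(UnsupportedVerbError):
        disambiguate_verb("blorbify", "was blorbified")


def test_insert_implicit_actions():
    sentence = "The organic layer was dried over sodium sulfate"
    bare = parse("DrySolution over sodium sulfate")
    out = insert_implicit_actions(bare, sentence)
    assert out.types()[0] is ActionType.COLLECT_LAYER
    assert len(out) == len(bare) + 1
    # no implicit trigger: unchanged
    plain = parse("Stir for 2 h")
    assert insert_implicit_actions(plain, "The mixture was stirred for 2 h.") == plain


def test_solution_subject_inserts_makesolution():
    sentence = "A solution of X1-ol (1 g) in water (5 mL) was stirred for 2 h."
    seq = extract_sentence(sentence)
    assert seq.types() == [
        ActionType.MAKE_SOLUTION,
        ActionType.ADD,
        ActionType.STIR,
    ]
    assert seq[1].materials[0].name == "SLN"


def test_totality_and_validity_on_arbitrary_input():
    rng = random.Random(7)
    noisy = generate_corpus(GeneratorConfig(seed=21, n_samples=150, noise=True))
    inputs = [s.sentence for s in noisy] + [random_noise_string(rng) for _ in range(100)]
    for text in inputs:
        seq = extract_sentence(text)
        assert validate_sequence(seq).ok
        assert try_parse(serialize(seq)).ok


def test_lexicon_extension_maps_new_verb():
    lexicon = DEFAULT_LEXICON.extended({"lyophilize": "DrySolid"})
    seq = extract_sentence("The solid was lyophilized.", lexicon)
    assert seq.types() == [ActionType.DRY_SOLID]
    # default lexicon treats the same sentence as unsupported
    assert extract_sentence("The solid was lyophilized.").types() == [
        ActionType.INVALID_ACTION
    ]


def test_extraction_with_repetitions_and_extract_verb():
    seq = extract_sentence("The aqueous layer was extracted three times with ethyl acetate (50 mL).")
    assert serialize(seq) == (
        "CollectLayer aqueous; Extract with ethyl acetate (50 mL) x 3"
    )
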