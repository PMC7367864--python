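"""Action model: the closed type set, allowed properties, validation."""

import pytest

from synthactions import (
    Action,
    ActionSequence,
    ActionType,
    Condition,
    KeepPhase,
    Quantity,
    QuantityKind,
    allowed_properties,
    mention,
    validate_action,
    validate_sequence,
)
from synthactions.actions import (
    NON_LABORATORY_TYPES,
    action_type_from_name,
    sequence_from_json,
    sequence_to_json,
)


def test_type_set_is_closed_with_28_members():
    assert len(ActionType) == 28
    assert len(NON_LABORATORY_TYPES) == 4
    assert action_type_from_name("makesolution") is ActionType.MAKE_SOLUTION
    assert action_type_from_name("ADD") is ActionType.ADD
    with pytest.raises(KeyError):
        action_type_from_name("Blorbify")


def test_allowed_properties_total_over_all_types():
    for t in ActionType:
        props = allowed_properties(t)
        assert props <= {
            "materials",
            "temperature",
            "duration",
            "atmosphere",
            "ph_value",
            "dropwise",
            "repetitions",
            "keep_phase",
        }
    for t in NON_LABORATORY_TYPES:
        assert allowed_properties(t) == frozenset()
    assert allowed_properties("Filter") == {"keep_phase"}
    assert allowed_properties(ActionType.NO_ACTION) == frozenset()
    assert allowed_properties(ActionType.ADD) == {
        "materials",
        "temperature",
        "atmosphere",
        "dropwise",
    }
    with pytest.raises(KeyError):
        allowed_properties("NotAnAction")


@pytest.mark.parametrize(
    "action, ok",
    [
        (Action(type=ActionType.STIR, condition=Condition(duration="2 h")), True),
        (Action(type=ActionType.CONCENTRATE), True),
        (Action(type=ActionType.STIR, materials=(mention("water"),)), False),
        (Action(type=ActionType.MAKE_SOLUTION, materials=(mention("water"),)), False),
        (
            Action(
                type=ActionType.MAKE_SOLUTION,
                materials=(mention("water"), mention("salt")),
            ),
            True,
        ),
        (Action(type=ActionType.FILTER, keep_phase=KeepPhase.AQUEOUS), False),
        (Action(type=ActionType.FILTER, keep_phase=KeepPhase.FILTRATE), True),
        (Action(type=ActionType.COLLECT_LAYER, keep_phase=KeepPhase.ORGANIC), True),
        (Action(type=ActionType.PH, condition=Condition(ph_value=15.0)), False),
        (Action(type=ActionType.NO_ACTION), True),
        (Action(type=ActionType.NO_ACTION, condition=Condition(duration="2 h")), False),
        (Action(type=ActionType.ADD), False),  # Add requires a material
    ],
)
def test_validate_action(action, ok):
    assert validate_action(action).ok is ok


def test_violations_name_the_offending_field():
    bad = Action(type=ActionType.STIR, materials=(mention("water"),))
    result = validate_action(bad)
    assert any("materials" in v and "Stir" in v for v in result.violations)


def test_sln_requires_preceding_makesolution():
    seq = ActionSequence((Action(type=ActionType.ADD, materials=(mention("SLN"),)),))
    assert not validate_sequence(seq).ok
    seq2 = ActionSequence(
        (
            Action(
                type=ActionType.MAKE_SOLUTION,
                materials=(mention("a"), mention("b")),
            ),
            Action(type=ActionType.ADD, materials=(mention("SLN"),)),
        )
    )
    assert validate_sequence(seq2).ok


@pytest.mark.parametrize(
    "raw, kind",
    [
        ("6.00 g", QuantityKind.MASS),
        ("147 mL", QuantityKind.VOLUME),
        ("88.2 mmol", QuantityKind.AMOUNT),
        ("1 M", QuantityKind.CONCENTRATION),
        ("92%", QuantityKind.CONCENTRATION),
        ("2.5 equiv", QuantityKind.EQUIVALENTS),
        ("3 drops", QuantityKind.OTHER),
    ],
)
def test_quantity_kind_inference(raw, kind):
    assert Quantity(raw).kind is kind


def test_quantity_rejects_empty_raw():
    with pytest.raises(ValueError):
        Quantity("  ")


def test_json_round_trip(small_corpus):
    for sample in small_corpus[:50]:
        restored = sequence_from_json(sequence_to_json(sample.actions))
        assert restored == sample.actions
    assert '"schema_version"' in sequence_to_json(small_corpus[0].actions)
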