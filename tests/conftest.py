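"""Shared fixtures: a seeded random generator of valid action sequences
(used by the bijectivity property tests) and small synthetic corpora."""

from __future__ import annotations

import random

import pytest

from synthactions import (
    Action,
    ActionSequence,
    ActionType,
    Condition,
    GeneratorConfig,
    KeepPhase,
    generate_corpus,
    generate_pools,
    mention,
)

_NAMES = [
    "water",
    "brine",
    "sodium sulfate",
    "ethyl acetate",
    "acetic acid",
    "4-(aminomethyl)phenol",
    "N,N-dimethylformamide",
    "2-(2-hydroxyphenyl)-ethanol",
    "methyl 3-[(2,4-dichlorophenyl)(hydroxy)methyl]benzoate",
    "tert-butyl carbamate",
    "10% hydrochloric acid",
    "saturated aqueous sodium chloride",
]
_QUANTITIES = [
    "6.00 g",
    "14.7 mmol",
    "7.4 mL",
    "1 M",
    "92%",
    "0.302 mmol",
    "18.7 g",
    "2.5 equiv",
    "0.05 ml",
]
_TEMPERATURES = ["0 °C", "room temperature", "-78 °C", "100–105 °C", "50 °C"]
_DURATIONS = ["30 min", "2 h", "overnight", "16 h"]
_ATMOSPHERES = ["nitrogen", "argon"]
_PH_VALUES = [1.5, 7.0, 10.0, 3.0]


def _random_mention(rng: random.Random, max_quantities: int = 2):
    n_q = rng.randrange(0, max_quantities + 1)
    return mention(rng.choice(_NAMES), *rng.sample(_QUANTITIES, n_q))


def random_valid_action(rng: random.Random) -> Action:
    """A random action satisfying the allowed-property table, in canonical
    form (the serializer's domain)."""
    atype = rng.choice(list(ActionType))
    cond = {}
    materials = ()
    keep = None
    allowed_map = {
        ActionType.ADD: ("temperature", "atmosphere", "dropwise"),
        ActionType.QUENCH: ("temperature", "dropwise"),
        ActionType.STIR: ("duration", "temperature", "atmosphere"),
        ActionType.SONICATE: ("duration", "temperature"),
        ActionType.MICROWAVE: ("duration", "temperature"),
        ActionType.DRY_SOLID: ("duration", "temperature"),
        ActionType.WAIT: ("duration", "temperature"),
        ActionType.REFLUX: ("duration", "atmosphere"),
        ActionType.DEGAS: ("duration", "atmosphere"),
        ActionType.WASH: ("repetitions",),
        ActionType.EXTRACT: ("repetitions",),
    }
    for f in allowed_map.get(atype, ()):
        if rng.random() < 0.5:
            if f == "temperature":
                cond["temperature"] = rng.choice(_TEMPERATURES)
            elif f == "duration":
                cond["duration"] = rng.choice(_DURATIONS)
            elif f == "atmosphere":
                cond["atmosphere"] = rng.choice(_ATMOSPHERES)
            elif f == "dropwise":
                cond["dropwise"] = True
            elif f == "repetitions":
                cond["repetitions"] = rng.choice([2, 3])
    if atype in (ActionType.ADD, ActionType.YIELD):
        materials = (_random_mention(rng),)
    elif atype in (
        ActionType.QUENCH,
        ActionType.WASH,
        ActionType.EXTRACT,
        ActionType.TRITURATE,
        ActionType.PH,
        ActionType.DRY_SOLUTION,
        ActionType.RECRYSTALLIZE,
    ):
        if rng.random() < 0.8:
            materials = (_random_mention(rng, max_quantities=1),)
    elif atype is ActionType.MAKE_SOLUTION:
        materials = tuple(_random_mention(rng, 1) for _ in range(rng.randrange(2, 4)))
    elif atype is ActionType.PARTITION:
        materials = (_random_mention(rng, 0), _random_mention(rng, 0))
    if atype is ActionType.PH and rng.random() < 0.8:
        cond["ph_value"] = rng.choice(_PH_VALUES)
    if atype is ActionType.SET_TEMPERATURE:
        cond = {"temperature": rng.choice(_TEMPERATURES)}
    if atype is ActionType.FILTER:
        keep = rng.choice([None, KeepPhase.FILTRATE, KeepPhase.PRECIPITATE])
    if atype is ActionType.COLLECT_LAYER:
        keep = rng.choice([KeepPhase.AQUEOUS, KeepPhase.ORGANIC])
    return Action(type=atype, materials=materials, condition=Condition(**cond), keep_phase=keep)


def random_valid_sequence(rng: random.Random, max_len: int = 6) -> ActionSequence:
    return ActionSequence(tuple(random_valid_action(rng) for _ in range(rng.randrange(0, max_len + 1))))


def random_noise_string(rng: random.Random) -> str:
    alphabet = "abcdefgh XYZ();,.°%<>123-–\tAddStirFilter"
    return "".join(rng.choice(alphabet) for _ in range(rng.randrange(0, 80)))


@pytest.fixture(scope="session")
def pools():
    return generate_pools(seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(seed=3, n_samples=200))
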