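"""Synthetic procedure sentences with exact ground-truth actions.

A seeded grammar generates patent-style single-reaction-step sentences —
additions with parenthesized quantities, stirring/temperature/duration
phrases, work-up chains and yield statements — jointly with their action
sequences, so the ground truth is exact by construction.  Template
frequencies default to the shape seen in patent corpora: addition, stirring
and concentration are the most common operations, while recrystallization,
microwaving and sonication are rare.

Compound names are syntactic stand-ins (plausible-looking, not necessarily
real chemistry).  A ``noise`` mode adds sentences with out-of-lexicon verbs
(ground truth ``InvalidAction``) and typos, to exercise robustness rather
than correctness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .actions import (
    SLN,
    Action,
    ActionSequence,
    ActionType,
    ChemicalMention,
    Condition,
    KeepPhase,
    mention,
)
from .augment import SubstitutionPools
from .corpus import PairedSample, SampleSource

# ---------------------------------------------------------------------------
# Entity vocabulary
# ---------------------------------------------------------------------------

_CATIONS = ["sodium", "potassium", "lithium", "calcium", "ammonium", "cesium"]
_ANIONS = [
    "acetate",
    "carbonate",
    "bicarbonate",
    "chloride",
    "hydroxide",
    "borohydride",
    "sulfate",
    "methoxide",
    "iodide",
    "tert-butoxide",
]
_SUBSTITUENTS = [
    "2-chloro",
    "3-bromo",
    "4-fluoro",
    "2,4-dichloro",
    "4-methoxy",
    "3-nitro",
    "2-methyl",
    "4-cyano",
]
_CORES = [
    "aniline",
    "phenol",
    "benzaldehyde",
    "benzoic acid",
    "toluene",
    "pyridine",
    "benzamide",
    "acetophenone",
]
_ESTER_HEADS = ["methyl", "ethyl", "tert-butyl", "benzyl", "isopropyl"]
_ESTER_TAILS = [
    "benzoate",
    "acetate",
    "propanoate",
    "butanoate",
    "glycinate",
    "carbamate",
]

_SOLVENTS = [
    "dichloromethane",
    "methanol",
    "ethanol",
    "ethyl acetate",
    "toluene",
    "tetrahydrofuran",
    "acetonitrile",
    "diethyl ether",
    "acetone",
    "hexane",
]
_DESICCANTS = [
    "sodium sulfate",
    "magnesium sulfate",
    "anhydrous sodium sulfate",
    "anhydrous magnesium sulfate",
]
_WASH_LIQUORS = [
    "water",
    "brine",
    "saturated sodium bicarbonate",
    "saturated ammonium chloride",
]
_QUENCHERS = ["water", "saturated ammonium chloride", "ice water", "methanol"]
_ACIDS_BASES = [
    "1 M hydrochloric acid",
    "10% hydrochloric acid",
    "2 M sodium hydroxide",
    "saturated sodium bicarbonate",
    "acetic acid",
]
_DURATIONS = [
    "30 min",
    "1 h",
    "2 h",
    "3 h",
    "5 h",
    "12 h",
    "16 h",
    "45 min",
    "90 min",
    "10 min",
    "overnight",
    "4 h",
]
_TEMPERATURES = [
    "0 °C",
    "room temperature",
    "50 °C",
    "80 °C",
    "100 °C",
    "120 °C",
    "-78 °C",
    "25 °C",
    "60 °C",
    "-10 °C",
    "40 °C",
    "reflux temperature",
]
_GASES = ["nitrogen", "argon"]
_PH_VALUES = [1.0, 1.5, 2.0, 3.0, 6.5, 7.0, 8.0, 9.0, 10.0]

_NOISE_VERBS = ["vortexed", "lyophilized", "centrifuged", "blorbified", "decanted"]

_NON_ENGLISH = [
    "Das Gemisch wurde über Nacht bei Raumtemperatur gerührt.",
    "La solución se agitó durante dos horas a temperatura ambiente.",
    "Le mélange a été chauffé pendant trois heures.",
]


class _Entities:
    """Deterministic entity factory over the pools above."""

    def __init__(self, rng: random.Random):
        self.rng = rng

    def compound(self) -> str:
        form = self.rng.randrange(3)
        if form == 0:
            return f"{self.rng.choice(_CATIONS)} {self.rng.choice(_ANIONS)}"
        if form == 1:
            return f"{self.rng.choice(_SUBSTITUENTS)}{self.rng.choice(_CORES)}"
        return f"{self.rng.choice(_ESTER_HEADS)} {self.rng.choice(_ESTER_TAILS)}"

    def solvent(self) -> str:
        return self.rng.choice(_SOLVENTS)

    def mass(self) -> str:
        return f"{self.rng.randrange(1, 250) / 10:g} g"

    def volume(self) -> str:
        return f"{self.rng.randrange(1, 60) * 5} mL"

    def amount(self) -> str:
        return f"{self.rng.randrange(1, 900) / 10:g} mmol"

    def quantity(self) -> str:
        return self.rng.choice((self.mass, self.volume, self.amount))()

    def duration(self) -> str:
        return self.rng.choice(_DURATIONS)

    def temperature(self) -> str:
        t = self.rng.choice(_TEMPERATURES)
        return t if t != "reflux temperature" else self.rng.choice(_TEMPERATURES[:-1])

    def gas(self) -> str:
        return self.rng.choice(_GASES)


def _cap(name: str) -> str:
    return name[0].upper() + name[1:] if name[:1].isalpha() else name


# ---------------------------------------------------------------------------
# Templates: each returns (sentence, actions)
# ---------------------------------------------------------------------------

Template = Callable[[random.Random, _Entities], tuple[str, list[Action]]]
_TEMPLATES: dict[str, tuple[float, Template]] = {}


def _template(name: str, weight: float):
    def register(fn: Template) -> Template:
        _TEMPLATES[name] = (weight, fn)
        return fn

    return register


@_template("add_simple", 18.0)
def _t_add_simple(rng, ent):
    name = ent.compound()
    q1, q2 = ent.mass(), ent.amount()
    dropwise = rng.random() < 0.25
    temp = ent.temperature() if rng.random() < 0.4 else None
    gas = ent.gas() if rng.random() < 0.2 else None
    s = f"{_cap(name)} ({q1}, {q2}) was added"
    if dropwise:
        s += " dropwise"
    if temp:
        s += f" at {temp}"
    if gas:
        s += f" under {gas}"
    s += "."
    action = Action(
        type=ActionType.ADD,
        materials=(mention(name, q1, q2),),
        condition=Condition(temperature=temp, atmosphere=gas, dropwise=dropwise),
    )
    return s, [action]


@_template("add_to_mixture", 7.0)
def _t_add_to_mixture(rng, ent):
    name, q = ent.compound(), ent.quantity()
    if rng.random() < 0.5:
        s = f"To the reaction mixture was added {name} ({q})."
    else:
        s = f"{_cap(name)} ({q}) was added to the mixture."
    return s, [Action(type=ActionType.ADD, materials=(mention(name, q),))]


@_template("dissolve", 8.0)
def _t_dissolve(rng, ent):
    name, qm = ent.compound(), ent.mass()
    solvent, qv = ent.solvent(), ent.volume()
    gas = ent.gas() if rng.random() < 0.25 else None
    s = f"{_cap(name)} ({qm}) was dissolved in {solvent} ({qv})"
    if gas:
        s += f" under {gas} atmosphere"
    s += "."
    actions = [
        Action(type=ActionType.ADD, materials=(mention(name, qm),)),
        Action(
            type=ActionType.ADD,
            materials=(mention(solvent, qv),),
            condition=Condition(atmosphere=gas),
        ),
    ]
    return s, actions


@_template("makesolution", 6.0)
def _t_makesolution(rng, ent):
    a, qa = ent.compound(), ent.mass()
    solvent, qs = ent.solvent(), ent.volume()
    b, qb = ent.compound(), ent.amount()
    temp = ent.temperature() if rng.random() < 0.5 else None
    s = f"To a solution of {a} ({qa}) in {solvent} ({qs}) was added {b} ({qb})"
    if temp:
        s += f" at {temp}"
    s += "."
    actions = [
        Action(
            type=ActionType.MAKE_SOLUTION,
            materials=(mention(a, qa), mention(solvent, qs)),
        ),
        Action(type=ActionType.ADD, materials=(ChemicalMention(name=SLN),)),
        Action(
            type=ActionType.ADD,
            materials=(mention(b, qb),),
            condition=Condition(temperature=temp),
        ),
    ]
    return s, actions


@_template("stir", 13.0)
def _t_stir(rng, ent):
    dur, temp = ent.duration(), ent.temperature()
    gas = ent.gas() if rng.random() < 0.2 else None
    s = f"The reaction mixture was stirred for {dur} at {temp}"
    if gas:
        s += f" under {gas}"
    s += "."
    return s, [
        Action(
            type=ActionType.STIR,
            condition=Condition(duration=dur, temperature=temp, atmosphere=gas),
        )
    ]


@_template("heat_stir", 5.0)
def _t_heat_stir(rng, ent):
    temp, dur = ent.temperature(), ent.duration()
    s = f"The mixture was heated at {temp} for {dur}."
    return s, [
        Action(type=ActionType.STIR, condition=Condition(duration=dur, temperature=temp))
    ]


@_template("settemp", 6.0)
def _t_settemp(rng, ent):
    verb = rng.choice(["cooled", "warmed", "heated"])
    temp = ent.temperature()
    s = f"The mixture was {verb} to {temp}."
    return s, [Action(type=ActionType.SET_TEMPERATURE, condition=Condition(temperature=temp))]


@_template("concentrate", 9.0)
def _t_concentrate(rng, ent):
    s = rng.choice(
        [
            "The reaction mixture was concentrated in vacuo.",
            "The mixture was concentrated under reduced pressure.",
            "The solvent was removed under reduced pressure.",
            "The solvent was evaporated in vacuo.",
        ]
    )
    return s, [Action(type=ActionType.CONCENTRATE)]


@_template("wash", 7.0)
def _t_wash(rng, ent):
    w1 = rng.choice(_WASH_LIQUORS)
    form = rng.randrange(3)
    if form == 0:
        s = f"The mixture was washed with {w1}."
        actions = [Action(type=ActionType.WASH, materials=(mention(w1),))]
    elif form == 1:
        w2 = rng.choice([w for w in _WASH_LIQUORS if w != w1])
        s = f"The mixture was washed with {w1} and {w2}."
        actions = [
            Action(type=ActionType.WASH, materials=(mention(w1),)),
            Action(type=ActionType.WASH, materials=(mention(w2),)),
        ]
    else:
        s = f"The mixture was washed twice with {w1}."
        actions = [
            Action(
                type=ActionType.WASH,
                materials=(mention(w1),),
                condition=Condition(repetitions=2),
            )
        ]
    return s, actions


@_template("dry_solution", 6.0)
def _t_dry_solution(rng, ent):
    desiccant = rng.choice(_DESICCANTS)
    tail = rng.random() < 0.4
    s = f"The organic layer was dried over {desiccant}"
    actions = [
        Action(type=ActionType.COLLECT_LAYER, keep_phase=KeepPhase.ORGANIC),
        Action(type=ActionType.DRY_SOLUTION, materials=(mention(desiccant),)),
    ]
    if tail:
        s += " and concentrated in vacuo"
        actions.append(Action(type=ActionType.CONCENTRATE))
    s += "."
    return s, actions


@_template("filter", 6.0)
def _t_filter(rng, ent):
    form = rng.randrange(3)
    if form == 0:
        return "The mixture was filtered.", [Action(type=ActionType.FILTER)]
    if form == 1:
        return (
            "The mixture was filtered and concentrated in vacuo.",
            [
                Action(type=ActionType.FILTER, keep_phase=KeepPhase.FILTRATE),
                Action(type=ActionType.CONCENTRATE),
            ],
        )
    return (
        "The precipitate was filtered off.",
        [Action(type=ActionType.FILTER, keep_phase=KeepPhase.PRECIPITATE)],
    )


@_template("extract", 5.0)
def _t_extract(rng, ent):
    solvent, qv = ent.solvent(), ent.volume()
    reps = rng.random() < 0.3
    s = "The aqueous layer was extracted "
    if reps:
        s += f"three times with {solvent} ({qv})."
    else:
        s += f"with {solvent} ({qv})."
    actions = [
        Action(type=ActionType.COLLECT_LAYER, keep_phase=KeepPhase.AQUEOUS),
        Action(
            type=ActionType.EXTRACT,
            materials=(mention(solvent, qv),),
            condition=Condition(repetitions=3 if reps else None),
        ),
    ]
    return s, actions


@_template("quench", 4.0)
def _t_quench(rng, ent):
    quencher = rng.choice(_QUENCHERS)
    temp = ent.temperature() if rng.random() < 0.3 else None
    s = f"The reaction was quenched with {quencher}"
    if temp:
        s += f" at {temp}"
    s += "."
    return s, [
        Action(
            type=ActionType.QUENCH,
            materials=(mention(quencher),),
            condition=Condition(temperature=temp),
        )
    ]


@_template("purify_yield", 6.0)
def _t_purify_yield(rng, ent):
    name, qm = ent.compound(), ent.mass()
    pct = rng.randrange(35, 99)
    s = (
        "The residue was purified by column chromatography to give "
        f"{name} ({qm}, {pct}%)."
    )
    actions = [
        Action(type=ActionType.PURIFY),
        Action(type=ActionType.YIELD, materials=(mention(name, qm, f"{pct}%"),)),
    ]
    return s, actions


@_template("wait", 3.0)
def _t_wait(rng, ent):
    dur = ent.duration()
    if rng.random() < 0.5:
        s = f"The mixture was allowed to stand for {dur}."
        return s, [Action(type=ActionType.WAIT, condition=Condition(duration=dur))]
    name, q = ent.compound(), ent.quantity()
    s = f"After {dur}, {name} ({q}) was added."
    return s, [
        Action(type=ActionType.WAIT, condition=Condition(duration=dur)),
        Action(type=ActionType.ADD, materials=(mention(name, q),)),
    ]


@_template("reflux", 3.0)
def _t_reflux(rng, ent):
    dur = ent.duration()
    s = rng.choice(
        [
            f"The mixture was heated to reflux for {dur}.",
            f"The solution was refluxed for {dur}.",
        ]
    )
    return s, [Action(type=ActionType.REFLUX, condition=Condition(duration=dur))]


@_template("ph", 2.0)
def _t_ph(rng, ent):
    value = rng.choice(_PH_VALUES)
    agent = rng.choice(_ACIDS_BASES)
    shown = str(int(value)) if float(value).is_integer() else f"{value:g}"
    s = f"The mixture was adjusted to pH {shown} with {agent}."
    return s, [
        Action(
            type=ActionType.PH,
            materials=(mention(agent),),
            condition=Condition(ph_value=float(value)),
        )
    ]


@_template("partition", 2.0)
def _t_partition(rng, ent):
    solvent = ent.solvent()
    s = f"The residue was partitioned between water and {solvent}."
    return s, [
        Action(
            type=ActionType.PARTITION,
            materials=(mention("water"), mention(solvent)),
        )
    ]


@_template("phasesep", 2.0)
def _t_phasesep(rng, ent):
    return "The layers were separated.", [Action(type=ActionType.PHASE_SEPARATION)]


@_template("collect_layer", 2.0)
def _t_collect_layer(rng, ent):
    s = "The organic layer was separated."
    return s, [
        Action(type=ActionType.PHASE_SEPARATION),
        Action(type=ActionType.COLLECT_LAYER, keep_phase=KeepPhase.ORGANIC),
    ]


@_template("recrystallize", 1.0)
def _t_recrystallize(rng, ent):
    solvent = ent.solvent()
    s = f"The solid was recrystallized from {solvent}."
    return s, [Action(type=ActionType.RECRYSTALLIZE, materials=(mention(solvent),))]


@_template("triturate", 1.0)
def _t_triturate(rng, ent):
    solvent = ent.solvent()
    s = f"The residue was triturated with {solvent}."
    return s, [Action(type=ActionType.TRITURATE, materials=(mention(solvent),))]


@_template("drysolid", 1.0)
def _t_drysolid(rng, ent):
    temp = ent.temperature()
    s = f"The solid was dried in vacuo at {temp}."
    return s, [Action(type=ActionType.DRY_SOLID, condition=Condition(temperature=temp))]


@_template("degas", 1.0)
def _t_degas(rng, ent):
    dur, gas = ent.duration(), ent.gas()
    s = f"The solution was purged with {gas} for {dur}."
    return s, [
        Action(type=ActionType.DEGAS, condition=Condition(duration=dur, atmosphere=gas))
    ]


@_template("microwave", 1.0)
def _t_microwave(rng, ent):
    temp, dur = ent.temperature(), ent.duration()
    s = f"The mixture was heated in a microwave at {temp} for {dur}."
    return s, [
        Action(type=ActionType.MICROWAVE, condition=Condition(duration=dur, temperature=temp))
    ]


@_template("sonicate", 1.0)
def _t_sonicate(rng, ent):
    dur = ent.duration()
    s = f"The mixture was sonicated for {dur}."
    return s, [Action(type=ActionType.SONICATE, condition=Condition(duration=dur))]


@_template("workup_chain", 4.0)
def _t_workup_chain(rng, ent):
    desiccant = rng.choice(_DESICCANTS)
    quencher = rng.choice(_QUENCHERS)
    s = (
        f"The reaction mixture was quenched with {quencher}, washed with brine, "
        f"dried over {desiccant}, filtered and concentrated in vacuo."
    )
    actions = [
        Action(type=ActionType.QUENCH, materials=(mention(quencher),)),
        Action(type=ActionType.WASH, materials=(mention("brine"),)),
        Action(type=ActionType.DRY_SOLUTION, materials=(mention(desiccant),)),
        Action(type=ActionType.FILTER, keep_phase=KeepPhase.FILTRATE),
        Action(type=ActionType.CONCENTRATE),
    ]
    return s, actions


@_template("followed_by", 2.0)
def _t_followed_by(rng, ent):
    name, qv, qa = ent.compound(), ent.volume(), ent.amount()
    dur, temp = ent.duration(), ent.temperature()
    s = (
        f"{_cap(name)} ({qv}, {qa}) was added to the reaction mixture "
        f"followed by stirring for {dur} at {temp}."
    )
    actions = [
        Action(type=ActionType.ADD, materials=(mention(name, qv, qa),)),
        Action(type=ActionType.STIR, condition=Condition(duration=dur, temperature=temp)),
    ]
    return s, actions


@_template("noaction", 1.5)
def _t_noaction(rng, ent):
    a = rng.randrange(60, 90) / 10
    b = a + rng.randrange(1, 5) / 10
    n = rng.randrange(100, 600)
    t = rng.randrange(80, 220)
    s = rng.choice(
        [
            f"1H NMR (400 MHz, CDCl3): δ {a:.2f}-{b:.2f} (m, {rng.randrange(1, 9)}H).",
            f"LCMS: m/z {n} (M+H).",
            f"m.p. {t}-{t + 2} °C.",
        ]
    )
    return s, [Action(type=ActionType.NO_ACTION)]


@_template("followother", 0.7)
def _t_followother(rng, ent):
    s = f"The title compound was prepared as described in Example {rng.randrange(1, 40)}."
    return s, [Action(type=ActionType.FOLLOW_OTHER_PROCEDURE)]


@_template("otherlang", 0.3)
def _t_otherlang(rng, ent):
    return rng.choice(_NON_ENGLISH), [Action(type=ActionType.OTHER_LANGUAGE)]


#: Noise-mode templates (out-of-lexicon operations → InvalidAction).
def _t_invalid(rng: random.Random, ent: _Entities) -> tuple[str, list[Action]]:
    verb = rng.choice(_NOISE_VERBS)
    s = f"The mixture was {verb} for {ent.duration()}."
    return s, [Action(type=ActionType.INVALID_ACTION)]


def default_template_weights() -> dict[str, float]:
    return {name: weight for name, (weight, _) in _TEMPLATES.items()}


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-corpus generator.

    The same config and seed always produce a byte-identical corpus.
    """

    seed: int = 0
    n_samples: int = 1000
    template_weights: Optional[dict[str, float]] = None
    noise: bool = False
    invalid_prob: float = 0.15  # noise mode: out-of-lexicon verb sentences
    typo_prob: float = 0.10  # noise mode: character swap in one word

    def resolved_weights(self) -> tuple[list[str], list[float]]:
        weights = dict(default_template_weights())
        if self.template_weights:
            unknown = set(self.template_weights) - set(weights)
            if unknown:
                raise ValueError(f"unknown template names: {sorted(unknown)}")
            weights.update(self.template_weights)
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("template weights must be non-negative and not all zero")
        names = sorted(weights)
        return names, [weights[n] for n in names]


def _apply_typo(sentence: str, rng: random.Random) -> str:
    words = sentence.split(" ")
    candidates = [i for i, w in enumerate(words) if len(w) >= 5 and w.isalpha()]
    if not candidates:
        return sentence
    i = rng.choice(candidates)
    w = words[i]
    j = rng.randrange(len(w) - 1)
    words[i] = w[:j] + w[j + 1] + w[j] + w[j + 2 :]
    return " ".join(words)


def generate_corpus(config: GeneratorConfig) -> list[PairedSample]:
    """Generate paired samples; ground truth exact by construction."""
    rng = random.Random(config.seed)
    ent = _Entities(rng)
    names, weights = config.resolved_weights()
    out: list[PairedSample] = []
    for _ in range(config.n_samples):
        if config.noise and rng.random() < config.invalid_prob:
            sentence, actions = _t_invalid(rng, ent)
        else:
            name = rng.choices(names, weights=weights, k=1)[0]
            sentence, actions = _TEMPLATES[name][1](rng, ent)
            if config.noise and rng.random() < config.typo_prob:
                sentence = _apply_typo(sentence, rng)
        out.append(
            PairedSample(
                sentence=sentence,
                actions=ActionSequence(tuple(actions)),
                source=SampleSource.SYNTHETIC,
            )
        )
    return out


#: Flagship worked example: a typical patent procedure (one reaction step,
#: reductive amination with full work-up) and its reference action sequence.
EXAMPLE_PROCEDURE = (
    "To a suspension of methyl 3-7-amino-2-[(2,4-dichlorophenyl)(hydroxy)"
    "methyl]-1H-benzimidazol-1-ylpropanoate (6.00 g, 14.7 mmol) and acetic "
    "acid (7.4 mL) in methanol (147 mL) was added acetaldehyde (4.95 mL, "
    "88.2 mmol) at 0 °C. After 30 min, sodium acetoxyborohydride (18.7 g, "
    "88.2 mmol) was added. After 2 h, the reaction mixture was quenched "
    "with water, concentrated in vacuo, diluted with ethyl acetate, washed "
    "with aqueous sodium hydroxide (1 M) and brine, dried over sodium "
    "sulfate, filtered and concentrated in vacuo. The residue was purified "
    "by column chromatography on silica gel eluting with a 10–30% ethyl "
    "acetate/n-hexane gradient mixture to give the title compound as a "
    "colorless amorphous (6.30 g, 13.6 mmol, 92%)."
)

EXAMPLE_ACTION_STRING = (
    "MakeSolution with methyl 3-7-amino-2-[(2,4-dichlorophenyl)(hydroxy)"
    "methyl]-1H-benzimidazol-1-ylpropanoate (6.00 g, 14.7 mmol) and acetic "
    "acid (7.4 mL) and methanol (147 mL); Add SLN; Add acetaldehyde "
    "(4.95 mL, 88.2 mmol) at 0 °C; Wait 30 min; Add sodium "
    "acetoxyborohydride (18.7 g, 88.2 mmol); Wait 2 h; Quench with water; "
    "Concentrate; Add ethyl acetate; Wash with aqueous sodium hydroxide "
    "(1 M); Wash with brine; DrySolution over sodium sulfate; Filter keep "
    "filtrate; Concentrate; Purify; Yield title compound (6.30 g, "
    "13.6 mmol, 92%)"
)


def generate_pools(seed: int = 0) -> SubstitutionPools:
    """Deterministic substitution pools for augmentation and tests."""
    rng = random.Random(seed)
    ent = _Entities(rng)
    compounds = sorted({ent.compound() for _ in range(80)}) + _SOLVENTS
    quantities = sorted({ent.quantity() for _ in range(60)})
    return SubstitutionPools(
        compounds=tuple(compounds),
        quantities=tuple(quantities),
        durations=tuple(_DURATIONS),
        temperatures=tuple(t for t in _TEMPERATURES if t != "reflux temperature"),
    )
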