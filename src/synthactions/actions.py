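"""Structured synthesis actions.

A synthesis *action* is one operation of conventional batch organic
chemistry (add a reagent, stir, filter, ...) together with a typed set of
properties (materials, temperature, duration, atmosphere, ...).  An ordered
list of actions — an :class:`ActionSequence` — is the machine-readable form
of one experimental-procedure sentence or of a whole procedure.

The action vocabulary is a closed set of 28 types.  24 correspond to real
laboratory operations; four (``FollowOtherProcedure``, ``InvalidAction``,
``OtherLanguage``, ``NoAction``) flag text that cannot be converted into
laboratory operations.  Each type admits a fixed set of properties, frozen
in :data:`ALLOWED_PROPERTIES` (schema version :data:`SCHEMA_VERSION`);
:func:`validate_action` checks an action against that table and reports
violations as data, never as exceptions.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

SCHEMA_VERSION = "1.0"

#: Reserved compound name referring to the product of the most recent
#: MakeSolution action.
SLN = "SLN"


class ActionType(str, enum.Enum):
    """The closed set of 28 action types."""

    ADD = "Add"
    COLLECT_LAYER = "CollectLayer"
    CONCENTRATE = "Concentrate"
    DEGAS = "Degas"
    DRY_SOLID = "DrySolid"
    DRY_SOLUTION = "DrySolution"
    EXTRACT = "Extract"
    FILTER = "Filter"
    MAKE_SOLUTION = "MakeSolution"
    MICROWAVE = "Microwave"
    PARTITION = "Partition"
    PH = "PH"
    PHASE_SEPARATION = "PhaseSeparation"
    PURIFY = "Purify"
    QUENCH = "Quench"
    RECRYSTALLIZE = "Recrystallize"
    REFLUX = "Reflux"
    SET_TEMPERATURE = "SetTemperature"
    SONICATE = "Sonicate"
    STIR = "Stir"
    TRITURATE = "Triturate"
    WAIT = "Wait"
    WASH = "Wash"
    YIELD = "Yield"
    FOLLOW_OTHER_PROCEDURE = "FollowOtherProcedure"
    INVALID_ACTION = "InvalidAction"
    OTHER_LANGUAGE = "OtherLanguage"
    NO_ACTION = "NoAction"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Types that do not correspond to laboratory operations.
NON_LABORATORY_TYPES = frozenset(
    {
        ActionType.FOLLOW_OTHER_PROCEDURE,
        ActionType.INVALID_ACTION,
        ActionType.OTHER_LANGUAGE,
        ActionType.NO_ACTION,
    }
)

#: Case-insensitive lookup of canonical action names.
_NAME_LOOKUP = {t.value.lower(): t for t in ActionType}


def action_type_from_name(name: str) -> ActionType:
    """Resolve an action-type name case-insensitively.

    Raises ``KeyError`` for names outside the closed set.
    """
    try:
        return _NAME_LOOKUP[name.strip().lower()]
    except KeyError:
        raise KeyError(f"unknown action type: {name!r}") from None


class QuantityKind(str, enum.Enum):
    MASS = "mass"
    VOLUME = "volume"
    AMOUNT = "amount"
    CONCENTRATION = "concentration"
    EQUIVALENTS = "equivalents"
    OTHER = "other"


_UNIT_KINDS = {
    QuantityKind.MASS: {"g", "mg", "kg", "µg", "ug"},
    QuantityKind.VOLUME: {"l", "ml", "µl", "ul", "cm3"},
    QuantityKind.AMOUNT: {"mol", "mmol", "µmol", "umol", "mole", "moles"},
    QuantityKind.CONCENTRATION: {"m", "n", "%", "wt%"},
    QuantityKind.EQUIVALENTS: {"equiv", "equivalents", "eq", "eq."},
}


def infer_quantity_kind(raw: str) -> QuantityKind:
    """Infer the kind of a raw quantity string from its unit token."""
    token = raw.strip().rstrip(".")
    m = re.search(r"([A-Za-zµ%]+%?)\s*$", token)
    if m:
        unit = m.group(1).lower()
        for kind, units in _UNIT_KINDS.items():
            if unit in units:
                return kind
    if token.endswith("%"):
        return QuantityKind.CONCENTRATION
    return QuantityKind.OTHER


@dataclass(frozen=True)
class Quantity:
    """A raw quantity string such as ``"6.00 g"`` with its inferred kind."""

    raw: str
    kind: QuantityKind = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.raw or not self.raw.strip():
            raise ValueError("Quantity.raw must be non-empty")
        if self.kind is None:
            object.__setattr__(self, "kind", infer_quantity_kind(self.raw))


class MentionRole(str, enum.Enum):
    SUBJECT = "subject"
    DIRECT_OBJECT = "direct_object"
    OBLIQUE = "oblique"
    SOLVENT = "solvent"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ChemicalMention:
    """A compound name with its attached raw quantities and sentence role."""

    name: str
    quantities: tuple[Quantity, ...] = ()
    role: MentionRole = MentionRole.UNKNOWN

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("ChemicalMention.name must be non-empty")
        object.__setattr__(self, "quantities", tuple(self.quantities))


def mention(name: str, *quantities: str, role: MentionRole = MentionRole.UNKNOWN) -> ChemicalMention:
    """Convenience constructor: ``mention("water", "10 mL")``."""
    return ChemicalMention(name=name, quantities=tuple(Quantity(q) for q in quantities), role=role)


@dataclass(frozen=True)
class Condition:
    """Optional operation conditions attached to an action."""

    temperature: Optional[str] = None
    duration: Optional[str] = None
    atmosphere: Optional[str] = None
    ph_value: Optional[float] = None
    dropwise: bool = False
    repetitions: Optional[int] = None

    def populated_fields(self) -> set[str]:
        out = set()
        if self.temperature is not None:
            out.add("temperature")
        if self.duration is not None:
            out.add("duration")
        if self.atmosphere is not None:
            out.add("atmosphere")
        if self.ph_value is not None:
            out.add("ph_value")
        if self.dropwise:
            out.add("dropwise")
        if self.repetitions is not None:
            out.add("repetitions")
        return out

    def is_empty(self) -> bool:
        return not self.populated_fields()


class KeepPhase(str, enum.Enum):
    FILTRATE = "filtrate"
    PRECIPITATE = "precipitate"
    AQUEOUS = "aqueous"
    ORGANIC = "organic"


@dataclass(frozen=True)
class Action:
    """One synthesis step: a type plus its populated properties."""

    type: ActionType
    materials: tuple[ChemicalMention, ...] = ()
    condition: Condition = field(default_factory=Condition)
    keep_phase: Optional[KeepPhase] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "materials", tuple(self.materials))

    def populated_fields(self) -> set[str]:
        out = self.condition.populated_fields()
        if self.materials:
            out.add("materials")
        if self.keep_phase is not None:
            out.add("keep_phase")
        return out

    def with_condition(self, **kwargs) -> "Action":
        return replace(self, condition=replace(self.condition, **kwargs))


@dataclass(frozen=True)
class ActionSequence:
    """An ordered (possibly empty) list of actions."""

    actions: tuple[Action, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))

    def __len__(self) -> int:
        return len(self.actions)

    def __iter__(self) -> Iterator[Action]:
        return iter(self.actions)

    def __getitem__(self, i):
        return self.actions[i]

    def __add__(self, other: "ActionSequence") -> "ActionSequence":
        return ActionSequence(self.actions + tuple(other))

    def types(self) -> list[ActionType]:
        return [a.type for a in self.actions]


# ---------------------------------------------------------------------------
# Allowed-property table (frozen, versioned)
# ---------------------------------------------------------------------------

#: Minimum / maximum number of materials per type (None = unbounded).
#: A zero minimum covers prose that omits the material ("washed and dried").
MATERIAL_ARITY: dict[ActionType, tuple[int, Optional[int]]] = {
    ActionType.ADD: (1, 1),
    ActionType.DRY_SOLUTION: (0, 1),
    ActionType.EXTRACT: (0, 1),
    ActionType.MAKE_SOLUTION: (2, None),
    ActionType.PARTITION: (2, 2),
    ActionType.PH: (0, 1),
    ActionType.QUENCH: (0, 1),
    ActionType.RECRYSTALLIZE: (0, 1),
    ActionType.TRITURATE: (0, 1),
    ActionType.WASH: (0, 1),
    ActionType.YIELD: (1, 1),
}

#: Allowed keep_phase values per type.
KEEP_PHASE_DOMAIN: dict[ActionType, frozenset[KeepPhase]] = {
    ActionType.FILTER: frozenset({KeepPhase.FILTRATE, KeepPhase.PRECIPITATE}),
    ActionType.COLLECT_LAYER: frozenset({KeepPhase.AQUEOUS, KeepPhase.ORGANIC}),
}

#: Allowed property fields per action type.  Reconstructed from the printed
#: example sequences and frozen here; amend together with SCHEMA_VERSION.
ALLOWED_PROPERTIES: dict[ActionType, frozenset[str]] = {
    ActionType.ADD: frozenset({"materials", "temperature", "atmosphere", "dropwise"}),
    ActionType.COLLECT_LAYER: frozenset({"keep_phase"}),
    ActionType.CONCENTRATE: frozenset(),
    ActionType.DEGAS: frozenset({"atmosphere", "duration"}),
    ActionType.DRY_SOLID: frozenset({"duration", "temperature"}),
    ActionType.DRY_SOLUTION: frozenset({"materials"}),
    ActionType.EXTRACT: frozenset({"materials", "repetitions"}),
    ActionType.FILTER: frozenset({"keep_phase"}),
    ActionType.MAKE_SOLUTION: frozenset({"materials"}),
    ActionType.MICROWAVE: frozenset({"duration", "temperature"}),
    ActionType.PARTITION: frozenset({"materials"}),
    ActionType.PH: frozenset({"materials", "ph_value"}),
    ActionType.PHASE_SEPARATION: frozenset(),
    ActionType.PURIFY: frozenset(),
    ActionType.QUENCH: frozenset({"materials", "temperature", "dropwise"}),
    ActionType.RECRYSTALLIZE: frozenset({"materials"}),
    ActionType.REFLUX: frozenset({"duration", "atmosphere"}),
    ActionType.SET_TEMPERATURE: frozenset({"temperature"}),
    ActionType.SONICATE: frozenset({"duration", "temperature"}),
    ActionType.STIR: frozenset({"duration", "temperature", "atmosphere"}),
    ActionType.TRITURATE: frozenset({"materials"}),
    ActionType.WAIT: frozenset({"duration", "temperature"}),
    ActionType.WASH: frozenset({"materials", "repetitions"}),
    ActionType.YIELD: frozenset({"materials"}),
    ActionType.FOLLOW_OTHER_PROCEDURE: frozenset(),
    ActionType.INVALID_ACTION: frozenset(),
    ActionType.OTHER_LANGUAGE: frozenset(),
    ActionType.NO_ACTION: frozenset(),
}


def allowed_properties(action_type: ActionType | str) -> frozenset[str]:
    """Return the closed set of property fields allowed for a type.

    Accepts an :class:`ActionType` or a (case-insensitive) type name;
    raises ``KeyError`` on a name outside the schema.
    """
    if isinstance(action_type, str):
        action_type = action_type_from_name(action_type)
    return ALLOWED_PROPERTIES[action_type]


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of :func:`validate_action`; violations are data."""

    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_action(action: Action) -> ValidationResult:
    """Check an action's populated properties against the allowed table."""
    allowed = ALLOWED_PROPERTIES[action.type]
    violations: list[str] = []
    for f in sorted(action.populated_fields()):
        if f not in allowed:
            violations.append(f"{f} not allowed on {action.type.value}")
    if "materials" in allowed:
        lo, hi = MATERIAL_ARITY.get(action.type, (0, None))
        n = len(action.materials)
        if n < lo:
            violations.append(
                f"{action.type.value} requires at least {lo} materials, got {n}"
            )
        if hi is not None and n > hi:
            violations.append(
                f"{action.type.value} admits at most {hi} materials, got {n}"
            )
    if action.keep_phase is not None and "keep_phase" in allowed:
        domain = KEEP_PHASE_DOMAIN[action.type]
        if action.keep_phase not in domain:
            names = "/".join(sorted(p.value for p in domain))
            violations.append(
                f"keep_phase {action.keep_phase.value} invalid for "
                f"{action.type.value} (allowed: {names})"
            )
    ph = action.condition.ph_value
    if ph is not None and "ph_value" in allowed and not (0.0 <= ph <= 14.0):
        violations.append(f"ph_value {ph} outside [0, 14]")
    return ValidationResult(tuple(violations))


def validate_sequence(seq: ActionSequence) -> ValidationResult:
    """Validate every action; also check the SLN ordering invariant."""
    violations: list[str] = []
    seen_makesolution = False
    for i, a in enumerate(seq):
        for v in validate_action(a).violations:
            violations.append(f"action {i + 1}: {v}")
        if a.type is ActionType.MAKE_SOLUTION:
            seen_makesolution = True
        elif any(m.name == SLN for m in a.materials) and not seen_makesolution:
            violations.append(f"action {i + 1}: SLN used before any MakeSolution")
    return ValidationResult(tuple(violations))


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def quantity_to_dict(q: Quantity) -> dict:
    return {"raw": q.raw, "kind": q.kind.value}


def mention_to_dict(m: ChemicalMention) -> dict:
    return {
        "name": m.name,
        "quantities": [quantity_to_dict(q) for q in m.quantities],
        "role": m.role.value,
    }


def action_to_dict(a: Action) -> dict:
    out: dict = {"type": a.type.value}
    if a.materials:
        out["materials"] = [mention_to_dict(m) for m in a.materials]
    c = a.condition
    for f in ("temperature", "duration", "atmosphere"):
        v = getattr(c, f)
        if v is not None:
            out[f] = v
    if c.ph_value is not None:
        out["ph_value"] = c.ph_value
    if c.dropwise:
        out["dropwise"] = True
    if c.repetitions is not None:
        out["repetitions"] = c.repetitions
    if a.keep_phase is not None:
        out["keep_phase"] = a.keep_phase.value
    return out


def action_from_dict(d: dict) -> Action:
    materials = tuple(
        ChemicalMention(
            name=m["name"],
            quantities=tuple(
                Quantity(q["raw"], QuantityKind(q["kind"])) for q in m.get("quantities", ())
            ),
            role=MentionRole(m.get("role", "unknown")),
        )
        for m in d.get("materials", ())
    )
    condition = Condition(
        temperature=d.get("temperature"),
        duration=d.get("duration"),
        atmosphere=d.get("atmosphere"),
        ph_value=d.get("ph_value"),
        dropwise=bool(d.get("dropwise", False)),
        repetitions=d.get("repetitions"),
    )
    keep = d.get("keep_phase")
    return Action(
        type=action_type_from_name(d["type"]),
        materials=materials,
        condition=condition,
        keep_phase=KeepPhase(keep) if keep is not None else None,
    )


def sequence_to_dict(seq: ActionSequence) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "actions": [action_to_dict(a) for a in seq],
    }


def sequence_from_dict(d: dict) -> ActionSequence:
    return ActionSequence(tuple(action_from_dict(a) for a in d.get("actions", ())))


def sequence_to_json(seq: ActionSequence) -> str:
    return json.dumps(sequence_to_dict(seq), ensure_ascii=False)


def sequence_from_json(s: str) -> ActionSequence:
    return sequence_from_dict(json.loads(s))
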