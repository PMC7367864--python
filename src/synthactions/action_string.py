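"""Bijective textual representation of action sequences.

An action string is a single line of semicolon-separated clauses, one per
action, e.g.::

    MakeSolution with aluminum chloride (23 g) and dichloroethane (30 mL);
    Add SLN; SetTemperature 50 °C

Each clause starts with the action-type name followed by its properties in
a fixed keyword grammar (``with`` / ``and`` / ``over`` / ``from`` / ``at`` /
``under`` / ``for`` / ``to pH`` / ``keep`` / ``x N`` / ``dropwise``).  The
representation is the target language of the sequence-to-sequence model, so
:func:`serialize` and :func:`parse` are mutual inverses on the canonical
form, action names are matched case-insensitively on input, and a trailing
period is accepted on input and never emitted on output.

Parsing arbitrary text never crashes: :func:`try_parse` reports failures as
a structured :class:`ParseFailure` (clause index + offending token), which
is what the validity metric counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .actions import (
    Action,
    ActionSequence,
    ActionType,
    ChemicalMention,
    Condition,
    KeepPhase,
    Quantity,
    action_type_from_name,
    validate_action,
)

CLAUSE_SEPARATOR = "; "

# A parenthesized group is a quantity group iff every comma-separated part
# looks like a quantity (number + unit / percentage / concentration).  This
# keeps parentheses inside chemical names, e.g. "(2,4-dichlorophenyl)", out.
_QTY_TOKEN = re.compile(
    r"""^(?:about\s+|ca\.\s*|~)?
        \d+(?:\.\d+)?(?:\s*[–\-]\s*\d+(?:\.\d+)?)?
        \s*(?:g|mg|kg|µg|ug|l|L|mL|ml|µL|uL|mol|mmol|µmol|umol|mole|moles|
             M|N|equiv(?:alents)?|eq\.?|%|wt\s?%)$""",
    re.VERBOSE,
)


def is_quantity_group(content: str) -> bool:
    parts = [p.strip() for p in content.split(",")]
    return bool(parts) and all(p and _QTY_TOKEN.match(p) for p in parts)


@dataclass(frozen=True)
class ParseError:
    """One unparseable clause: its 1-based index and offending token."""

    clause_index: int
    token: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"clause {self.clause_index}: {self.message} ({self.token!r})"


class ActionStringParseError(ValueError):
    """Raised by :func:`parse`; carries the structured :class:`ParseError`."""

    def __init__(self, error: ParseError):
        super().__init__(str(error))
        self.error = error


@dataclass(frozen=True)
class ParseFailure:
    error: ParseError

    @property
    def ok(self) -> bool:
        return False


@dataclass(frozen=True)
class ParseSuccess:
    sequence: ActionSequence

    @property
    def ok(self) -> bool:
        return True


ParseResult = Union[ParseSuccess, ParseFailure]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _format_ph(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else f"{value:g}"


def _format_mention(m: ChemicalMention) -> str:
    if m.quantities:
        inner = ", ".join(q.raw for q in m.quantities)
        return f"{m.name} ({inner})"
    return m.name


def _serialize_action(a: Action) -> str:
    t = a.type
    c = a.condition
    parts: list[str] = [t.value]
    if t is ActionType.MAKE_SOLUTION:
        parts.append("with " + " and ".join(_format_mention(m) for m in a.materials))
    elif t is ActionType.PARTITION:
        parts.append("with " + " and ".join(_format_mention(m) for m in a.materials))
    elif t in (ActionType.QUENCH, ActionType.WASH, ActionType.EXTRACT, ActionType.TRITURATE, ActionType.PH):
        if a.materials:
            parts.append("with " + _format_mention(a.materials[0]))
    elif t is ActionType.DRY_SOLUTION:
        if a.materials:
            parts.append("over " + _format_mention(a.materials[0]))
    elif t is ActionType.RECRYSTALLIZE:
        if a.materials:
            parts.append("from " + _format_mention(a.materials[0]))
    elif t in (ActionType.ADD, ActionType.YIELD):
        parts.append(_format_mention(a.materials[0]))
    if t in (ActionType.FILTER, ActionType.COLLECT_LAYER) and a.keep_phase is not None:
        if t is ActionType.FILTER:
            parts.append("keep " + a.keep_phase.value)
        else:
            parts.append(a.keep_phase.value)
    if t is ActionType.SET_TEMPERATURE:
        parts.append(c.temperature or "")
    elif t is ActionType.WAIT:
        if c.duration:
            parts.append(c.duration)
        if c.temperature:
            parts.append("at " + c.temperature)
    else:
        if c.dropwise:
            parts.append("dropwise")
        if c.ph_value is not None:
            parts.append("to pH " + _format_ph(c.ph_value))
        if c.duration:
            parts.append("for " + c.duration)
        if c.temperature:
            parts.append("at " + c.temperature)
        if c.atmosphere:
            parts.append("under " + c.atmosphere)
        if c.repetitions is not None:
            parts.append(f"x {c.repetitions}")
    return " ".join(p for p in parts if p)


def serialize(seq: ActionSequence) -> str:
    """Serialize a sequence into its canonical single-line form.

    Every action must pass :func:`synthactions.actions.validate_action`;
    an invalid action raises ``ValueError`` naming the violating field.
    """
    for i, a in enumerate(seq):
        result = validate_action(a)
        if not result.ok:
            raise ValueError(f"action {i + 1} invalid: " + "; ".join(result.violations))
    return CLAUSE_SEPARATOR.join(_serialize_action(a) for a in seq)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SUFFIX_PATTERNS = [
    ("repetitions", re.compile(r"(?:^|\s)x\s+(\d+)$")),
    ("atmosphere", re.compile(r"(?:^|\s)under\s+(.+)$")),
    ("temperature", re.compile(r"(?:^|\s)at\s+(.+)$")),
    ("duration", re.compile(r"(?:^|\s)for\s+(.+)$")),
    ("ph_value", re.compile(r"(?:^|\s)to\s+pH\s+(\d+(?:\.\d+)?)$")),
    ("dropwise", re.compile(r"(?:^|\s)dropwise$")),
]


def _strip_modifiers(text: str) -> tuple[str, dict]:
    """Peel condition modifiers off the clause tail, rightmost first."""
    mods: dict = {}
    changed = True
    while changed:
        changed = False
        for name, pat in _SUFFIX_PATTERNS:
            m = pat.search(text)
            if m and name not in mods:
                if name == "dropwise":
                    mods[name] = True
                elif name == "repetitions":
                    mods[name] = int(m.group(1))
                elif name == "ph_value":
                    mods[name] = float(m.group(1))
                else:
                    mods[name] = m.group(1).strip()
                text = text[: m.start()]
                changed = True
                break
    return text.strip(), mods


_MENTION_RE = re.compile(r"^(?P<name>.*?)(?:\s*\((?P<qty>[^()]*)\))?$")


def _parse_mention(text: str) -> ChemicalMention:
    text = text.strip()
    m = _MENTION_RE.match(text)
    name, qty = text, None
    if m and m.group("qty") is not None and is_quantity_group(m.group("qty")):
        name = m.group("name").strip()
        qty = m.group("qty")
    if not name:
        raise ValueError("empty compound name")
    quantities = ()
    if qty:
        quantities = tuple(Quantity(p.strip()) for p in qty.split(","))
    return ChemicalMention(name=name, quantities=quantities)


def _split_mentions(text: str) -> list[ChemicalMention]:
    return [_parse_mention(p) for p in re.split(r"\s+and\s+", text) if p.strip()]


def _parse_clause(clause: str, index: int) -> Action:
    clause = clause.strip()
    if not clause:
        raise ActionStringParseError(ParseError(index, "", "empty clause"))
    head = clause.split(None, 1)
    try:
        atype = action_type_from_name(head[0])
    except KeyError:
        raise ActionStringParseError(
            ParseError(index, head[0], "unknown action name")
        ) from None
    rest = head[1].strip() if len(head) > 1 else ""

    keep_phase: Optional[KeepPhase] = None
    cond_kwargs: dict = {}
    materials: tuple[ChemicalMention, ...] = ()

    try:
        if atype is ActionType.SET_TEMPERATURE:
            if not rest:
                raise ValueError("SetTemperature requires a temperature")
            cond_kwargs["temperature"] = rest
        elif atype is ActionType.WAIT:
            core, mods = _strip_modifiers(rest)
            cond_kwargs.update(mods)
            if core:
                cond_kwargs["duration"] = core
        else:
            core, mods = _strip_modifiers(rest)
            cond_kwargs.update(mods)
            if atype is ActionType.FILTER:
                if core:
                    m = re.match(r"^keep\s+(filtrate|precipitate)$", core)
                    if not m:
                        raise ValueError(f"bad Filter argument: {core!r}")
                    keep_phase = KeepPhase(m.group(1))
            elif atype is ActionType.COLLECT_LAYER:
                m = re.match(r"^(aqueous|organic)$", core)
                if not m:
                    raise ValueError(f"bad CollectLayer argument: {core!r}")
                keep_phase = KeepPhase(m.group(1))
            elif atype in (ActionType.MAKE_SOLUTION, ActionType.PARTITION):
                m = re.match(r"^with\s+(.+)$", core)
                if not m:
                    raise ValueError(f"{atype.value} requires 'with ...'")
                materials = tuple(_split_mentions(m.group(1)))
            elif atype in (
                ActionType.QUENCH,
                ActionType.WASH,
                ActionType.EXTRACT,
                ActionType.TRITURATE,
                ActionType.PH,
            ):
                if core:
                    m = re.match(r"^with\s+(.+)$", core)
                    if not m:
                        raise ValueError(f"{atype.value} requires 'with ...'")
                    materials = (_parse_mention(m.group(1)),)
            elif atype is ActionType.DRY_SOLUTION:
                if core:
                    m = re.match(r"^over\s+(.+)$", core)
                    if not m:
                        raise ValueError("DrySolution requires 'over ...'")
                    materials = (_parse_mention(m.group(1)),)
            elif atype is ActionType.RECRYSTALLIZE:
                if core:
                    m = re.match(r"^from\s+(.+)$", core)
                    if not m:
                        raise ValueError("Recrystallize requires 'from ...'")
                    materials = (_parse_mention(m.group(1)),)
            elif atype in (ActionType.ADD, ActionType.YIELD):
                if not core:
                    raise ValueError(f"{atype.value} requires a material")
                materials = (_parse_mention(core),)
            else:
                if core:
                    raise ValueError(f"unexpected argument for {atype.value}: {core!r}")
    except ActionStringParseError:
        raise
    except ValueError as exc:
        raise ActionStringParseError(ParseError(index, rest, str(exc))) from None

    action = Action(
        type=atype,
        materials=materials,
        condition=Condition(**cond_kwargs),
        keep_phase=keep_phase,
    )
    result = validate_action(action)
    if not result.ok:
        raise ActionStringParseError(
            ParseError(index, clause, "; ".join(result.violations))
        )
    return action


def parse(s: str) -> ActionSequence:
    """Parse an action string; raises :class:`ActionStringParseError`."""
    text = s.strip()
    if text.endswith("."):
        text = text[:-1].rstrip()
    if not text:
        return ActionSequence()
    clauses = [c for c in re.split(r"\s*;\s*", text)]
    actions = [_parse_clause(c, i + 1) for i, c in enumerate(clauses)]
    return ActionSequence(tuple(actions))


def try_parse(s: str) -> ParseResult:
    """Parse without raising; failures come back as data."""
    try:
        return ParseSuccess(parse(s))
    except ActionStringParseError as exc:
        return ParseFailure(exc.error)
    except Exception as exc:  # defensive: arbitrary input must never crash
        return ParseFailure(ParseError(0, s[:40], f"unexpected: {exc}"))


def count_actions(s: str) -> int:
    """Number of actions in a parseable action string ('' counts as 0)."""
    return len(parse(s))
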