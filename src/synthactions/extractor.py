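"""Rule-based extraction of action sequences from procedure sentences.

The extractor maps one sentence to an :class:`ActionSequence` in three
stages: (1) sentence-level classification — non-English text, cross
references to other procedures, and analytical/characterization text are
flagged with the corresponding non-laboratory action; (2) clause analysis —
operation verbs are located via an extensible lexicon, disambiguated by
context (e.g. "heat" with a duration is stirring at temperature, "remove"
with a solvent is concentration), and their arguments (materials,
conditions) parsed from the surrounding phrase structure; (3) implicit
actions — solution-phrase subjects become ``MakeSolution`` + ``Add SLN``,
bare "organic layer"/"aqueous layer" subjects prepend ``CollectLayer``, and
a ``Filter`` whose kept phase is unspecified but which is followed by
``Concentrate``/``DrySolution``/``Purify`` keeps the filtrate.

Every sentence yields a valid sequence: unsupported constructs come back as
``InvalidAction``, never as an exception, so serialized extractor output is
parseable by construction.
"""

from __future__ import annotations

import json
import re
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
    MentionRole,
    Quantity,
    allowed_properties,
    validate_action,
)
from .action_string import is_quantity_group
from .textproc import (
    SOLVENT_DICTIONARY,
    _ATMOSPHERE_RE,
    _DURATION_RE,
    _TEMPERATURE_RE,
    normalize_text,
    split_sentences,
)

# ---------------------------------------------------------------------------
# Verb lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClauseContext:
    """Context visible to verb-disambiguation rules."""

    clause: str = ""
    sentence: str = ""
    subject_kind: str = "neutral"  # compound|sln|layer|solid|neutral|unknown
    has_duration: bool = False
    has_temperature: bool = False
    has_reflux: bool = False
    has_microwave: bool = False
    has_filtration: bool = False
    has_desiccant_phrase: bool = False
    has_solvent_context: bool = False


ContextRule = tuple[Callable[[ClauseContext], bool], ActionType]


@dataclass(frozen=True)
class VerbLexiconEntry:
    """A verb lemma, its default action, and ordered context rules."""

    lemma: str
    default_action: ActionType
    context_rules: tuple[ContextRule, ...] = ()

    def resolve(self, context: ClauseContext) -> ActionType:
        for predicate, action_type in self.context_rules:
            if predicate(context):
                return action_type
        return self.default_action


class UnsupportedVerbError(KeyError):
    """Lemma absent from the lexicon (caller emits InvalidAction)."""


_HEAT_RULES: tuple[ContextRule, ...] = (
    (lambda c: c.has_reflux, ActionType.REFLUX),
    (lambda c: c.has_microwave, ActionType.MICROWAVE),
    (lambda c: c.has_duration, ActionType.STIR),
    (lambda c: c.has_temperature, ActionType.SET_TEMPERATURE),
)

_REMOVE_RULES: tuple[ContextRule, ...] = (
    (lambda c: c.has_filtration, ActionType.FILTER),
    (lambda c: c.has_solvent_context, ActionType.CONCENTRATE),
)

_DRY_RULES: tuple[ContextRule, ...] = (
    (
        lambda c: c.has_desiccant_phrase or c.subject_kind in ("layer", "sln"),
        ActionType.DRY_SOLUTION,
    ),
)

_COLLECT_RULES: tuple[ContextRule, ...] = (
    (lambda c: c.has_filtration, ActionType.FILTER),
)

_STAND_RULES: tuple[ContextRule, ...] = ()


def _entries() -> dict[str, VerbLexiconEntry]:
    table: dict[str, tuple[ActionType, tuple[ContextRule, ...]]] = {}

    def put(lemmas: str, action: ActionType, rules: tuple[ContextRule, ...] = ()):
        for lemma in lemmas.split():
            table[lemma] = (action, rules)

    put("add combine suspend charge dilute dissolve mix place pour treat introduce", ActionType.ADD)
    put("concentrate evaporate distill", ActionType.CONCENTRATE)
    put("remove", ActionType.CONCENTRATE, _REMOVE_RULES)
    put("quench", ActionType.QUENCH)
    put("wash", ActionType.WASH)
    put("dry", ActionType.DRY_SOLID, _DRY_RULES)
    put("filter", ActionType.FILTER)
    put("purify chromatograph", ActionType.PURIFY)
    put("recrystallize crystallize", ActionType.RECRYSTALLIZE)
    put("reflux", ActionType.REFLUX)
    put("stir agitate shake", ActionType.STIR)
    put("triturate", ActionType.TRITURATE)
    put("sonicate", ActionType.SONICATE)
    put("degas purge sparge", ActionType.DEGAS)
    put("microwave", ActionType.MICROWAVE)
    put("partition", ActionType.PARTITION)
    put("extract", ActionType.EXTRACT)
    put("separate", ActionType.PHASE_SEPARATION)
    put("heat warm cool chill", ActionType.SET_TEMPERATURE, _HEAT_RULES)
    put("stand wait age", ActionType.WAIT)
    put("give afford obtain yield furnish produce", ActionType.YIELD)
    put("adjust acidify basify neutralize", ActionType.PH)
    put("collect", ActionType.COLLECT_LAYER, _COLLECT_RULES)

    return {
        lemma: VerbLexiconEntry(lemma, action, rules)
        for lemma, (action, rules) in table.items()
    }


_IRREGULAR_FORMS = {
    "give": ("give", "gives", "gave", "given", "giving"),
    "stand": ("stand", "stands", "stood", "standing"),
    "degas": ("degas", "degasses", "degassed", "degassing"),
}

_VOWELS = set("aeiou")


def _inflections(lemma: str) -> set[str]:
    if lemma in _IRREGULAR_FORMS:
        return set(_IRREGULAR_FORMS[lemma])
    forms = {lemma, lemma + "s"}
    if lemma.endswith("e"):
        forms.add(lemma + "d")
        forms.add(lemma[:-1] + "ing")
    elif lemma.endswith("y") and len(lemma) > 1 and lemma[-2] not in _VOWELS:
        forms.add(lemma[:-1] + "ied")
        forms.add(lemma + "ing")
        forms.add(lemma[:-1] + "ies")
    elif (
        len(lemma) <= 4
        and len(lemma) >= 3
        and lemma[-1] in "bdglmnprt"
        and lemma[-2] in _VOWELS
        and lemma[-3] not in _VOWELS
    ):
        forms.add(lemma + lemma[-1] + "ed")
        forms.add(lemma + lemma[-1] + "ing")
    else:
        forms.add(lemma + "ed")
        forms.add(lemma + "ing")
    if lemma.endswith("ize"):  # accept British spelling on input
        forms |= {f.replace("iz", "is", 1) if "iz" in f else f for f in {lemma, lemma + "d", lemma[:-1] + "ing", lemma + "s"}}
    return forms


class Lexicon:
    """Verb lexicon with surface-form lookup; extensible from JSON."""

    def __init__(self, entries: Optional[dict[str, VerbLexiconEntry]] = None):
        self.entries = dict(entries or _entries())
        self._form_to_lemma: dict[str, str] = {}
        for lemma in self.entries:
            for form in _inflections(lemma):
                self._form_to_lemma[form] = lemma

    def lemma_for_form(self, word: str) -> Optional[str]:
        return self._form_to_lemma.get(word.lower())

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def resolve(self, lemma: str, context: ClauseContext) -> ActionType:
        try:
            entry = self.entries[lemma]
        except KeyError:
            raise UnsupportedVerbError(lemma) from None
        return entry.resolve(context)

    def extended(self, mapping: dict[str, str]) -> "Lexicon":
        """New lexicon with extra lemma → action-name entries."""
        entries = dict(self.entries)
        for lemma, action_name in mapping.items():
            entries[lemma.lower()] = VerbLexiconEntry(
                lemma.lower(), ActionType(action_name)
            )
        return Lexicon(entries)

    @classmethod
    def from_json(cls, path: str) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return DEFAULT_LEXICON.extended(json.load(fh))


DEFAULT_LEXICON = Lexicon()


def disambiguate_verb(lemma: str, context: "ClauseContext | str", lexicon: Lexicon = DEFAULT_LEXICON) -> ActionType:
    """Resolve a verb lemma to an action type given its sentence context.

    ``context`` may be a :class:`ClauseContext` or raw clause text; raises
    :class:`UnsupportedVerbError` for lemmas outside the lexicon.
    """
    if isinstance(context, str):
        context = _clause_context(context, subject_kind="neutral")
    return lexicon.resolve(lemma, context)


# ---------------------------------------------------------------------------
# Sentence-level classification
# ---------------------------------------------------------------------------

#: Keywords marking analytical / characterization text.
ANALYSIS_KEYWORDS = (
    "NMR",
    "MS",
    "HPLC",
    "LCMS",
    "m/z",
    "δ",
    "Hz",
    "IR",
    "mp",
    "m.p.",
    "anal",
    "calcd",
    "found",
)

_ANALYSIS_RE = re.compile(
    r"\b(?:NMR|MS|HPLC|LCMS|LC-MS|GC|IR|UV|ESI|mp|anal\.?|calcd\.?|found)\b"
    r"|m/z|δ|\bHz\b|m\.p\.",
)

_CROSS_REF_RE = re.compile(
    r"as\s+described\s+in|according\s+to\s+the\s+(?:general\s+)?procedure"
    r"|prepared\s+as\s+in|in\s+a\s+(?:similar\s+)?manner\s+(?:similar\s+)?"
    r"(?:to|as)|following\s+the\s+(?:general\s+)?procedure|same\s+manner\s+as"
    r"|as\s+in\s+example|analogous(?:ly)?\s+to",
    re.IGNORECASE,
)

_ENGLISH_HINTS = frozenset(
    "the was were is are of with to and then at under for from over by".split()
)


def _has_lexicon_verb(text: str, lexicon: Lexicon) -> bool:
    return any(
        lexicon.lemma_for_form(m.group(0)) is not None
        for m in re.finditer(r"[A-Za-z][A-Za-z'-]*", text)
    )


def _is_other_language(text: str, lexicon: Lexicon) -> bool:
    letters = [c for c in text if c.isalpha()]
    if letters:
        non_ascii = sum(1 for c in letters if ord(c) > 127)
        if non_ascii / len(letters) > 0.3:
            return True
    words = {w.lower() for w in re.findall(r"[A-Za-z'-]+", text)}
    if words & _ENGLISH_HINTS:
        return False
    return not _has_lexicon_verb(text, lexicon)


# ---------------------------------------------------------------------------
# Noun-phrase / mention parsing
# ---------------------------------------------------------------------------

_NEUTRAL_NP_RE = re.compile(
    r"^(?:the\s+|this\s+|a\s+|an\s+)?(?:reaction\s+|resulting\s+|solution\s+)?"
    r"(?:mixture|solution|reaction|residue|filtrate|contents|mass|it|flask|"
    r"vessel|pot|suspension|slurry|title\s+compound)$",
    re.IGNORECASE,
)

_SOLID_NP_RE = re.compile(
    r"^(?:the\s+)?(?:resulting\s+|crude\s+)?"
    r"(?:solid|precipitate|crystals|product|cake|powder)s?$",
    re.IGNORECASE,
)

_LAYER_RE = re.compile(
    r"^(?:the\s+)?(?:combined\s+)?(organic|aqueous)\s+(?:layer|phase|extract|fraction)s?$",
    re.IGNORECASE,
)

_INLINE_QTY_OF_RE = re.compile(
    r"""^(?P<qty>(?:about\s+)?\d+(?:\.\d+)?\s*
        (?:g|mg|kg|µg|ug|mL|ml|µL|uL|L|l|mol|mmol|µmol|umol|mole|moles))
        \s+of\s+(?P<name>.+)$""",
    re.VERBOSE | re.IGNORECASE,
)

_TRAILING_QTY_RE = re.compile(r"^(?P<name>.*?)\s*\((?P<qty>[^()]*)\)\s*$")

_SOLUTION_HEAD_RE = re.compile(
    r"^(?:a|an|the)?\s*(?:stirred\s+|cooled\s+|ice-cold\s+)?"
    r"(?:solution|suspension|mixture|slurry)\s+of\s+(?P<body>.+)$",
    re.IGNORECASE,
)


def _split_top(text: str, sep: str) -> list[str]:
    """Split on a regex separator at parenthesis depth zero."""
    parts: list[str] = []
    depth = 0
    last = 0
    for m in re.finditer(rf"[()]|{sep}", text):
        tok = m.group(0)
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth = max(0, depth - 1)
        elif depth == 0:
            parts.append(text[last : m.start()])
            last = m.end()
    parts.append(text[last:])
    return [p for p in (p.strip() for p in parts) if p]


def parse_mention_np(text: str, role: MentionRole = MentionRole.UNKNOWN) -> Optional[ChemicalMention]:
    """Parse a noun phrase into a compound mention, or None."""
    t = text.strip().strip(",.;:")
    t = re.sub(r"^(?:a|an|the)\s+", "", t, flags=re.IGNORECASE)
    t = re.sub(r"\s+as\s+an?\s+[\w\s-]+$", "", t)
    if not t or _NEUTRAL_NP_RE.match(t):
        return None
    m = _INLINE_QTY_OF_RE.match(t)
    if m:
        name = re.sub(r"^(?:a|an|the)\s+", "", m.group("name").strip(), flags=re.IGNORECASE)
        if name:
            return ChemicalMention(name=name, quantities=(Quantity(m.group("qty")),), role=role)
    m = _TRAILING_QTY_RE.match(t)
    if m and m.group("qty") is not None and is_quantity_group(m.group("qty")):
        name = re.sub(r"\s+as\s+an?\s+[\w\s-]+$", "", m.group("name").strip())
        if name:
            return ChemicalMention(
                name=name,
                quantities=tuple(Quantity(q.strip()) for q in m.group("qty").split(",")),
                role=role,
            )
    return ChemicalMention(name=t, role=role) if t else None


def _parse_mention_list(text: str, role: MentionRole = MentionRole.UNKNOWN) -> list[ChemicalMention]:
    out = []
    for part in _split_top(text, r"\s+and\s+|,\s+"):
        m = parse_mention_np(part, role)
        if m is not None:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# Subject analysis & implicit actions
# ---------------------------------------------------------------------------


@dataclass
class SubjectInfo:
    kind: str = "neutral"  # compound|sln|layer|solid|neutral|unknown
    mention: Optional[ChemicalMention] = None
    layer: Optional[KeepPhase] = None
    collect_pending: bool = False
    temperature: Optional[str] = None
    consumed: bool = False


def _solution_np_actions(body: str) -> Optional[tuple[list[Action], SubjectInfo]]:
    """Interpret "X (q) [and Y (q)] in Z (q)" as MakeSolution + Add SLN."""
    in_parts = _split_top(body, r"\s+in\s+")
    if len(in_parts) == 2:
        solutes_text, solvent_text = in_parts
        solvent = parse_mention_np(solvent_text, MentionRole.SOLVENT)
    elif len(in_parts) == 1:
        solutes_text, solvent = in_parts[0], None
    else:  # "X in Y in Z" — ambiguous, take last as solvent
        solutes_text = " in ".join(in_parts[:-1])
        solvent = parse_mention_np(in_parts[-1], MentionRole.SOLVENT)
    solutes = _parse_mention_list(solutes_text, MentionRole.SUBJECT)
    materials = solutes + ([solvent] if solvent else [])
    if len(materials) >= 2:
        actions = [
            Action(type=ActionType.MAKE_SOLUTION, materials=tuple(materials)),
            Action(type=ActionType.ADD, materials=(ChemicalMention(name=SLN),)),
        ]
        return actions, SubjectInfo(kind="sln")
    if len(materials) == 1:
        return [], SubjectInfo(kind="compound", mention=materials[0])
    return None


def analyze_subject(subject_text: str) -> tuple[list[Action], SubjectInfo]:
    """Derive implicit prefix actions and a subject descriptor."""
    t = normalize_text(subject_text).strip().strip(",")
    prefix: list[Action] = []
    to_target = False
    m = re.match(r"^To\s+", t, re.IGNORECASE)
    if m:
        to_target = True
        t = t[m.end():]

    temperature = None
    tm = _TEMPERATURE_RE.search(t)
    if tm:
        temperature = tm.group(0)
        t = (t[: tm.start()] + t[tm.end():]).strip().strip(",.")
        t = re.sub(r"\s+(?:at|to)\s*$", "", t).strip()

    info = SubjectInfo()
    sol = _SOLUTION_HEAD_RE.match(t)
    if sol:
        parsed = _solution_np_actions(sol.group("body"))
        if parsed:
            prefix_actions, info = parsed
            prefix.extend(prefix_actions)
    elif _LAYER_RE.match(t):
        phase = _LAYER_RE.match(t).group(1).lower()
        info = SubjectInfo(kind="layer", layer=KeepPhase(phase), collect_pending=True)
    elif re.match(r"^(?:the\s+)?[\w\s-]+\s+(?:solution|layer|phase|extract)s?$", t, re.IGNORECASE) and any(
        s in t.lower() for s in SOLVENT_DICTIONARY
    ):
        info = SubjectInfo(kind="layer", layer=KeepPhase.ORGANIC, collect_pending=True)
    elif _NEUTRAL_NP_RE.match(t) or not t:
        info = SubjectInfo(kind="neutral")
    elif _SOLID_NP_RE.match(t):
        info = SubjectInfo(kind="solid")
    elif len(_split_top(t, r"\s+in\s+")) == 2 and not to_target:
        parsed = _solution_np_actions(t)
        if parsed and parsed[0]:
            prefix_actions, info = parsed
            prefix.extend(prefix_actions)
        elif parsed:
            info = parsed[1]
        else:
            info = SubjectInfo(kind="unknown")
    else:
        mention = parse_mention_np(t, MentionRole.SUBJECT)
        if mention is not None:
            info = SubjectInfo(kind="compound", mention=mention)
        else:
            info = SubjectInfo(kind="neutral")

    if to_target:
        # "To X was added Y": the target is in the pot first.
        if info.kind == "sln" and not prefix:
            pass
        elif info.kind == "compound" and info.mention is not None:
            prefix.append(Action(type=ActionType.ADD, materials=(info.mention,)))
            info = SubjectInfo(kind="neutral")
        elif info.kind == "sln":
            info = SubjectInfo(kind="sln")
        else:
            info = SubjectInfo(kind="neutral")
        info.kind = info.kind if info.kind == "sln" else "neutral"
    info.temperature = temperature
    return prefix, info


def insert_implicit_actions(seq: ActionSequence, sentence: str) -> ActionSequence:
    """Prepend the implicit actions a sentence's subject implies.

    Solution-phrase subjects prepend ``MakeSolution`` + ``Add SLN``; bare
    organic/aqueous-layer subjects prepend ``CollectLayer``.  Sequences
    whose subject carries no implicit action are returned unchanged.
    """
    s = normalize_text(sentence)
    m = re.search(r"\b(?:was|were|is|are)\b", s)
    subject_text = s[: m.start()] if m else s
    prefix, info = analyze_subject(subject_text)
    actions = list(seq)
    if prefix and not (actions and actions[0].type is ActionType.MAKE_SOLUTION):
        return ActionSequence(tuple(prefix) + tuple(actions))
    if (
        info.kind == "layer"
        and actions
        and actions[0].type
        in (
            ActionType.DRY_SOLUTION,
            ActionType.WASH,
            ActionType.EXTRACT,
            ActionType.CONCENTRATE,
            ActionType.FILTER,
        )
        and not (actions and actions[0].type is ActionType.COLLECT_LAYER)
    ):
        collect = Action(type=ActionType.COLLECT_LAYER, keep_phase=info.layer)
        return ActionSequence((collect,) + tuple(actions))
    return seq


# ---------------------------------------------------------------------------
# Clause parsing
# ---------------------------------------------------------------------------

_AUX_RE = re.compile(r"\b(?:was|were|is|are|has\s+been|have\s+been|had\s+been)\b")

_IN_VACUO_RE = re.compile(
    r"\bin\s+vacuo\b|\bunder\s+(?:reduced\s+pressure|(?:high\s+)?vacuum)\b",
    re.IGNORECASE,
)
_REFLUX_MARK_RE = re.compile(r"\b(?:to|at|under)\s+reflux\b", re.IGNORECASE)
_DROPWISE_RE = re.compile(r"\bdropwise\b", re.IGNORECASE)
_PH_MARK_RE = re.compile(r"(?:\bto\s+)?\bpH\s*(?:=|of|to)?\s*(\d+(?:\.\d+)?)")
_REPS_RE = re.compile(
    r"\b(?:(once)|(twice)|(three)\s+times|(four)\s+times|(five)\s+times|(\d+)\s+times)\b",
    re.IGNORECASE,
)
_FILTRATION_RE = re.compile(r"\bfiltrat|filter", re.IGNORECASE)

_DESICCANTS_RE = re.compile(
    r"sulfate|sulphate|sieves|chloride|Na2SO4|MgSO4|CaCl2|desiccant",
    re.IGNORECASE,
)


@dataclass
class ClauseParts:
    lemma: str
    verb_form: str
    text: str
    post: str  # text after the verb, conditions stripped
    temperature: Optional[str] = None
    duration: Optional[str] = None
    atmosphere: Optional[str] = None
    ph_value: Optional[float] = None
    dropwise: bool = False
    repetitions: Optional[int] = None
    in_vacuo: bool = False
    reflux: bool = False


def _remove_span(text: str, start: int, end: int) -> str:
    return (text[:start] + " " + text[end:]).strip()


def _strip_conditions(text: str) -> tuple[str, dict]:
    """Pull conditions out of clause text; returns (residue, values)."""
    vals: dict = {}
    if _IN_VACUO_RE.search(text):
        vals["in_vacuo"] = True
        text = _IN_VACUO_RE.sub(" ", text)
    m = _REFLUX_MARK_RE.search(text)
    if m:
        vals["reflux"] = True
        text = _remove_span(text, m.start(), m.end())
    m = _ATMOSPHERE_RE.search(text)
    if m:
        vals["atmosphere"] = m.group("gas") or m.group("gas2")
        end = m.end()
        tail = re.match(r"\s+atmosphere\b", text[end:])
        if tail:
            end += tail.end()
        text = _remove_span(text, m.start(), end)
    m = _PH_MARK_RE.search(text)
    if m:
        vals["ph_value"] = float(m.group(1))
        text = _remove_span(text, m.start(), m.end())
    m = _TEMPERATURE_RE.search(text)
    if m:
        vals["temperature"] = normalize_text(m.group(0))
        start = m.start()
        lead = re.search(r"(?:\bat\s+|\bto\s+)$", text[:start])
        if lead:
            start = lead.start()
        text = _remove_span(text, start, m.end())
    m = _DURATION_RE.search(text)
    if m:
        duration = normalize_text(re.sub(r"\badditional\s+", "", m.group(0)))
        duration = re.sub(r"^(?:about|approximately)\s+", "", duration)
        vals["duration"] = duration
        start = m.start()
        lead = re.search(r"\bfor\s+$", text[:start])
        if lead:
            start = lead.start()
        text = _remove_span(text, start, m.end())
    if _DROPWISE_RE.search(text):
        vals["dropwise"] = True
        text = _DROPWISE_RE.sub(" ", text)
    m = _REPS_RE.search(text)
    if m:
        word_values = {"once": 1, "twice": 2, "three": 3, "four": 4, "five": 5}
        token = next(g for g in m.groups() if g)
        vals["repetitions"] = word_values.get(token.lower(), None) or int(token)
        text = _remove_span(text, m.start(), m.end())
    return normalize_text(text), vals


def _clause_context(clause: str, subject_kind: str, sentence: str = "") -> ClauseContext:
    _, vals = _strip_conditions(clause)
    return ClauseContext(
        clause=clause,
        sentence=sentence or clause,
        subject_kind=subject_kind,
        has_duration="duration" in vals,
        has_temperature="temperature" in vals,
        has_reflux=vals.get("reflux", False),
        has_microwave="microwave" in clause.lower(),
        has_filtration=bool(_FILTRATION_RE.search(clause)),
        has_desiccant_phrase=bool(
            re.search(r"\bover\s+", clause) and _DESICCANTS_RE.search(clause)
        ),
        has_solvent_context=bool(
            re.search(r"\bsolvents?\b", clause, re.IGNORECASE)
            or _IN_VACUO_RE.search(clause)
        ),
    )


@dataclass(frozen=True)
class _VerbMatch:
    start: int
    end: int
    lemma: str
    form: str


def _find_verbs(text: str, lexicon: Lexicon) -> list[_VerbMatch]:
    out: list[_VerbMatch] = []
    depth = 0
    idx = 0
    for m in re.finditer(r"[()]|[A-Za-z][A-Za-z'-]*", text):
        tok = m.group(0)
        if tok == "(":
            depth += 1
            continue
        if tok == ")":
            depth = max(0, depth - 1)
            continue
        if depth > 0:
            continue
        lemma = lexicon.lemma_for_form(tok)
        if lemma is None:
            continue
        before = text[: m.start()].rstrip()
        if re.search(r"\b(?:the|a|an|this|of)$", before, re.IGNORECASE):
            continue  # noun usage: "the extract", "of the mixture"
        if lemma == "reflux" and re.search(r"\b(?:to|at|under)$", before, re.IGNORECASE):
            continue  # "heated to reflux": noun, handled as a condition
        out.append(_VerbMatch(m.start(), m.end(), lemma, tok))
        idx += 1
    return out


_CONNECTOR_TAIL_RE = re.compile(
    r"[\s,;]*(?:\b(?:and\s+then|and|then|followed\s+by|to|before|while|whilst|"
    r"after|during)\b)?[\s,;]*$",
    re.IGNORECASE,
)


def _split_into_clauses(text: str, lexicon: Lexicon) -> list[tuple[_VerbMatch, str]]:
    verbs = _find_verbs(text, lexicon)
    clauses: list[tuple[_VerbMatch, str]] = []
    for i, v in enumerate(verbs):
        end = verbs[i + 1].start if i + 1 < len(verbs) else len(text)
        seg = text[v.start : end].rstrip(" .;")
        seg = _CONNECTOR_TAIL_RE.sub("", seg)
        clauses.append((v, seg))
    return clauses


_KEYWORD_SPLIT_RE = re.compile(
    r"\b(with|over|from|between|into|in|to|onto)\b", re.IGNORECASE
)


def _phrase(post: str, keyword: str) -> Optional[str]:
    m = re.search(rf"\b{keyword}\s+(.+)$", post, re.IGNORECASE)
    if not m:
        return None
    return m.group(1).strip().strip(",.;")


def _direct_object(post: str) -> str:
    return _KEYWORD_SPLIT_RE.split(post, maxsplit=1)[0].strip().strip(",.;")


def _cond(atype: ActionType, parts: ClauseParts, extra_temp: Optional[str] = None) -> Condition:
    allowed = allowed_properties(atype)
    return Condition(
        temperature=(parts.temperature or extra_temp) if "temperature" in allowed else None,
        duration=parts.duration if "duration" in allowed else None,
        atmosphere=parts.atmosphere if "atmosphere" in allowed else None,
        ph_value=parts.ph_value if "ph_value" in allowed else None,
        dropwise=parts.dropwise if "dropwise" in allowed else False,
        repetitions=parts.repetitions if "repetitions" in allowed else None,
    )


class _ClauseUnsupported(Exception):
    pass


def _build_actions(
    atype: ActionType, parts: ClauseParts, subj: SubjectInfo
) -> list[Action]:
    post = parts.post
    lemma = parts.lemma

    if atype is ActionType.ADD:
        actions: list[Action] = []
        in_obj = _phrase(post, "in(?:to)?")
        with_obj = _phrase(post, "with")
        to_obj = _phrase(post, "to")
        direct = _direct_object(post)
        primary: Optional[ChemicalMention] = None
        if direct:
            primary = parse_mention_np(direct, MentionRole.DIRECT_OBJECT)
        if primary is None and lemma in ("dilute", "treat", "charge", "combine", "mix") and with_obj:
            primary = parse_mention_np(with_obj, MentionRole.DIRECT_OBJECT)
            with_obj = None
        if primary is None and not subj.consumed and subj.kind == "compound" and subj.mention:
            primary = subj.mention
            subj.consumed = True
        if to_obj and lemma != "dissolve":
            target = parse_mention_np(to_obj, MentionRole.OBLIQUE)
            if target is not None:
                actions.append(Action(type=ActionType.ADD, materials=(target,)))
        solvent = None
        if in_obj and lemma in ("dissolve", "suspend", "dilute", "take", "pour", "add", "mix", "place"):
            solvent = parse_mention_np(in_obj, MentionRole.SOLVENT)
        mats = [m for m in (primary, solvent) if m is not None]
        if not mats and subj.kind == "sln":
            return actions  # Add SLN already emitted from the subject
        if not mats:
            return actions
        cond = _cond(ActionType.ADD, parts, extra_temp=subj.temperature)
        for i, m in enumerate(mats):
            last = i == len(mats) - 1
            actions.append(
                Action(
                    type=ActionType.ADD,
                    materials=(m,),
                    condition=cond if last else Condition(dropwise=cond.dropwise),
                )
            )
        return actions

    if atype is ActionType.MAKE_SOLUTION:
        with_obj = _phrase(post, "with")
        mats = _parse_mention_list(with_obj) if with_obj else []
        if len(mats) >= 2:
            return [
                Action(type=ActionType.MAKE_SOLUTION, materials=tuple(mats)),
                Action(type=ActionType.ADD, materials=(ChemicalMention(name=SLN),)),
            ]
        raise _ClauseUnsupported(parts.text)

    if atype is ActionType.DEGAS:
        cond = _cond(atype, parts)
        if cond.atmosphere is None:
            obj = _phrase(post, "with")
            if obj and re.fullmatch(
                r"(?:nitrogen|argon|air|hydrogen|oxygen|N2|Ar|H2|O2|CO)", obj, re.IGNORECASE
            ):
                cond = replace(cond, atmosphere=obj)
        return [Action(type=atype, condition=cond)]

    if atype in (ActionType.STIR, ActionType.SONICATE, ActionType.MICROWAVE,
                 ActionType.DRY_SOLID, ActionType.REFLUX):
        return [Action(type=atype, condition=_cond(atype, parts))]

    if atype is ActionType.SET_TEMPERATURE:
        temp = parts.temperature or subj.temperature
        if temp is None:
            raise _ClauseUnsupported(parts.text)
        return [Action(type=atype, condition=Condition(temperature=temp))]

    if atype is ActionType.WAIT:
        if parts.duration is None:
            raise _ClauseUnsupported(parts.text)
        return [Action(type=atype, condition=_cond(atype, parts))]

    if atype is ActionType.QUENCH:
        obj = _phrase(post, "with") or _phrase(post, "by\\s+addition\\s+of")
        mats = (parse_mention_np(obj, MentionRole.OBLIQUE),) if obj else ()
        mats = tuple(m for m in mats if m is not None)
        return [Action(type=atype, materials=mats, condition=_cond(atype, parts))]

    if atype in (ActionType.WASH, ActionType.EXTRACT):
        obj = _phrase(post, "with")
        mats = _parse_mention_list(obj, MentionRole.OBLIQUE) if obj else []
        cond = _cond(atype, parts)
        if not mats:
            return [Action(type=atype, condition=cond)]
        return [Action(type=atype, materials=(m,), condition=cond) for m in mats]

    if atype is ActionType.DRY_SOLUTION:
        obj = _phrase(post, "over") or _phrase(post, "with")
        mats = (parse_mention_np(obj, MentionRole.OBLIQUE),) if obj else ()
        mats = tuple(m for m in mats if m is not None)
        return [Action(type=atype, materials=mats)]

    if atype is ActionType.FILTER:
        keep = None
        if re.search(r"\bfiltered\s+off\b", parts.text, re.IGNORECASE) or parts.lemma == "collect":
            keep = KeepPhase.PRECIPITATE
        return [Action(type=atype, keep_phase=keep)]

    if atype in (ActionType.CONCENTRATE, ActionType.PHASE_SEPARATION, ActionType.PURIFY):
        actions = []
        if atype is ActionType.PHASE_SEPARATION:
            actions.append(Action(type=atype))
            if subj.kind == "layer" and subj.collect_pending:
                actions.append(Action(type=ActionType.COLLECT_LAYER, keep_phase=subj.layer))
                subj.collect_pending = False
            return actions
        return [Action(type=atype)]

    if atype is ActionType.PH:
        obj = _phrase(post, "with")
        mats = (parse_mention_np(obj, MentionRole.OBLIQUE),) if obj else ()
        mats = tuple(m for m in mats if m is not None)
        return [Action(type=atype, materials=mats, condition=_cond(atype, parts))]

    if atype is ActionType.COLLECT_LAYER:
        phase = subj.layer
        m = re.search(r"\b(organic|aqueous)\b", parts.text, re.IGNORECASE)
        if m:
            phase = KeepPhase(m.group(1).lower())
        if phase is None:
            raise _ClauseUnsupported(parts.text)
        subj.collect_pending = False
        return [Action(type=atype, keep_phase=phase)]

    if atype is ActionType.PARTITION:
        obj = _phrase(post, "between")
        mats = _parse_mention_list(obj, MentionRole.OBLIQUE) if obj else []
        if len(mats) == 2:
            return [Action(type=atype, materials=tuple(mats))]
        raise _ClauseUnsupported(parts.text)

    if atype is ActionType.RECRYSTALLIZE:
        obj = _phrase(post, "from") or _phrase(post, "with")
        mats = (parse_mention_np(obj, MentionRole.OBLIQUE),) if obj else ()
        mats = tuple(m for m in mats if m is not None)
        return [Action(type=atype, materials=mats)]

    if atype is ActionType.TRITURATE:
        obj = _phrase(post, "with") or _phrase(post, "in")
        mats = (parse_mention_np(obj, MentionRole.OBLIQUE),) if obj else ()
        mats = tuple(m for m in mats if m is not None)
        return [Action(type=atype, materials=mats)]

    if atype is ActionType.YIELD:
        direct = _direct_object(post)
        mention = parse_mention_np(direct, MentionRole.DIRECT_OBJECT) if direct else None
        if mention is None and direct:
            mention = ChemicalMention(name=re.sub(r"^(?:a|an|the)\s+", "", direct))
        if mention is None:
            raise _ClauseUnsupported(parts.text)
        return [Action(type=atype, materials=(mention,))]

    raise _ClauseUnsupported(parts.text)


def _clause_actions(
    verb: _VerbMatch, clause: str, subj: SubjectInfo, lexicon: Lexicon, sentence: str
) -> list[Action]:
    post_raw = clause[verb.end - verb.start :].strip() if clause.lower().startswith(verb.form.lower()) else clause
    post, vals = _strip_conditions(post_raw)
    parts = ClauseParts(
        lemma=verb.lemma,
        verb_form=verb.form,
        text=clause,
        post=post,
        temperature=vals.get("temperature"),
        duration=vals.get("duration"),
        atmosphere=vals.get("atmosphere"),
        ph_value=vals.get("ph_value"),
        dropwise=vals.get("dropwise", False),
        repetitions=vals.get("repetitions"),
        in_vacuo=vals.get("in_vacuo", False),
        reflux=vals.get("reflux", False),
    )
    context = _clause_context(clause, subj.kind, sentence)
    atype = lexicon.resolve(verb.lemma, context)
    actions = _build_actions(atype, parts, subj)
    # implicit layer collection before the first solution-phase operation
    if (
        subj.collect_pending
        and actions
        and actions[0].type
        in (
            ActionType.DRY_SOLUTION,
            ActionType.WASH,
            ActionType.EXTRACT,
            ActionType.CONCENTRATE,
            ActionType.FILTER,
        )
    ):
        actions.insert(0, Action(type=ActionType.COLLECT_LAYER, keep_phase=subj.layer))
        subj.collect_pending = False
    return actions


# ---------------------------------------------------------------------------
# Sentence / procedure extraction
# ---------------------------------------------------------------------------

_SUBSENTENCE_SPLIT_RE = re.compile(
    r"(?:,\s+|,?\s+and\s+)(?=(?:the|a|an|it|this)\b[^,;]{0,80}?\s(?:was|were|is|are)\s)",
    re.IGNORECASE,
)

_LEADING_SUBORDINATE_RE = re.compile(
    r"^(?:After|Upon|Following|Once|Then)\s+([^,]+),\s*", re.IGNORECASE
)

_PASSIVE_UNKNOWN_RE = re.compile(r"\b(?:was|were|is|are)\s+(?:\w+\s+)?\w+(?:ed|en)\b")


def _fill_filter_phase(actions: list[Action]) -> list[Action]:
    out = list(actions)
    for i, a in enumerate(out):
        if a.type is ActionType.FILTER and a.keep_phase is None:
            for b in out[i + 1 :]:
                if b.type is ActionType.WASH:
                    continue
                if b.type in (
                    ActionType.CONCENTRATE,
                    ActionType.DRY_SOLUTION,
                    ActionType.PURIFY,
                ):
                    out[i] = replace(a, keep_phase=KeepPhase.FILTRATE)
                break
    return out


def _sanitize(actions: list[Action]) -> list[Action]:
    """Guarantee validity: strip disallowed fields, degrade to InvalidAction."""
    out: list[Action] = []
    for a in actions:
        if validate_action(a).ok:
            out.append(a)
            continue
        allowed = allowed_properties(a.type)
        cleaned = Action(
            type=a.type,
            materials=a.materials if "materials" in allowed else (),
            condition=Condition(
                temperature=a.condition.temperature if "temperature" in allowed else None,
                duration=a.condition.duration if "duration" in allowed else None,
                atmosphere=a.condition.atmosphere if "atmosphere" in allowed else None,
                ph_value=a.condition.ph_value if "ph_value" in allowed else None,
                dropwise=a.condition.dropwise if "dropwise" in allowed else False,
                repetitions=a.condition.repetitions if "repetitions" in allowed else None,
            ),
            keep_phase=a.keep_phase if "keep_phase" in allowed else None,
        )
        out.append(cleaned if validate_action(cleaned).ok else Action(type=ActionType.INVALID_ACTION))
    return out


def _extract_subsentence(sub: str, lexicon: Lexicon, sentence: str) -> list[Action]:
    actions: list[Action] = []
    m = _AUX_RE.search(sub)
    if m:
        subject_text, predicate = sub[: m.start()], sub[m.end():]
    else:
        first = re.match(r"\s*([A-Za-z][A-Za-z'-]*)", sub)
        if first and lexicon.lemma_for_form(first.group(1)):
            subject_text, predicate = "", sub
        else:
            return []
    prefix, subj = analyze_subject(subject_text) if subject_text else ([], SubjectInfo())
    actions.extend(prefix)
    clauses = _split_into_clauses(predicate, lexicon)
    for verb, clause in clauses:
        try:
            actions.extend(_clause_actions(verb, clause, subj, lexicon, sentence))
        except (_ClauseUnsupported, UnsupportedVerbError):
            actions.append(Action(type=ActionType.INVALID_ACTION))
    if not clauses and prefix:
        pass  # subject-only fragment: keep the implicit actions
    return actions


def extract_sentence(sentence: str, lexicon: Lexicon = DEFAULT_LEXICON) -> ActionSequence:
    """Extract the action sequence of a single sentence.

    Total: every input yields a valid (possibly ``[InvalidAction]``,
    ``[NoAction]``, ``[OtherLanguage]`` or ``[FollowOtherProcedure]``)
    sequence and never raises.
    """
    s = normalize_text(sentence)
    if not s:
        return ActionSequence()
    if _ANALYSIS_RE.search(s) and not _has_lexicon_verb(s, lexicon):
        return ActionSequence((Action(type=ActionType.NO_ACTION),))
    if _is_other_language(s, lexicon):
        return ActionSequence((Action(type=ActionType.OTHER_LANGUAGE),))
    if _CROSS_REF_RE.search(s):
        return ActionSequence((Action(type=ActionType.FOLLOW_OTHER_PROCEDURE),))
    # sentence-initial capitalization is orthographic, not part of the name
    if len(s) > 1 and s[0].isupper() and s[1].islower():
        s = s[0].lower() + s[1:]

    actions: list[Action] = []
    rest = s
    while True:
        m = _LEADING_SUBORDINATE_RE.match(rest)
        if not m:
            break
        phrase = m.group(1).strip()
        rest = rest[m.end():]
        dur = _DURATION_RE.fullmatch(phrase)
        if dur:
            actions.append(
                Action(type=ActionType.WAIT, condition=Condition(duration=normalize_text(phrase)))
            )
            continue
        sub_actions = _extract_subsentence(phrase, lexicon, s)
        actions.extend(sub_actions)

    for sub in _SUBSENTENCE_SPLIT_RE.split(rest):
        if sub.strip():
            actions.extend(_extract_subsentence(sub.strip(), lexicon, s))

    actions = _sanitize(actions)
    actions = _fill_filter_phase(actions)

    if not actions:
        if _ANALYSIS_RE.search(s):
            return ActionSequence((Action(type=ActionType.NO_ACTION),))
        if _PASSIVE_UNKNOWN_RE.search(s) or _has_lexicon_verb(s, lexicon):
            return ActionSequence((Action(type=ActionType.INVALID_ACTION),))
        return ActionSequence((Action(type=ActionType.NO_ACTION),))
    return ActionSequence(tuple(actions))


def extract_procedure(procedure: str, lexicon: Lexicon = DEFAULT_LEXICON) -> ActionSequence:
    """Extract actions for a whole procedure (sentence by sentence).

    Per-sentence extractions are concatenated in order; cross-sentence
    post-processing then resolves unspecified Filter phases from the
    following work-up actions.
    """
    actions: list[Action] = []
    for span in split_sentences(procedure):
        actions.extend(extract_sentence(span.text, lexicon))
    return ActionSequence(tuple(_fill_filter_phase(actions)))
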