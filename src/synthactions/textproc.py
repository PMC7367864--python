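"""Text preprocessing for experimental procedures.

Procedures are normalized (unicode NFKC, whitespace collapsed), split into
sentences with an abbreviation-aware splitter, and scanned for the entities
that matter to action extraction: compound names, quantities, temperatures,
durations, atmospheres, pH values, and yield percentages.  Recognition is
pattern- and dictionary-based — deterministic and dependency-free — rather
than a trained chemical NER.

Entity spans are character offsets on the normalized sentence, 0-based and
half-open, so ``sentence[tag.start:tag.end]`` reproduces the surface text.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass
from typing import Optional


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

_CHAR_FIXES = {
    "−": "-",  # minus sign
    "’": "'",
    "‘": "'",
    "“": '"',
    "”": '"',
    "℃": "°C",  # ℃
    "º": "°",  # masculine ordinal used as degree
    "∘": "°",  # ring operator used as degree
}


def normalize_text(text: str) -> str:
    """NFKC-normalize, fix common unicode variants, collapse whitespace."""
    out = unicodedata.normalize("NFKC", text)
    for src, dst in _CHAR_FIXES.items():
        out = out.replace(src, dst)
    out = re.sub(r"\s+", " ", out)
    return out.strip()


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence of a procedure and its position."""

    text: str
    index: int


#: Tokens after which a period does not end a sentence.
_ABBREVIATIONS = {
    "aq",
    "conc",
    "e.g",
    "i.e",
    "ca",
    "approx",
    "anal",
    "calcd",
    "vs",
    "wt",
    "equiv",
    "sat",
    "satd",
    "dil",
    "dec",
    "temp",
    "mp",
    "m.p",
    "b.p",
    "cf",
    "ref",
    "vol",
    "et al",
    "no",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def _is_abbreviation(prefix: str) -> bool:
    m = re.search(r"(\S+)$", prefix)
    if not m:
        return False
    token = m.group(1).rstrip(".").lower()
    return token in _ABBREVIATIONS


def split_sentences(procedure: str) -> list[SentenceSpan]:
    """Split a procedure into sentences.

    Deterministic and abbreviation-aware: no split after known
    abbreviations, on decimal points (no whitespace follows), or when the
    next word is lowercase (e.g. the mid-sentence ``"... at 30 °C. was
    treated ..."`` artifact common in patent text).
    """
    text = normalize_text(procedure)
    if not text:
        return []
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        rest = text[end:].lstrip()
        if not rest:
            continue
        if not (rest[0].isupper() or rest[0].isdigit()):
            continue
        if _is_abbreviation(text[: m.start()]):
            continue
        cuts.append(end)
    pieces: list[str] = []
    start = 0
    for cut in cuts:
        pieces.append(text[start:cut].strip())
        start = cut
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [SentenceSpan(text=p, index=i) for i, p in enumerate(pieces) if p]


# ---------------------------------------------------------------------------
# Entity tagging
# ---------------------------------------------------------------------------


class EntityLabel(str, enum.Enum):
    COMPOUND = "COMPOUND"
    QUANTITY = "QUANTITY"
    TEMPERATURE = "TEMPERATURE"
    DURATION = "DURATION"
    ATMOSPHERE = "ATMOSPHERE"
    PH_VALUE = "PH_VALUE"
    YIELD_PCT = "YIELD_PCT"


@dataclass(frozen=True)
class EntityTag:
    """A labelled half-open character span on the normalized sentence."""

    start: int
    end: int
    label: EntityLabel
    value: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


_TEMPERATURE_RE = re.compile(
    r"""(?:about\s+)?
        (?:-\s?)?\d+(?:\.\d+)?(?:\s*[–\-]\s*\d+(?:\.\d+)?)?\s*°\s*[CF]
        |room\s+temperature|ambient\s+temperature|\bRT\b|\br\.t\.""",
    re.VERBOSE,
)

_DURATION_RE = re.compile(
    r"""(?:about\s+|approximately\s+)?
        \d+(?:\.\d+)?(?:\s*[–\-]\s*\d+(?:\.\d+)?)?\s*
        (?:additional\s+)?
        (?:h(?:ours?|rs?)?|min(?:utes?|s)?|sec(?:onds?)?|days?|weeks?)\b
        |overnight""",
    re.VERBOSE,
)

_ATMOSPHERE_GASES = (
    "nitrogen|argon|air|hydrogen|oxygen|carbon\\s+monoxide|N2|Ar|H2|O2|CO"
)
_ATMOSPHERE_RE = re.compile(
    rf"""(?:under|in)\s+(?:an?\s+)?(?:atmosphere\s+of\s+)?
         (?P<gas>{_ATMOSPHERE_GASES})(?:\s+atmosphere)?
         |purged?\s+with\s+(?P<gas2>{_ATMOSPHERE_GASES})""",
    re.VERBOSE | re.IGNORECASE,
)

_PH_RE = re.compile(r"pH\s*(?:=|of|to)?\s*(?P<value>\d+(?:\.\d+)?)")

_YIELD_RE = re.compile(r"(?P<value>\d+(?:\.\d+)?)\s*%(?=\s*(?:yield|\)))")

# quantity inside parentheses: "(6.00 g, 14.7 mmol)" — delegated to
# action_string.is_quantity_group so both modules agree on what a quantity is
from .action_string import _QTY_TOKEN, is_quantity_group  # noqa: E402

_INLINE_QTY_RE = re.compile(
    r"""\b\d+(?:\.\d+)?\s*
        (?:g|mg|kg|µg|ug|mL|ml|µL|uL|L|mol|mmol|µmol|umol|mole|moles|
           equiv(?:alents)?|eq)\b(?:\s+of\b)?""",
    re.VERBOSE,
)

_PAREN_RE = re.compile(r"\(([^()]*)\)")

#: Common solvents / work-up reagents recognized by dictionary.
SOLVENT_DICTIONARY = frozenset(
    {
        "water",
        "brine",
        "methanol",
        "ethanol",
        "meoh",
        "etoh",
        "dcm",
        "dichloromethane",
        "dichloroethane",
        "chloroform",
        "thf",
        "tetrahydrofuran",
        "etoac",
        "ethyl acetate",
        "hexane",
        "n-hexane",
        "hexanes",
        "heptane",
        "ether",
        "diethyl ether",
        "et2o",
        "toluene",
        "benzene",
        "acetone",
        "acetonitrile",
        "mecn",
        "dmf",
        "dmso",
        "dioxane",
        "pentane",
        "isopropanol",
        "ipa",
        "benzotrifluoride",
        "xylene",
        "sodium sulfate",
        "magnesium sulfate",
        "na2so4",
        "mgso4",
        "silica gel",
        "celite",
    }
)

_NAME_STOPWORDS = frozenset(
    {
        "a",
        "an",
        "the",
        "was",
        "were",
        "is",
        "are",
        "be",
        "been",
        "being",
        "of",
        "in",
        "with",
        "to",
        "and",
        "or",
        "by",
        "from",
        "over",
        "at",
        "under",
        "into",
        "onto",
        "for",
        "on",
        "then",
        "added",
        "using",
        "via",
        "as",
        "after",
        "before",
        "during",
        "followed",
        "give",
        "afford",
        "yield",
        "obtain",
        "containing",
        "solution",
        "suspension",
        "mixture",
        "slurry",
        "residue",
        "reaction",
    }
)

_CHEMICAL_SUFFIX_RE = re.compile(
    r"(?:yl|ide|ate|ane|ene|yne|ine|ol|one|ose|ium|acid|amine|aniline|"
    r"ether|ester|oxide|borohydride|hydride|chloride|bromide|iodide|"
    r"fluoride|sulfate|sulfonate|carbonate|hydroxide|phosphate|nitrate|"
    r"acetate)$",
    re.IGNORECASE,
)


def _looks_chemical(token: str) -> bool:
    t = token.strip(",.;:")
    if not t or t.lower() in _NAME_STOPWORDS:
        return False
    if re.search(r"\d", t) and re.search(r"[A-Za-z]", t) and "-" in t:
        return True
    return bool(_CHEMICAL_SUFFIX_RE.search(t))


def _compound_before(sentence: str, pos: int) -> Optional[tuple[int, int]]:
    """Walk back from ``pos`` over the compound-name noun phrase."""
    left = sentence[:pos].rstrip()
    end = len(left)
    # words are consumed right-to-left until a stopword or punctuation
    tokens = []
    i = end
    while i > 0:
        m = re.search(r"(\S+)\s*$", left[:i])
        if not m:
            break
        word = m.group(1)
        bare = word.strip(",.;:")
        if not bare or bare.lower() in _NAME_STOPWORDS or bare in (";", ","):
            break
        if word.endswith((",", ";", ":")):
            break
        tokens.insert(0, (m.start(1), m.start(1) + len(word)))
        i = m.start(1)
    if not tokens:
        return None
    start = tokens[0][0]
    return (start, end)


def tag_entities(sentence: str) -> list[EntityTag]:
    """Tag quantities, temperatures, durations, atmospheres, pH values,
    yield percentages, and compound names in one (normalized) sentence.

    Later labels never overlap an earlier tag of the same label; compounds
    are found next to quantity parentheses, via the solvent dictionary, and
    by chemical-looking token heuristics.
    """
    s = normalize_text(sentence)
    tags: list[EntityTag] = []
    taken: list[tuple[int, int]] = []

    def free(start: int, end: int) -> bool:
        return all(end <= a or start >= b for a, b in taken)

    def add(start: int, end: int, label: EntityLabel, value: str) -> None:
        if start < end and free(start, end):
            tags.append(EntityTag(start, end, label, value))
            taken.append((start, end))

    for m in _TEMPERATURE_RE.finditer(s):
        add(m.start(), m.end(), EntityLabel.TEMPERATURE, m.group(0))
    for m in _PH_RE.finditer(s):
        add(m.start(), m.end(), EntityLabel.PH_VALUE, m.group("value"))
    for m in _ATMOSPHERE_RE.finditer(s):
        gas = m.group("gas") or m.group("gas2")
        add(m.start(), m.end(), EntityLabel.ATMOSPHERE, gas)
    for m in _DURATION_RE.finditer(s):
        add(m.start(), m.end(), EntityLabel.DURATION, m.group(0))
    for m in _YIELD_RE.finditer(s):
        add(m.start(), m.end(), EntityLabel.YIELD_PCT, m.group("value"))

    compound_anchors: list[int] = []
    for m in _PAREN_RE.finditer(s):
        if not is_quantity_group(m.group(1)):
            continue
        offset = m.start(1)
        for part_m in re.finditer(r"[^,]+", m.group(1)):
            part = part_m.group(0).strip()
            lead = len(part_m.group(0)) - len(part_m.group(0).lstrip())
            start = offset + part_m.start() + lead
            add(start, start + len(part), EntityLabel.QUANTITY, part)
        compound_anchors.append(m.start())
    for m in _INLINE_QTY_RE.finditer(s):
        qty = m.group(0)
        trailing_of = qty.endswith("of")
        end = m.end() - 3 if trailing_of else m.end()
        add(m.start(), end, EntityLabel.QUANTITY, s[m.start():end])
        if trailing_of:
            compound_anchors.append(-m.end())  # negative: compound follows

    # compounds adjacent to quantity groups
    for anchor in compound_anchors:
        if anchor >= 0:
            span = _compound_before(s, anchor)
            if span and free(*span):
                add(span[0], span[1], EntityLabel.COMPOUND, s[span[0]:span[1]])
        else:
            pos = -anchor
            m = re.match(r"\s*([^,;.()]+?)(?=\s+(?:was|were|is|are|in)\b|[,;.]|$)", s[pos:])
            if m:
                start = pos + m.start(1)
                add(start, start + len(m.group(1)), EntityLabel.COMPOUND, m.group(1))

    # dictionary solvents
    for name in sorted(SOLVENT_DICTIONARY, key=len, reverse=True):
        for m in re.finditer(rf"\b{re.escape(name)}\b", s, re.IGNORECASE):
            add(m.start(), m.end(), EntityLabel.COMPOUND, m.group(0))

    # chemical-looking tokens
    for m in re.finditer(r"[A-Za-z0-9][\w\[\]()'\-]*", s):
        if _looks_chemical(m.group(0)) and free(m.start(), m.end()):
            add(m.start(), m.end(), EntityLabel.COMPOUND, m.group(0))

    tags.sort(key=lambda t: (t.start, t.end))
    return tags


# ---------------------------------------------------------------------------
# Compound relationships
# ---------------------------------------------------------------------------

Relation = tuple[str, str, str]

_SOLUTION_OF_RE = re.compile(
    r"(?:a|the)\s+(?:solution|suspension|mixture|slurry)\s+of\s+(?P<body>.+?)"
    r"(?=\s+(?:was|were|is|are)\b|[;.]|$)",
    re.IGNORECASE,
)

_TO_X_ADDED_Y_RE = re.compile(
    r"^To\s+(?P<target>.+?)\s+(?:was|were|is|are)\s+added\s+(?P<added>.+?)"
    r"(?=\s+(?:at|under|over|dropwise)\b|[,;.]|$)",
    re.IGNORECASE,
)

_Y_ADDED_TO_X_RE = re.compile(
    r"^(?P<added>.+?)\s+(?:was|were|is|are)\s+added\s+(?:dropwise\s+)?to\s+"
    r"(?P<target>.+?)(?=\s+(?:at|under|dropwise)\b|[,;.]|$)",
    re.IGNORECASE,
)


def _strip_np(text: str) -> str:
    """Reduce a noun phrase to its head compound name."""
    t = text.strip().strip(",.;")
    t = re.sub(r"^(?:a|an|the)\s+", "", t, flags=re.IGNORECASE)
    t = re.sub(
        r"^(?:solution|suspension|mixture|slurry)\s+of\s+",
        "",
        t,
        flags=re.IGNORECASE,
    )
    t = re.sub(r"\s*\([^()]*\)\s*$", "", t)  # trailing quantity group
    t = re.sub(r"\s+in\s+.+$", "", t, flags=re.IGNORECASE)
    return t.strip()


def compound_relationships(sentence: str, tags: Optional[list[EntityTag]] = None) -> list[Relation]:
    """Extract (mention, relation, mention) triples from one sentence.

    Emits ``SOLUTE_IN`` for "a solution of X in Z" constructions and
    ``ADDED_TO`` ordered pairs; "To X is added Y" and "Y is added to X"
    resolve to the same ``(Y, ADDED_TO, X)``.  Ambiguous attachments yield
    no relation.
    """
    s = normalize_text(sentence)
    if len(s) > 1 and s[0].isupper() and s[1].islower():
        s = s[0].lower() + s[1:]  # sentence-initial capitalization
    relations: list[Relation] = []

    for m in _SOLUTION_OF_RE.finditer(s):
        body = m.group("body")
        in_split = re.split(r"\s+in\s+", body, maxsplit=1, flags=re.IGNORECASE)
        if len(in_split) != 2:
            continue
        solutes_text, solvent_text = in_split
        solvent = _strip_np(re.split(r"\s+(?:was|were|is|are)\s+", solvent_text)[0])
        for solute in re.split(r"\s+and\s+|,\s*", solutes_text):
            name = _strip_np(solute)
            if name and solvent:
                relations.append((name, "SOLUTE_IN", solvent))

    m = _TO_X_ADDED_Y_RE.match(s) or _Y_ADDED_TO_X_RE.match(s)
    if m:
        added = _strip_np(m.group("added"))
        target = _strip_np(m.group("target"))
        if added and target:
            relations.append((added, "ADDED_TO", target))

    return relations
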