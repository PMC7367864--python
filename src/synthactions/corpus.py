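"""Corpus construction for pretraining and refinement.

Paired samples (sentence, action sequence, provenance) are built from two
rule-based sources: the custom NLP extractor and an adapter for legacy
action records whose property set is not operation-specific (one common
schema for all types).  The two are combined conservatively — the legacy
side is only trusted for its Yield actions, which it extracts better than
the sentence-level rules.  Pretraining pairs are then filtered (InvalidAction
dropped; long non-analytical NoAction dropped; duplicate sentences removed)
and split reproducibly at sentence level.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .actions import (
    Action,
    ActionSequence,
    ActionType,
    ChemicalMention,
    Condition,
    Quantity,
    action_type_from_name,
    allowed_properties,
    sequence_from_dict,
    sequence_to_dict,
)
from . import action_string
from .extractor import ANALYSIS_KEYWORDS, DEFAULT_LEXICON, Lexicon


class SampleSource(str, enum.Enum):
    RULE_NLP = "rule_nlp"
    LEGACY = "legacy"
    COMBINED = "combined"
    ANNOTATION = "annotation"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class PairedSample:
    """One corpus unit: a sentence and its ground-truth action sequence."""

    sentence: str
    actions: ActionSequence
    source: SampleSource = SampleSource.SYNTHETIC

    def __post_init__(self) -> None:
        if not self.sentence or not self.sentence.strip():
            raise ValueError("PairedSample.sentence must be non-empty")

    @property
    def action_string(self) -> str:
        return action_string.serialize(self.actions)


# ---------------------------------------------------------------------------
# Legacy (one-schema-per-all-types) action records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LegacyActionRecord:
    """An action record in the legacy format: a free-form action name plus
    a property set common to all action types."""

    action_name: str
    compounds: tuple[tuple[str, tuple[str, ...]], ...] = ()
    temperature: Optional[str] = None
    duration: Optional[str] = None
    atmosphere: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "LegacyActionRecord":
        compounds = tuple(
            (c["name"], tuple(c.get("quantities", ())))
            for c in d.get("compounds", ())
        )
        return cls(
            action_name=d["action_name"],
            compounds=compounds,
            temperature=d.get("temperature"),
            duration=d.get("duration"),
            atmosphere=d.get("atmosphere"),
        )


#: Legacy action names with a direct equivalent.
_LEGACY_NAME_MAP = {
    "add": ActionType.ADD,
    "stir": ActionType.STIR,
    "concentrate": ActionType.CONCENTRATE,
    "evaporate": ActionType.CONCENTRATE,
    "wash": ActionType.WASH,
    "filter": ActionType.FILTER,
    "extract": ActionType.EXTRACT,
    "purify": ActionType.PURIFY,
    "yield": ActionType.YIELD,
    "quench": ActionType.QUENCH,
    "reflux": ActionType.REFLUX,
    "wait": ActionType.WAIT,
    "recrystallize": ActionType.RECRYSTALLIZE,
    "partition": ActionType.PARTITION,
    "degas": ActionType.DEGAS,
    "sonicate": ActionType.SONICATE,
    "triturate": ActionType.TRITURATE,
    "microwave": ActionType.MICROWAVE,
    "makesolution": ActionType.MAKE_SOLUTION,
    "collectlayer": ActionType.COLLECT_LAYER,
    "phaseseparation": ActionType.PHASE_SEPARATION,
    "settemperature": ActionType.SET_TEMPERATURE,
}

#: Heat-like legacy records: attached compounds become Add actions
#: prepended to the resulting Stir (duration given) or SetTemperature.
_LEGACY_HEAT_NAMES = {"heat", "warm", "cool"}


def _legacy_mentions(record: LegacyActionRecord) -> list[ChemicalMention]:
    return [
        ChemicalMention(name=name, quantities=tuple(Quantity(q) for q in qtys))
        for name, qtys in record.compounds
    ]


def _legacy_condition(record: LegacyActionRecord, atype: ActionType) -> Condition:
    allowed = allowed_properties(atype)
    return Condition(
        temperature=record.temperature if "temperature" in allowed else None,
        duration=record.duration if "duration" in allowed else None,
        atmosphere=record.atmosphere if "atmosphere" in allowed else None,
    )


def adapt_legacy(records: Sequence[LegacyActionRecord]) -> ActionSequence:
    """Convert legacy records to the operation-specific action model."""
    actions: list[Action] = []
    for record in records:
        key = record.action_name.strip().lower()
        if key in _LEGACY_HEAT_NAMES:
            for m in _legacy_mentions(record):
                actions.append(Action(type=ActionType.ADD, materials=(m,)))
            if record.duration is not None:
                atype = ActionType.STIR
            else:
                atype = ActionType.SET_TEMPERATURE
            if atype is ActionType.SET_TEMPERATURE and record.temperature is None:
                actions.append(Action(type=ActionType.INVALID_ACTION))
            else:
                actions.append(Action(type=atype, condition=_legacy_condition(record, atype)))
            continue
        atype = _LEGACY_NAME_MAP.get(key)
        if atype is None:
            actions.append(Action(type=ActionType.INVALID_ACTION))
            continue
        mentions = _legacy_mentions(record)
        allowed = allowed_properties(atype)
        lo_hi = (0, None)
        from .actions import MATERIAL_ARITY

        lo_hi = MATERIAL_ARITY.get(atype, (0, 0))
        materials: tuple[ChemicalMention, ...] = ()
        if "materials" in allowed and mentions:
            hi = lo_hi[1]
            materials = tuple(mentions[: hi if hi is not None else len(mentions)])
        action = Action(
            type=atype,
            materials=materials,
            condition=_legacy_condition(record, atype),
        )
        from .actions import validate_action

        actions.append(action if validate_action(action).ok else Action(type=ActionType.INVALID_ACTION))
    return ActionSequence(tuple(actions))


def combine_sources(nlp_seq: ActionSequence, legacy_seq: ActionSequence) -> ActionSequence:
    """Append legacy Yield actions to the NLP extraction (nothing else).

    Yields already present in the NLP sequence (by serialized equality) are
    not duplicated; the NLP sequence is always a prefix of the result.
    """
    existing = {
        action_string._serialize_action(a)
        for a in nlp_seq
        if a.type is ActionType.YIELD
    }
    extra = [
        a
        for a in legacy_seq
        if a.type is ActionType.YIELD
        and action_string._serialize_action(a) not in existing
    ]
    return ActionSequence(tuple(nlp_seq) + tuple(extra))


# ---------------------------------------------------------------------------
# Filtering, splitting, hard-sentence selection
# ---------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def _normalized_sentence(s: str) -> str:
    return _WS_RE.sub(" ", s).strip()


_ANALYSIS_KEYWORD_RE = re.compile(
    "|".join(re.escape(k) for k in ANALYSIS_KEYWORDS), re.IGNORECASE
)


def filter_pretraining(samples: Sequence[PairedSample]) -> list[PairedSample]:
    """Filter pairs before pretraining.

    Drops samples containing InvalidAction; drops NoAction samples whose
    sentence exceeds 30 characters and carries no analysis keyword; then
    removes duplicate sentences keeping the first occurrence.
    """
    out: list[PairedSample] = []
    seen: set[str] = set()
    for sample in samples:
        types = sample.actions.types()
        if ActionType.INVALID_ACTION in types:
            continue
        if types == [ActionType.NO_ACTION]:
            sentence = sample.sentence.strip()
            if len(sentence) > 30 and not _ANALYSIS_KEYWORD_RE.search(sentence):
                continue
        key = _normalized_sentence(sample.sentence)
        if key in seen:
            continue
        seen.add(key)
        out.append(sample)
    return out


def split_dataset(
    samples: Sequence[PairedSample],
    fractions: tuple[float, float, float] = (0.785, 0.107, 0.107),
    seed: int = 0,
) -> tuple[list[PairedSample], list[PairedSample], list[PairedSample]]:
    """Split into (train, valid, test) at sentence level, reproducibly.

    Fractions must sum to 1 (within rounding).  Samples sharing a sentence
    always land in the same split.
    """
    import random

    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    groups: dict[str, list[PairedSample]] = {}
    order: list[str] = []
    for sample in samples:
        key = _normalized_sentence(sample.sentence)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sample)
    rng = random.Random(seed)
    rng.shuffle(order)
    n = len(samples)
    sizes = [int(f * n) for f in fractions]
    for i in sorted(range(3), key=lambda i: fractions[i] * n - sizes[i], reverse=True):
        if sum(sizes) < n:
            sizes[i] += 1
    splits: tuple[list[PairedSample], ...] = ([], [], [])
    idx = 0
    for key in order:
        while idx < 2 and len(splits[idx]) >= sizes[idx]:
            idx += 1
        splits[idx].extend(groups[key])
    return splits


_CONTEXT_DEPENDENT_FORMS = re.compile(
    r"\b(?:heat(?:ed|ing|s)?|remov(?:e|ed|ing|es)|treat(?:ed|ing|s)?)\b",
    re.IGNORECASE,
)


def select_hard_sentences(samples: Sequence[PairedSample]) -> list[PairedSample]:
    """Pick sentences the rule-based extraction struggles with.

    Flags sentences containing highly context-dependent verbs (heat /
    remove / treat), the literal phrase "followed by", or extractions in
    which the same compound name occurs in more than one action.
    """
    out: list[PairedSample] = []
    for sample in samples:
        hard = False
        if "followed by" in sample.sentence.lower():
            hard = True
        elif _CONTEXT_DEPENDENT_FORMS.search(sample.sentence):
            hard = True
        else:
            seen: set[str] = set()
            for action in sample.actions:
                for m in action.materials:
                    name = m.name.lower()
                    if name == "sln":
                        continue
                    if name in seen:
                        hard = True
                    seen.add(name)
        if hard:
            out.append(sample)
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_tsv(samples: Iterable[PairedSample], path: str) -> None:
    """sentence TAB action-string, one sample per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for sample in samples:
            fh.write(f"{sample.sentence}\t{sample.action_string}\n")


def read_tsv(path: str, source: SampleSource = SampleSource.SYNTHETIC) -> list[PairedSample]:
    out: list[PairedSample] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sentence, _, actions = line.partition("\t")
            out.append(
                PairedSample(
                    sentence=sentence,
                    actions=action_string.parse(actions),
                    source=source,
                )
            )
    return out


def write_jsonl(samples: Iterable[PairedSample], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample in samples:
            record = {
                "sentence": sample.sentence,
                "actions": sequence_to_dict(sample.actions),
                "source": sample.source.value,
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_jsonl(path: str) -> list[PairedSample]:
    out: list[PairedSample] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                PairedSample(
                    sentence=d["sentence"],
                    actions=sequence_from_dict(d["actions"]),
                    source=SampleSource(d.get("source", "synthetic")),
                )
            )
    return out


def read_legacy_jsonl(path: str) -> list[tuple[str, list[LegacyActionRecord]]]:
    """Read legacy records: one JSON object per line with a "sentence" and
    an "actions" array in the legacy common-property schema."""
    out: list[tuple[str, list[LegacyActionRecord]]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            records = [LegacyActionRecord.from_dict(r) for r in d.get("actions", ())]
            out.append((d["sentence"], records))
    return out


def build_combined_corpus(
    sentences: Sequence[str],
    legacy: Optional[Sequence[Sequence[LegacyActionRecord]]] = None,
    lexicon: Lexicon = DEFAULT_LEXICON,
) -> list[PairedSample]:
    """Run the rule extractor over sentences and merge legacy Yields."""
    from .extractor import extract_sentence

    out: list[PairedSample] = []
    for i, sentence in enumerate(sentences):
        seq = extract_sentence(sentence, lexicon)
        source = SampleSource.RULE_NLP
        if legacy is not None and i < len(legacy) and legacy[i]:
            seq = combine_sources(seq, adapt_legacy(legacy[i]))
            source = SampleSource.COMBINED
        if len(seq) == 0:
            continue
        out.append(PairedSample(sentence=sentence, actions=seq, source=source))
    return out
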