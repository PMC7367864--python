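"""Entity-substitution data augmentation of paired samples.

Annotated corpora for refinement are small; augmentation multiplies them by
substituting compound names, quantities, durations and temperatures with
draws from substitution pools, each tagged entity independently with a
configurable probability (default 0.5).  The same substitution is applied
to the sentence and to its action string, so sentence/action alignment is
preserved by construction.  Substitution is deliberately not chemistry
aware: implausible combinations are acceptable because the model must learn
the sentence structure, not the chemistry.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field

from . import action_string
from .corpus import PairedSample, SampleSource
from .textproc import EntityLabel, EntityTag, normalize_text, tag_entities

#: Entity labels subject to substitution.
SUBSTITUTABLE = (
    EntityLabel.COMPOUND,
    EntityLabel.QUANTITY,
    EntityLabel.DURATION,
    EntityLabel.TEMPERATURE,
)


@dataclass(frozen=True)
class SubstitutionPools:
    """Replacement pools, one per substitutable entity class."""

    compounds: tuple[str, ...] = ()
    quantities: tuple[str, ...] = ()
    durations: tuple[str, ...] = ()
    temperatures: tuple[str, ...] = ()

    def pool_for(self, label: EntityLabel) -> tuple[str, ...]:
        return {
            EntityLabel.COMPOUND: self.compounds,
            EntityLabel.QUANTITY: self.quantities,
            EntityLabel.DURATION: self.durations,
            EntityLabel.TEMPERATURE: self.temperatures,
        }[label]

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "compounds": list(self.compounds),
                    "quantities": list(self.quantities),
                    "durations": list(self.durations),
                    "temperatures": list(self.temperatures),
                },
                fh,
                ensure_ascii=False,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "SubstitutionPools":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            compounds=tuple(d.get("compounds", ())),
            quantities=tuple(d.get("quantities", ())),
            durations=tuple(d.get("durations", ())),
            temperatures=tuple(d.get("temperatures", ())),
        )


class EmptyPoolError(ValueError):
    pass


def _boundary_sub(text: str, old: str, new: str) -> str:
    """Replace whole-entity occurrences (no digit/letter context bleed)."""
    pattern = r"(?<![\w.])" + re.escape(old) + r"(?![\w.])"
    return re.sub(pattern, new.replace("\\", "\\\\"), text)


def substitutable_entities(sentence: str) -> list[EntityTag]:
    """The tags of a sentence eligible for substitution."""
    return [t for t in tag_entities(sentence) if t.label in SUBSTITUTABLE]


def augment_sample(
    sample: PairedSample,
    pools: SubstitutionPools,
    p: float = 0.5,
    seed: int = 0,
) -> PairedSample:
    """One augmented variant of a sample.

    Every distinct taggable entity surface is replaced with probability
    ``p`` by a draw from the pool of its class; the identical substitution
    is applied to the sentence and to the action string.  Tags sharing the
    same surface string share one decision, which keeps the two sides
    aligned.  Deterministic for a given (sample, seed).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    rng = random.Random(seed)
    sentence = normalize_text(sample.sentence)
    # sentence-initial capitalization is orthographic; fold it so an initial
    # entity surface matches its action-string counterpart
    if len(sentence) > 1 and sentence[0].isupper() and sentence[1].islower():
        sentence = sentence[0].lower() + sentence[1:]
    actions_text = sample.action_string
    tags = substitutable_entities(sentence)

    decisions: dict[tuple[EntityLabel, str], str | None] = {}
    for tag in tags:
        surface = sentence[tag.start : tag.end]
        key = (tag.label, surface)
        if key in decisions:
            continue
        if rng.random() < p:
            pool = pools.pool_for(tag.label)
            if not pool:
                raise EmptyPoolError(f"empty pool for {tag.label.value}")
            # a substitution replaces the entity with a *different* string
            candidates = [x for x in pool if x != surface]
            decisions[key] = (
                candidates[rng.randrange(len(candidates))] if candidates else None
            )
        else:
            decisions[key] = None

    # apply right-to-left so earlier spans stay valid
    new_sentence = sentence
    for tag in sorted(tags, key=lambda t: t.start, reverse=True):
        surface = sentence[tag.start : tag.end]
        replacement = decisions[(tag.label, surface)]
        if replacement is None:
            continue
        new_sentence = new_sentence[: tag.start] + replacement + new_sentence[tag.end :]
    for (label, surface), replacement in decisions.items():
        if replacement is not None:
            actions_text = _boundary_sub(actions_text, surface, replacement)

    result = action_string.try_parse(actions_text)
    if not result.ok:
        # substitution broke the action grammar (e.g. a replacement clashing
        # with a keyword) — keep the original sample rather than emit garbage
        return sample
    return PairedSample(
        sentence=new_sentence, actions=result.sequence, source=sample.source
    )


def augment_corpus(
    samples: list[PairedSample],
    pools: SubstitutionPools,
    p: float = 0.5,
    n_target: int = 20_000,
    dedup: bool = False,
    seed: int = 0,
) -> list[PairedSample]:
    """Grow a corpus to ``n_target`` samples by repeated augmentation.

    The originals come first, then augmented variants cycling over the
    input.  With ``dedup`` duplicates (sentence, action string) are removed
    afterwards, so the output may be smaller than ``n_target`` (the
    "augmented unique" variant).
    """
    if n_target < len(samples):
        raise ValueError("n_target must be >= len(samples)")
    rng = random.Random(seed)
    out = list(samples)
    i = 0
    while len(out) < n_target:
        sample = samples[i % len(samples)]
        out.append(augment_sample(sample, pools, p=p, seed=rng.randrange(2**31)))
        i += 1
    if dedup:
        seen: set[tuple[str, str]] = set()
        unique: list[PairedSample] = []
        for sample in out:
            key = (sample.sentence, sample.action_string)
            if key in seen:
                continue
            seen.add(key)
            unique.append(sample)
        out = unique
    return out
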