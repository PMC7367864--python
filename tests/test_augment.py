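"""Entity-substitution augmentation: degenerate probabilities, alignment
preservation, determinism, pool errors."""

import pytest

from synthactions import PairedSample, SampleSource, parse
from synthactions.augment import (
    EmptyPoolError,
    SubstitutionPools,
    augment_corpus,
    augment_sample,
    substitutable_entities,
)

REFERENCE = PairedSample(
    sentence=(
        "diisopropylazodicarboxylate (0.05 ml, 0.302 mmol) was added to the "
        "reaction mixture followed by stirring for 3 h at room temperature."
    ),
    actions=parse(
        "Add diisopropylazodicarboxylate (0.05 ml, 0.302 mmol); "
        "Stir for 3 h at room temperature"
    ),
    source=SampleSource.ANNOTATION,
)


def test_reference_sentence_has_substitutable_entities():
    labels = {t.label.value for t in substitutable_entities(REFERENCE.sentence)}
    assert labels == {"COMPOUND", "QUANTITY", "DURATION", "TEMPERATURE"}


def test_p_zero_is_identity(pools):
    out = augment_sample(REFERENCE, pools, p=0.0, seed=5)
    assert out.sentence == REFERENCE.sentence
    assert out.actions == REFERENCE.actions


def test_p_one_substitutes_every_entity(pools):
    out = augment_sample(REFERENCE, pools, p=1.0, seed=5)
    assert out.sentence != REFERENCE.sentence
    # none of the original entity surfaces survive
    for tag in substitutable_entities(REFERENCE.sentence):
        surface = REFERENCE.sentence[tag.start : tag.end]
        if surface in pools.pool_for(tag.label):
            continue  # a replacement could coincide with the original pool item
        assert surface not in out.sentence


def test_variants_mirror_sentence_and_actions(pools):
    # substituted entities appear identically on both sides
    for seed in range(20):
        out = augment_sample(REFERENCE, pools, p=0.5, seed=seed)
        text = out.action_string
        for action in out.actions:
            for m in action.materials:
                assert m.name in out.sentence
                for q in m.quantities:
                    assert q.raw in out.sentence
            c = action.condition
            for value in (c.temperature, c.duration):
                if value is not None:
                    assert value in out.sentence
        assert text  # still serializable


def test_seed_determinism(pools):
    a = augment_sample(REFERENCE, pools, p=0.5, seed=123)
    b = augment_sample(REFERENCE, pools, p=0.5, seed=123)
    assert a == b


def test_distinct_seeds_produce_distinct_variants(pools):
    variants = {augment_sample(REFERENCE, pools, p=0.5, seed=s).sentence for s in range(8)}
    assert len(variants) >= 4


def test_empty_pool_raises(pools):
    empty = SubstitutionPools(
        compounds=(), quantities=pools.quantities, durations=pools.durations,
        temperatures=pools.temperatures,
    )
    with pytest.raises(EmptyPoolError):
        augment_sample(REFERENCE, empty, p=1.0, seed=1)


def test_invalid_probability_rejected(pools):
    with pytest.raises(ValueError):
        augment_sample(REFERENCE, pools, p=1.5, seed=0)


class TestAugmentCorpus:
    def test_grows_to_target(self, pools, small_corpus):
        out = augment_corpus(small_corpus[:50], pools, p=0.5, n_target=300, seed=2)
        assert len(out) == 300
        assert out[:50] == small_corpus[:50]  # originals first

    def test_dedup_never_exceeds_target(self, pools, small_corpus):
        out = augment_corpus(
            small_corpus[:50], pools, p=0.5, n_target=300, dedup=True, seed=2
        )
        assert len(out) <= 300
        keys = [(s.sentence, s.action_string) for s in out]
        assert len(keys) == len(set(keys))

    def test_identity_when_target_equals_input(self, pools, small_corpus):
        samples = small_corpus[:30]
        out = augment_corpus(samples, pools, p=0.0, n_target=30, seed=0)
        assert out == samples

    def test_target_below_input_rejected(self, pools, small_corpus):
        with pytest.raises(ValueError):
            augment_corpus(small_corpus[:30], pools, p=0.5, n_target=10, seed=0)
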