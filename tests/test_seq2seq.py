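"""Translation harness: subword vocabulary, delexicalization, training
determinism, beam decoding, checkpoint selection, ensembles.

Training here is deliberately tiny (a few hundred steps); the full
scaled-down grammar-recovery experiment lives in the acceptance tests.
"""

import numpy as np
import pytest

from synthactions import (
    ActionType,
    GeneratorConfig,
    ModelConfig,
    build_vocabulary,
    ensemble_translate,
    generate_corpus,
    load_model,
    predict_actions,
    pretrain,
    save_model,
    select_best_checkpoint,
    translate,
)
from synthactions.seq2seq import Checkpoint, SubwordVocab, delexicalize, relexicalize


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(GeneratorConfig(seed=31, n_samples=120))


@pytest.fixture(scope="module")
def tiny_model(corpus):
    cfg = ModelConfig.desk_scale(seed=2, train_steps=150, checkpoint_every=75)
    return pretrain(corpus[:100], cfg, valid=corpus[100:110])


class TestVocabulary:
    def test_round_trips_every_training_sentence(self, corpus):
        vocab = build_vocabulary(corpus[:80], vocab_size=500)
        for sample in corpus[:80]:
            d = delexicalize(sample.sentence, sample.action_string)
            assert vocab.decode(vocab.encode(d.source)) == d.source
            assert vocab.decode(vocab.encode(d.target)) == d.target

    def test_deterministic(self, corpus):
        a = build_vocabulary(corpus[:50], vocab_size=400)
        b = build_vocabulary(corpus[:50], vocab_size=400)
        assert a == b

    def test_vocab_size_below_alphabet_is_error(self, corpus):
        with pytest.raises(ValueError):
            build_vocabulary(corpus[:50], vocab_size=10)

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            build_vocabulary([], vocab_size=100)

    def test_requested_size_is_upper_bound(self, corpus):
        vocab = build_vocabulary(corpus[:50], vocab_size=280)
        assert len(vocab) <= 280


class TestDelexicalization:
    def test_slots_shared_between_source_and_target(self, corpus):
        sample = corpus[0]
        d = delexicalize(sample.sentence, sample.action_string)
        for ph, surface in d.slots.items():
            assert ph in d.source
            assert surface not in d.source
        assert relexicalize(d.source, d.slots)  # placeholders resolve

    def test_relexicalize_inverts_target(self, corpus):
        for sample in corpus[:40]:
            d = delexicalize(sample.sentence, sample.action_string)
            assert relexicalize(d.target, d.slots) == sample.action_string


class TestTraining:
    def test_pretrain_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            pretrain([], ModelConfig.desk_scale())

    def test_training_curve_logged(self, tiny_model):
        assert tiny_model.history
        assert {"step", "loss", "validation_accuracy"} <= set(tiny_model.history[0])

    def test_checkpoints_carry_validation_accuracy(self, tiny_model):
        assert [c.step for c in tiny_model.checkpoints] == [75, 150]
        assert all(c.validation_accuracy is not None for c in tiny_model.checkpoints)

    def test_translate_deterministic(self, tiny_model, corpus):
        sentences = [s.sentence for s in corpus[100:105]]
        a = translate(tiny_model, sentences, beam_size=3, n_best=2)
        b = translate(tiny_model, sentences, beam_size=3, n_best=2)
        assert a == b

    def test_scores_sorted_descending(self, tiny_model, corpus):
        for candidates in translate(
            tiny_model, [corpus[100].sentence], beam_size=4, n_best=4
        ):
            scores = [s for _, s in candidates]
            assert scores == sorted(scores, reverse=True)

    def test_n_best_exceeding_beam_is_error(self, tiny_model):
        with pytest.raises(ValueError):
            translate(tiny_model, ["Add water."], beam_size=2, n_best=5)


class TestCheckpointSelection:
    def test_argmax_with_ties_to_latest(self, tiny_model):
        model = tiny_model.clone()
        w = model.engine.snapshot()
        model.checkpoints = [
            Checkpoint(step=100, validation_accuracy=0.5, weights=w),
            Checkpoint(
                step=200,
                validation_accuracy=0.9,
                weights=(w[0] * 2, w[1] + 1),
            ),
            Checkpoint(
                step=300,
                validation_accuracy=0.9,
                weights=(w[0] * 3, w[1] + 2),
            ),
        ]
        best = select_best_checkpoint(model)
        # accuracy tie between steps 200 and 300 → latest step wins
        assert np.allclose(best.engine.b, w[1].astype(np.float64) + 2)

    def test_unscored_checkpoints_keep_final_weights(self, tiny_model):
        model = tiny_model.clone()
        model.checkpoints = []
        assert select_best_checkpoint(model) is model


class TestEnsemble:
    def test_ensemble_of_identical_models_matches_single(self, tiny_model, corpus):
        sentences = [s.sentence for s in corpus[100:103]]
        single = translate(tiny_model, sentences, beam_size=2, n_best=1)
        double = ensemble_translate([tiny_model, tiny_model], sentences, beam_size=2, n_best=1)
        assert [c[0][0] for c in single] == [c[0][0] for c in double]

    def test_vocabulary_mismatch_is_error(self, tiny_model, corpus):
        other = pretrain(
            corpus[:30], ModelConfig.desk_scale(seed=3, train_steps=20, vocab_size=250)
        )
        with pytest.raises(ValueError, match="vocabulary"):
            ensemble_translate([tiny_model, other], ["Add water."])


def test_invalid_decodes_map_to_invalid_action(tiny_model, monkeypatch):
    import synthactions.seq2seq as s2s

    monkeypatch.setattr(
        s2s, "translate", lambda model, sentences, **kw: [[("Blorbify now", -1.0)]]
    )
    seqs = s2s.predict_actions(tiny_model, ["whatever"])
    assert seqs[0].types() == [ActionType.INVALID_ACTION]


def test_save_and_load_round_trip(tiny_model, corpus, tmp_path):
    path = tmp_path / "model.joblib"
    save_model(tiny_model, str(path))
    restored = load_model(str(path))
    sentences = [s.sentence for s in corpus[100:103]]
    assert translate(restored, sentences) == translate(tiny_model, sentences)
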