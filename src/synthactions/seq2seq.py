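"""Sequence-to-sequence translation protocol for action extraction.

Sentences are translated one at a time into action strings.  The protocol
follows the pretrain-and-refine recipe: a shared source/target subword
vocabulary is built from the training corpus, a model is pretrained on
pairs generated by the rule-based extractors, then training continues on a
small annotated corpus with periodic checkpoints; the checkpoint with the
highest validation exact-match accuracy is selected, several refined models
can be combined into an ensemble, and beam search returns the n best
candidate action sequences per sentence with scores.

The translation engine sits behind a narrow train/translate/save/load
interface so it is swappable.  The default engine is an autoregressive
log-linear model over subword tokens: entity delexicalization (compounds,
quantities, durations, temperatures become indexed placeholder tokens
shared by both sides) acts as the copy mechanism, and hashed features of
the target prefix and source tokens feed a softmax trained by SGD on the
categorical cross-entropy.  :class:`ModelConfig` also carries the
transformer hyperparameters (layers, hidden size, attention heads) as a
preset for neural engines plugged behind the same interface; the default
engine ignores them.
"""

from __future__ import annotations

import copy
import random
import re
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import action_string
from .actions import Action, ActionSequence, ActionType
from .augment import _boundary_sub
from .corpus import PairedSample
from .textproc import EntityLabel, normalize_text, tag_entities

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration.

    The architecture fields (layers, hidden/embedding size, attention
    heads, label smoothing, gradient accumulation) describe the reference
    transformer preset; the built-in log-linear engine uses the vocabulary,
    step, checkpoint and optimizer fields only.
    """

    layers: int = 4
    hidden_size: int = 256
    embedding_size: int = 256
    attention_heads: int = 8
    shared_source_target_vocab: bool = True
    label_smoothing: float = 0.0
    gradient_accumulation: int = 4
    vocab_size: int = 16000
    train_steps: int = 500_000
    checkpoint_every: int = 1000
    seed: int = 0
    # engine knobs
    batch_size: int = 64
    learning_rate: float = 0.5
    feature_dim: int = 2**14
    max_decode_len: int = 120

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Small CPU-trainable preset used throughout the test suite."""
        base = dict(
            layers=2,
            hidden_size=128,
            embedding_size=128,
            vocab_size=300,
            train_steps=2000,
            checkpoint_every=500,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Entity delexicalization (the copy mechanism)
# ---------------------------------------------------------------------------

_LABEL_PREFIX = {
    EntityLabel.COMPOUND: "C",
    EntityLabel.QUANTITY: "Q",
    EntityLabel.TEMPERATURE: "T",
    EntityLabel.DURATION: "D",
    EntityLabel.YIELD_PCT: "Y",
}
_MAX_SLOTS_PER_LABEL = 10

PLACEHOLDER_TOKENS = tuple(
    f"<{p}{i}>" for p in "CQTDY" for i in range(_MAX_SLOTS_PER_LABEL)
)
_PH_RE = re.compile(r"<[CQTDY]\d>")


@dataclass(frozen=True)
class Delexicalized:
    source: str
    target: Optional[str]
    slots: dict[str, str]  # placeholder -> surface text


def delexicalize(sentence: str, target: Optional[str] = None) -> Delexicalized:
    """Replace tagged entities by indexed placeholders on both sides."""
    s = normalize_text(sentence)
    # sentence-initial capitalization is orthographic, not part of a name
    if len(s) > 1 and s[0].isupper() and s[1].islower():
        s = s[0].lower() + s[1:]
    tags = [t for t in tag_entities(s) if t.label in _LABEL_PREFIX]
    counters: dict[EntityLabel, int] = defaultdict(int)
    assigned: dict[tuple[EntityLabel, str], str] = {}
    slots: dict[str, str] = {}
    spans: list[tuple[int, int, str]] = []
    for t in tags:
        surface = s[t.start : t.end]
        key = (t.label, surface)
        if key not in assigned:
            if counters[t.label] >= _MAX_SLOTS_PER_LABEL:
                continue  # beyond the slot budget: left lexical
            ph = f"<{_LABEL_PREFIX[t.label]}{counters[t.label]}>"
            counters[t.label] += 1
            assigned[key] = ph
            slots[ph] = surface
        spans.append((t.start, t.end, assigned[key]))
    src = s
    for start, end, ph in sorted(spans, reverse=True):
        src = src[:start] + ph + src[end:]
    tgt = None
    if target is not None:
        tgt = target
        for (label, surface), ph in sorted(
            assigned.items(), key=lambda kv: -len(kv[0][1])
        ):
            tgt = _boundary_sub(tgt, surface, ph)
    return Delexicalized(source=src, target=tgt, slots=slots)


def relexicalize(text: str, slots: dict[str, str]) -> str:
    for ph, surface in slots.items():
        text = text.replace(ph, surface)
    return text


# ---------------------------------------------------------------------------
# Subword vocabulary (shared source/target BPE with character fallback)
# ---------------------------------------------------------------------------

PAD, BOS, EOS, UNK, EOW = "<pad>", "<s>", "</s>", "<unk>", "</w>"
_SPECIALS = (PAD, BOS, EOS, UNK, EOW) + PLACEHOLDER_TOKENS


def _word_units(word: str) -> list[tuple[str, bool]]:
    """Split a word into placeholder and plain-text units."""
    parts: list[tuple[str, bool]] = []
    last = 0
    for m in _PH_RE.finditer(word):
        if m.start() > last:
            parts.append((word[last : m.start()], False))
        parts.append((m.group(0), True))
        last = m.end()
    if last < len(word):
        parts.append((word[last:], False))
    return parts


class SubwordVocab:
    """Byte-pair-encoding subword vocabulary, shared across both sides.

    Encoding is lossless on any text whose characters were seen at training
    time (unseen characters map to ``<unk>``); placeholders are atomic.
    """

    def __init__(self, symbols: list[str], merges: list[tuple[str, str]]):
        self.symbols = list(symbols)
        self.index = {s: i for i, s in enumerate(self.symbols)}
        self.merges = [tuple(m) for m in merges]
        self._rank = {tuple(m): i for i, m in enumerate(self.merges)}
        self.pad_id = self.index[PAD]
        self.bos_id = self.index[BOS]
        self.eos_id = self.index[EOS]
        self.unk_id = self.index[UNK]
        self.eow_id = self.index[EOW]

    def __len__(self) -> int:
        return len(self.symbols)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubwordVocab)
            and self.symbols == other.symbols
            and self.merges == other.merges
        )

    # -- training ----------------------------------------------------------

    @classmethod
    def train(cls, texts: Sequence[str], vocab_size: int) -> "SubwordVocab":
        """Learn merges from raw texts; deterministic for a given corpus."""
        word_freq: Counter = Counter()
        alphabet: set[str] = set()
        for text in texts:
            for word in text.split(" "):
                if not word:
                    continue
                units = _word_units(word)
                for i, (u, is_ph) in enumerate(units):
                    if is_ph:
                        continue
                    syms = list(u)
                    if i == len(units) - 1:
                        syms.append(EOW)
                    alphabet.update(c for c in u)
                    word_freq[tuple(syms)] += 1
        base = list(_SPECIALS) + sorted(alphabet)
        if vocab_size < len(base):
            raise ValueError(
                f"vocab_size {vocab_size} smaller than alphabet+specials ({len(base)})"
            )
        symbols = list(base)
        merges: list[tuple[str, str]] = []
        words = dict(word_freq)
        while len(symbols) < vocab_size:
            pair_counts: Counter = Counter()
            for syms, freq in words.items():
                for a, b in zip(syms, syms[1:]):
                    pair_counts[(a, b)] += freq
            if not pair_counts:
                break
            best = max(pair_counts.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
            (a, b), count = best
            if count < 2:
                break
            merges.append((a, b))
            merged = a + b
            symbols.append(merged)
            new_words: dict[tuple, int] = {}
            for syms, freq in words.items():
                out = []
                i = 0
                while i < len(syms):
                    if i + 1 < len(syms) and syms[i] == a and syms[i + 1] == b:
                        out.append(merged)
                        i += 2
                    else:
                        out.append(syms[i])
                        i += 1
                key = tuple(out)
                new_words[key] = new_words.get(key, 0) + freq
            words = new_words
        return cls(symbols, merges)

    # -- encode / decode ---------------------------------------------------

    def _bpe(self, unit: str, final: bool) -> list[int]:
        syms = [c if c in self.index else UNK for c in unit]
        if final:
            syms.append(EOW)
        while len(syms) > 1:
            best_rank = None
            best_i = -1
            for i, pair in enumerate(zip(syms, syms[1:])):
                rank = self._rank.get(pair)
                if rank is not None and (best_rank is None or rank < best_rank):
                    best_rank, best_i = rank, i
            if best_rank is None:
                break
            syms[best_i : best_i + 2] = [syms[best_i] + syms[best_i + 1]]
        return [self.index.get(s, self.unk_id) for s in syms]

    def encode(self, text: str) -> list[int]:
        ids: list[int] = []
        for word in text.split(" "):
            if not word:
                continue
            units = _word_units(word)
            for i, (u, is_ph) in enumerate(units):
                final = i == len(units) - 1
                if is_ph:
                    ids.append(self.index[u])
                    if final:
                        ids.append(self.eow_id)
                else:
                    ids.extend(self._bpe(u, final))
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        parts: list[str] = []
        for i in ids:
            if i in (self.pad_id, self.bos_id, self.eos_id):
                continue
            sym = self.symbols[i]
            if sym == EOW:
                parts.append(" ")
            elif sym.endswith(EOW):
                parts.append(sym[: -len(EOW)])
                parts.append(" ")
            else:
                parts.append(sym)
        return "".join(parts).strip()


def build_vocabulary(corpus: Sequence[PairedSample], vocab_size: int, seed: int = 0) -> SubwordVocab:
    """Shared source/target subword vocabulary from a paired corpus.

    Trained on the delexicalized sentence and action-string sides; the
    requested size is an upper bound (merges stop when no pair repeats).
    ``seed`` is accepted for interface uniformity; training is
    deterministic regardless.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    texts: list[str] = []
    for sample in corpus:
        d = delexicalize(sample.sentence, sample.action_string)
        texts.append(d.source)
        texts.append(d.target or "")
    return SubwordVocab.train(texts, vocab_size)


# ---------------------------------------------------------------------------
# Feature hashing
# ---------------------------------------------------------------------------


def _h(s: str, dim: int) -> int:
    return zlib.crc32(s.encode("utf-8")) % dim


def _feature_indices(src_ids: Sequence[int], prefix: Sequence[int], dim: int) -> np.ndarray:
    """Hashed feature indices for one decoding state (counts collapsed)."""
    feats: set[int] = set()
    feats.add(_h("bias", dim))
    p1 = prefix[-1] if len(prefix) >= 1 else -1
    p2 = prefix[-2] if len(prefix) >= 2 else -1
    p3 = prefix[-3] if len(prefix) >= 3 else -1
    feats.add(_h(f"p1={p1}", dim))
    feats.add(_h(f"p2={p2},{p1}", dim))
    feats.add(_h(f"p3={p3},{p2},{p1}", dim))
    feats.add(_h(f"pos={min(len(prefix), 24)}", dim))
    unique_src = sorted(set(src_ids))
    for s in unique_src:
        feats.add(_h(f"s={s}", dim))
        feats.add(_h(f"p1s={p1}|{s}", dim))
    for a, b in zip(src_ids, src_ids[1:]):
        feats.add(_h(f"sb={a},{b}", dim))
    return np.fromiter(sorted(feats), dtype=np.int64)


# ---------------------------------------------------------------------------
# The default engine: softmax regression over hashed features
# ---------------------------------------------------------------------------


class _SoftmaxEngine:
    """Multinomial logistic regression trained by SGD on cross-entropy."""

    def __init__(self, n_classes: int, dim: int, seed: int, learning_rate: float):
        self.n_classes = n_classes
        self.dim = dim
        self.lr0 = learning_rate
        self.W = np.zeros((n_classes, dim), dtype=np.float64)
        self.b = np.zeros(n_classes, dtype=np.float64)
        self.t = 0
        self.rng = random.Random(seed)

    def log_probs(self, feat_idx: np.ndarray) -> np.ndarray:
        z = self.W[:, feat_idx].sum(axis=1) + self.b
        z -= z.max()
        logz = np.log(np.exp(z).sum())
        return z - logz

    def sgd_step(self, batch: list[tuple[np.ndarray, int]]) -> float:
        """One step on a minibatch; returns the mean cross-entropy."""
        self.t += 1
        lr = self.lr0 / (1.0 + self.t / 2000.0) ** 0.5
        loss = 0.0
        for feat_idx, label in batch:
            lp = self.log_probs(feat_idx)
            loss -= lp[label]
            g = np.exp(lp)
            g[label] -= 1.0
            self.W[:, feat_idx] -= lr * g[:, None]
            self.b -= lr * 0.1 * g
        return loss / max(len(batch), 1)

    def snapshot(self) -> tuple[np.ndarray, np.ndarray]:
        return self.W.astype(np.float32).copy(), self.b.astype(np.float32).copy()

    def restore(self, weights: tuple[np.ndarray, np.ndarray]) -> None:
        self.W = weights[0].astype(np.float64).copy()
        self.b = weights[1].astype(np.float64).copy()


# ---------------------------------------------------------------------------
# Trained model, checkpoints
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    step: int
    validation_accuracy: Optional[float]
    weights: tuple[np.ndarray, np.ndarray]


@dataclass
class TrainedModel:
    """Opaque handle: engine weights + vocabulary + config + checkpoints."""

    vocab: SubwordVocab
    config: ModelConfig
    engine: _SoftmaxEngine
    checkpoints: list[Checkpoint] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)  # training curve

    def clone(self) -> "TrainedModel":
        return copy.deepcopy(self)


def _make_examples(
    corpus: Sequence[PairedSample], vocab: SubwordVocab, dim: int
) -> list[tuple[np.ndarray, int]]:
    examples: list[tuple[np.ndarray, int]] = []
    for sample in corpus:
        d = delexicalize(sample.sentence, sample.action_string)
        src_ids = vocab.encode(d.source)
        tgt_ids = vocab.encode(d.target or "") + [vocab.eos_id]
        prefix = [vocab.bos_id]
        for label in tgt_ids:
            examples.append((_feature_indices(src_ids, prefix, dim), label))
            prefix.append(label)
    return examples


def _exact_match_accuracy(model: "TrainedModel", corpus: Sequence[PairedSample]) -> float:
    if not corpus:
        return 0.0
    predictions = translate(model, [s.sentence for s in corpus], beam_size=1, n_best=1)
    hits = sum(
        1
        for cands, sample in zip(predictions, corpus)
        if cands and cands[0][0] == sample.action_string
    )
    return hits / len(corpus)


def _train_loop(
    model: TrainedModel,
    corpus: Sequence[PairedSample],
    config: ModelConfig,
    valid: Optional[Sequence[PairedSample]],
) -> TrainedModel:
    examples = _make_examples(corpus, model.vocab, config.feature_dim)
    if not examples:
        raise ValueError("no training examples")
    rng = random.Random(config.seed)
    order = list(range(len(examples)))
    rng.shuffle(order)
    cursor = 0
    for step in range(1, config.train_steps + 1):
        batch = []
        for _ in range(config.batch_size):
            if cursor >= len(order):
                rng.shuffle(order)
                cursor = 0
            batch.append(examples[order[cursor]])
            cursor += 1
        loss = model.engine.sgd_step(batch)
        if step % config.checkpoint_every == 0 or step == config.train_steps:
            acc = _exact_match_accuracy(model, valid) if valid is not None else None
            model.checkpoints.append(
                Checkpoint(step=step, validation_accuracy=acc, weights=model.engine.snapshot())
            )
            model.history.append({"step": step, "loss": loss, "validation_accuracy": acc})
    return model


def pretrain(
    corpus: Sequence[PairedSample],
    config: ModelConfig,
    valid: Optional[Sequence[PairedSample]] = None,
) -> TrainedModel:
    """Train a fresh model on (rule-generated) paired samples."""
    if not corpus:
        raise ValueError("cannot pretrain on an empty corpus")
    vocab = build_vocabulary(corpus, config.vocab_size, seed=config.seed)
    engine = _SoftmaxEngine(
        n_classes=len(vocab),
        dim=config.feature_dim,
        seed=config.seed,
        learning_rate=config.learning_rate,
    )
    model = TrainedModel(vocab=vocab, config=config, engine=engine)
    return _train_loop(model, corpus, config, valid)


def refine(
    model: TrainedModel,
    annotated_corpus: Sequence[PairedSample],
    config: Optional[ModelConfig] = None,
    valid: Optional[Sequence[PairedSample]] = None,
) -> TrainedModel:
    """Continue training a pretrained model on annotated samples.

    Returns a new model (the input is untouched) whose checkpoints carry
    validation exact-match accuracies when a validation set is given; use
    :func:`select_best_checkpoint` afterwards.
    """
    if config is None:
        config = model.config
    refined = model.clone()
    refined.config = config
    refined.checkpoints = []
    refined.history = list(model.history)
    return _train_loop(refined, annotated_corpus, config, valid)


def select_best_checkpoint(model: TrainedModel) -> TrainedModel:
    """Restore the checkpoint with the highest validation accuracy.

    Ties go to the latest step; models without scored checkpoints are
    returned unchanged (final weights).
    """
    scored = [c for c in model.checkpoints if c.validation_accuracy is not None]
    if not scored:
        return model
    best = max(scored, key=lambda c: (c.validation_accuracy, c.step))
    out = model.clone()
    out.engine.restore(best.weights)
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def _beam_decode(
    engines: list[_SoftmaxEngine],
    vocab: SubwordVocab,
    src_ids: list[int],
    beam_size: int,
    n_best: int,
    max_len: int,
    dim: int,
) -> list[tuple[list[int], float]]:
    beams: list[tuple[float, tuple[int, ...], bool]] = [(0.0, (vocab.bos_id,), False)]
    finished: list[tuple[float, tuple[int, ...]]] = []
    for _ in range(max_len):
        candidates: list[tuple[float, tuple[int, ...], bool]] = []
        for score, prefix, done in beams:
            if done:
                candidates.append((score, prefix, True))
                continue
            feat_idx = _feature_indices(src_ids, prefix, dim)
            lp = engines[0].log_probs(feat_idx)
            for engine in engines[1:]:
                lp = lp + engine.log_probs(feat_idx)
            lp = lp / len(engines)
            top = np.argsort(lp, kind="stable")[::-1][: beam_size + 1]
            for token in top:
                token = int(token)
                if token in (vocab.pad_id, vocab.bos_id):
                    continue
                new_score = score + float(lp[token])
                if token == vocab.eos_id:
                    candidates.append((new_score, prefix, True))
                else:
                    candidates.append((new_score, prefix + (token,), False))
        candidates.sort(key=lambda c: (-c[0], c[1]))
        beams = candidates[:beam_size]
        if all(done for _, _, done in beams):
            break
    for score, prefix, done in beams:
        finished.append((score, prefix))
    finished.sort(key=lambda c: (-c[0], c[1]))
    out = []
    for score, prefix in finished[:n_best]:
        out.append((list(prefix[1:]), score))
    return out


def translate(
    model: TrainedModel,
    sentences: Sequence[str],
    beam_size: int = 5,
    n_best: int = 1,
) -> list[list[tuple[str, float]]]:
    """Per-sentence ranked action-string candidates with scores.

    Deterministic for a given model, input and beam parameters; requires
    ``n_best <= beam_size``.
    """
    return ensemble_translate([model], sentences, beam_size=beam_size, n_best=n_best)


def ensemble_translate(
    models: Sequence[TrainedModel],
    sentences: Sequence[str],
    beam_size: int = 5,
    n_best: int = 1,
) -> list[list[tuple[str, float]]]:
    """Joint decoding averaging per-step token log-probabilities."""
    if not models:
        raise ValueError("need at least one model")
    if n_best > beam_size:
        raise ValueError("n_best must not exceed beam_size")
    vocab = models[0].vocab
    for m in models[1:]:
        if m.vocab != vocab:
            raise ValueError("ensemble models must share a vocabulary")
    config = models[0].config
    engines = [m.engine for m in models]
    out: list[list[tuple[str, float]]] = []
    for sentence in sentences:
        d = delexicalize(sentence)
        src_ids = vocab.encode(d.source)
        max_len = min(config.max_decode_len, 4 * max(len(src_ids), 1) + 10)
        decoded = _beam_decode(
            engines, vocab, src_ids, beam_size, n_best, max_len, config.feature_dim
        )
        ranked = [
            (relexicalize(vocab.decode(ids), d.slots), score) for ids, score in decoded
        ]
        out.append(ranked)
    return out


def predict_actions(
    model: TrainedModel, sentences: Sequence[str], beam_size: int = 5
) -> list[ActionSequence]:
    """Pipeline wrapper: best decode per sentence, invalid decodes mapped
    to ``[InvalidAction]``."""
    out: list[ActionSequence] = []
    for candidates in translate(model, sentences, beam_size=beam_size, n_best=1):
        text = candidates[0][0] if candidates else ""
        result = action_string.try_parse(text)
        if result.ok:
            out.append(result.sequence)
        else:
            out.append(ActionSequence((Action(type=ActionType.INVALID_ACTION),)))
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str) -> None:
    import joblib

    joblib.dump(
        {
            "symbols": model.vocab.symbols,
            "merges": model.vocab.merges,
            "config": model.config,
            "W": model.engine.W,
            "b": model.engine.b,
            "t": model.engine.t,
            "history": model.history,
        },
        path,
        compress=3,
    )


def load_model(path: str) -> TrainedModel:
    import joblib

    d = joblib.load(path)
    vocab = SubwordVocab(d["symbols"], d["merges"])
    config: ModelConfig = d["config"]
    engine = _SoftmaxEngine(
        n_classes=len(vocab),
        dim=config.feature_dim,
        seed=config.seed,
        learning_rate=config.learning_rate,
    )
    engine.W = d["W"].astype(np.float64)
    engine.b = d["b"].astype(np.float64)
    engine.t = d["t"]
    return TrainedModel(vocab=vocab, config=config, engine=engine, history=d["history"])
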