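"""Evaluation metrics for predicted action strings.

The headline metrics: *validity* (share of predictions that parse back into
actions), an *adapted BLEU* that does not penalize predictions shorter than
four words (the n-gram order is capped per pair at the shorter side's word
count), the mean character-level *Levenshtein similarity*
``1 − d(pred, ref) / max(|pred|, |ref|)``, and *threshold accuracies* — the
fractions of sentences whose similarity is ≥ 1.0, ≥ 0.9 and ≥ 0.75 (the
100% accuracy is the fraction of perfectly predicted action sequences).

For error analysis, :func:`confusion_ledger` aligns predicted and reference
actions per sentence by a minimal edit script over action types and counts,
per type: type matches, full matches (type and properties), actions only in
the prediction, and actions only in the ground truth, plus the off-diagonal
substitution matrix.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from . import action_string
from .actions import ActionSequence, ActionType
from .corpus import PairedSample


# ---------------------------------------------------------------------------
# Validity and string similarity
# ---------------------------------------------------------------------------


def validity(predictions: Sequence[str]) -> float:
    """Fraction of prediction strings that parse back into actions."""
    if not predictions:
        return 1.0
    ok = sum(1 for p in predictions if action_string.try_parse(p).ok)
    return ok / len(predictions)


def levenshtein_similarity(pred: str, ref: str) -> float:
    """1 − normalized character edit distance; both empty → 1.0."""
    if not pred and not ref:
        return 1.0
    if not pred or not ref:
        return 0.0
    distance = edlib.align(pred, ref)["editDistance"]
    return 1.0 - distance / max(len(pred), len(ref))


def threshold_accuracies(similarities: Sequence[float]) -> tuple[float, float, float]:
    """Fractions of similarities ≥ 1.0, ≥ 0.9, ≥ 0.75 (in that order)."""
    if not similarities:
        raise ValueError("threshold accuracies are undefined on an empty list")
    n = len(similarities)
    acc100 = sum(1 for s in similarities if s >= 1.0) / n
    acc90 = sum(1 for s in similarities if s >= 0.9) / n
    acc75 = sum(1 for s in similarities if s >= 0.75) / n
    return acc100, acc90, acc75


# ---------------------------------------------------------------------------
# Adapted BLEU
# ---------------------------------------------------------------------------


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def adapted_bleu(pred_corpus: Sequence[str], ref_corpus: Sequence[str]) -> float:
    """Corpus BLEU with the n-gram order capped per pair.

    For each pair the maximum n-gram order is ``min(4, |pred|, |ref|)``
    (word counts), so single-word exact predictions score 1.0 instead of 0.
    When every pair has at least four words on both sides this reduces to
    standard corpus BLEU (uniform weights, corpus-level brevity penalty).
    """
    if len(pred_corpus) != len(ref_corpus):
        raise ValueError(
            f"corpus length mismatch: {len(pred_corpus)} vs {len(ref_corpus)}"
        )
    if not pred_corpus:
        raise ValueError("adapted BLEU is undefined on empty corpora")
    matches = [0] * 4
    totals = [0] * 4
    pred_len = 0
    ref_len = 0
    for pred, ref in zip(pred_corpus, ref_corpus):
        pred_tokens = pred.split()
        ref_tokens = ref.split()
        pred_len += len(pred_tokens)
        ref_len += len(ref_tokens)
        cap = min(4, len(pred_tokens), len(ref_tokens))
        for n in range(1, cap + 1):
            pred_ngrams = _ngrams(pred_tokens, n)
            ref_ngrams = _ngrams(ref_tokens, n)
            totals[n - 1] += max(len(pred_tokens) - n + 1, 0)
            matches[n - 1] += sum(
                min(count, ref_ngrams[gram]) for gram, count in pred_ngrams.items()
            )
    log_precisions = []
    for m, t in zip(matches, totals):
        if t == 0:
            continue
        if m == 0:
            return 0.0
        log_precisions.append(math.log(m / t))
    if not log_precisions:
        return 0.0
    brevity = 1.0 if pred_len >= ref_len else math.exp(1.0 - ref_len / max(pred_len, 1))
    return brevity * math.exp(sum(log_precisions) / len(log_precisions))


# ---------------------------------------------------------------------------
# Metrics report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """The metric suite over one prediction set (all values in [0, 1])."""

    validity: float
    bleu: float
    levenshtein_similarity: float
    acc100: float
    acc90: float
    acc75: float
    n: int

    def __post_init__(self) -> None:
        assert self.acc100 <= self.acc90 + 1e-12 and self.acc90 <= self.acc75 + 1e-12

    def to_dict(self) -> dict:
        return {
            "validity": self.validity,
            "bleu": self.bleu,
            "levenshtein_similarity": self.levenshtein_similarity,
            "acc100": self.acc100,
            "acc90": self.acc90,
            "acc75": self.acc75,
            "n": self.n,
        }


def evaluate_predictions(predictions: Sequence[str], references: Sequence[str]) -> MetricsReport:
    """Compute the full metric suite for aligned prediction/reference sets.

    Validity is computed on the raw prediction strings before any other
    processing; similarity-based metrics use the strings as given.
    """
    if len(predictions) != len(references):
        raise ValueError("predictions and references must be aligned")
    sims = [levenshtein_similarity(p, r) for p, r in zip(predictions, references)]
    acc100, acc90, acc75 = threshold_accuracies(sims)
    return MetricsReport(
        validity=validity(predictions),
        bleu=adapted_bleu(predictions, references),
        levenshtein_similarity=sum(sims) / len(sims),
        acc100=acc100,
        acc90=acc90,
        acc75=acc75,
        n=len(predictions),
    )


# ---------------------------------------------------------------------------
# Per-action-type confusion ledger
# ---------------------------------------------------------------------------


@dataclass
class TypeCounts:
    type_match: int = 0
    full_match: int = 0
    only_in_prediction: int = 0
    only_in_ground_truth: int = 0


@dataclass
class ConfusionLedger:
    """Per-type accuracy counts plus the substitution (off-diagonal) matrix."""

    per_type: dict[str, TypeCounts] = field(default_factory=lambda: defaultdict(TypeCounts))
    substitutions: Counter = field(default_factory=Counter)  # (ref, pred) -> n

    def to_dict(self) -> dict:
        return {
            "per_type": {
                t: vars(c)
                for t, c in sorted(self.per_type.items())
            },
            "substitutions": {
                f"{ref}->{pred}": n for (ref, pred), n in sorted(self.substitutions.items())
            },
        }


def _align(pred_types: list[str], ref_types: list[str]) -> list[tuple[str, Optional[int], Optional[int]]]:
    """Minimal edit script between type sequences.

    Returns ops ``(kind, pred_index, ref_index)`` with kind in
    match/substitute/insert/delete; ties broken preferring match, then
    substitution, then deletion, leftmost-first — a fixed convention so the
    ledger is deterministic.
    """
    np_, nr = len(pred_types), len(ref_types)
    # DP over (i, j): cost of aligning pred[:i] with ref[:j]
    cost = [[0] * (nr + 1) for _ in range(np_ + 1)]
    for i in range(1, np_ + 1):
        cost[i][0] = i
    for j in range(1, nr + 1):
        cost[0][j] = j
    for i in range(1, np_ + 1):
        for j in range(1, nr + 1):
            same = pred_types[i - 1] == ref_types[j - 1]
            cost[i][j] = min(
                cost[i - 1][j - 1] + (0 if same else 1),
                cost[i - 1][j] + 1,
                cost[i][j - 1] + 1,
            )
    ops: list[tuple[str, Optional[int], Optional[int]]] = []
    i, j = np_, nr
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            same = pred_types[i - 1] == ref_types[j - 1]
            diag = cost[i - 1][j - 1] + (0 if same else 1)
            if diag == cost[i][j]:
                ops.append(("match" if same else "substitute", i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if j > 0 and cost[i][j - 1] + 1 == cost[i][j]:
            ops.append(("delete", None, j - 1))  # only in ground truth
            j -= 1
            continue
        ops.append(("insert", i - 1, None))  # only in prediction
        i -= 1
    ops.reverse()
    return ops


def confusion_ledger(
    pred_seqs: Sequence[ActionSequence], ref_seqs: Sequence[ActionSequence]
) -> ConfusionLedger:
    """Align predictions with references per sentence and tally per type."""
    if len(pred_seqs) != len(ref_seqs):
        raise ValueError("prediction and reference sequences must be aligned")
    ledger = ConfusionLedger()
    for pred, ref in zip(pred_seqs, ref_seqs):
        pred_actions = list(pred)
        ref_actions = list(ref)
        pred_types = [a.type.value for a in pred_actions]
        ref_types = [a.type.value for a in ref_actions]
        for kind, pi, ri in _align(pred_types, ref_types):
            if kind == "match":
                counts = ledger.per_type[ref_types[ri]]
                counts.type_match += 1
                same_clause = action_string._serialize_action(
                    pred_actions[pi]
                ) == action_string._serialize_action(ref_actions[ri])
                if same_clause:
                    counts.full_match += 1
            elif kind == "substitute":
                ledger.substitutions[(ref_types[ri], pred_types[pi])] += 1
            elif kind == "insert":
                ledger.per_type[pred_types[pi]].only_in_prediction += 1
            else:  # delete
                ledger.per_type[ref_types[ri]].only_in_ground_truth += 1
    return ledger


# ---------------------------------------------------------------------------
# Corpus distribution summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSummary:
    """Counts behind the corpus-statistics views: per-type frequencies and
    per-sentence action / character counts."""

    type_frequencies: dict[str, int]
    actions_per_sentence: list[int]
    characters_per_sentence: list[int]

    @property
    def most_common_type(self) -> Optional[str]:
        if not self.type_frequencies:
            return None
        return max(self.type_frequencies.items(), key=lambda kv: (kv[1], kv[0]))[0]


def action_distribution(corpus: Sequence[PairedSample]) -> DistributionSummary:
    """Deterministic distribution summary of a paired corpus."""
    freqs: Counter = Counter()
    n_actions: list[int] = []
    n_chars: list[int] = []
    for sample in corpus:
        types = sample.actions.types()
        freqs.update(t.value for t in types)
        n_actions.append(len(types))
        n_chars.append(len(sample.sentence))
    return DistributionSummary(
        type_frequencies=dict(freqs),
        actions_per_sentence=n_actions,
        characters_per_sentence=n_chars,
    )
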