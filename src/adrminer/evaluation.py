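"""Recall/precision/F-score of predicted per-drug preferred-term sets.

Scoring is at the level of normalized preferred terms per drug (not text
spans). Both micro (pool counts, then compute metrics) and macro (average
per-drug metrics) aggregation are provided; reports must state which mode
was used, since the two can differ substantially on skewed corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

from .errors import EmptyInputError


@dataclass(frozen=True)
class EvaluationResult:
    true_positives: int
    gold_count: int
    predicted_count: int
    recall: float
    precision: float
    f_score: float

    @classmethod
    def from_counts(cls, tp: int, gold: int, predicted: int) -> "EvaluationResult":
        if tp < 0 or gold < 0 or predicted < 0 or tp > gold or tp > predicted:
            raise ValueError(f"inconsistent counts tp={tp} gold={gold} pred={predicted}")
        recall = tp / gold if gold else 0.0
        precision = tp / predicted if predicted else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return cls(tp, gold, predicted, recall, precision, f)

    @classmethod
    def from_metrics(cls, recall: float, precision: float, f: float) -> "EvaluationResult":
        return cls(-1, -1, -1, recall, precision, f)


def evaluate_drug(predicted: Set[str], gold: Set[str]) -> EvaluationResult:
    """Score one drug's predicted PT set against its gold PT set."""
    tp = len(set(predicted) & set(gold))
    return EvaluationResult.from_counts(tp, len(gold), len(predicted))


def aggregate(results: Iterable[EvaluationResult], mode: str = "micro") -> EvaluationResult:
    """Pool per-drug results: ``micro`` sums counts first, ``macro`` averages metrics."""
    results = list(results)
    if not results:
        raise EmptyInputError("aggregate() needs at least one result")
    if mode == "micro":
        return EvaluationResult.from_counts(
            sum(r.true_positives for r in results),
            sum(r.gold_count for r in results),
            sum(r.predicted_count for r in results),
        )
    if mode == "macro":
        n = len(results)
        return EvaluationResult.from_metrics(
            sum(r.recall for r in results) / n,
            sum(r.precision for r in results) / n,
            sum(r.f_score for r in results) / n,
        )
    raise ValueError(f"unknown mode {mode!r} (expected 'micro' or 'macro')")
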