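"""Three-tier micro P/R/F1 scoring of predicted relation triples.

Matching is per document on unordered entity-id pairs:

* tier ``pair`` — the predicted pair exists in gold, any relation type;
* tier ``pair+type`` — additionally the relation type matches;
* tier ``pair+type+novelty`` — additionally the novelty flag matches.

Counts are pooled over all documents (micro-averaging); precision is
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean.  Scores are
non-increasing from tier to tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import AnnotatedDocument
from .ensemble import PredictionSet

__all__ = ["TierScore", "TierScores", "evaluate", "TIERS"]

TIERS = ("pair", "pair+type", "pair+type+novelty")


@dataclass(frozen=True)
class TierScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class TierScores:
    pair: TierScore
    pair_type: TierScore
    pair_type_novelty: TierScore

    def as_dict(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, score in zip(TIERS, (self.pair, self.pair_type, self.pair_type_novelty)):
            out[name] = {
                "precision": score.precision,
                "recall": score.recall,
                "f1": score.f1,
                "tp": score.tp,
                "fp": score.fp,
                "fn": score.fn,
            }
        return out


def _canonical(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def evaluate(
    predictions: Iterable[PredictionSet],
    gold_docs: Sequence[AnnotatedDocument],
) -> TierScores:
    """Micro P/R/F1 over all documents at the three matching tiers."""
    gold_by_doc: dict[str, dict[tuple[str, str], tuple[str, str]]] = {}
    for doc in gold_docs:
        gold_by_doc[doc.doc_id] = {
            r.pair: (r.relation_type, r.novelty) for r in doc.relations
        }

    tp = [0, 0, 0]
    fp = [0, 0, 0]
    n_pred_docs: set[str] = set()
    for pred in predictions:
        if pred.doc_id not in gold_by_doc:
            raise ValueError(f"predictions for unknown doc_id {pred.doc_id!r}")
        if pred.doc_id in n_pred_docs:
            raise ValueError(f"duplicate prediction set for doc {pred.doc_id!r}")
        n_pred_docs.add(pred.doc_id)
        gold = gold_by_doc[pred.doc_id]
        for pair, (rel, nov) in pred.triples.items():
            key = _canonical(pair)
            if key not in gold:
                for t in range(3):
                    fp[t] += 1
                continue
            g_rel, g_nov = gold[key]
            hits = [True, rel == g_rel, rel == g_rel and nov == g_nov]
            for t, hit in enumerate(hits):
                if hit:
                    tp[t] += 1
                else:
                    fp[t] += 1

    n_gold = sum(len(g) for g in gold_by_doc.values())
    scores = [TierScore(tp[t], fp[t], n_gold - tp[t]) for t in range(3)]
    return TierScores(*scores)
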