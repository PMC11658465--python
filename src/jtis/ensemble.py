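"""Two-stage prediction and k-fold ensemble voting.

Prediction is staged: the RE model proposes a relation type (or None) for
every candidate pair; only pairs predicted related are passed to the TNT
model for novelty typing.  Pairs filtered out by the entity-type constraint
map are None without any model call.

The ensemble trains one (RE, TNT) model pair per held-out fold of a k-fold
document-level partition of the merged train+dev corpus, predicts the test
corpus with each, and combines predictions by per-pair plurality voting over
relation labels (None is a votable label).  Ties break by highest mean
predicted probability among the tied labels, then by schema label order;
novelty is decided by majority among the models that voted the winning
relation, with ``No`` winning novelty ties.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .corpus import AnnotatedDocument, NOVEL, NOT_NOVEL
from .samples import EncoderConfig, LabelSchema, NONE_LABEL, PairSample, build_samples
from .training import TrainConfig, train_model

__all__ = [
    "PredictionSet",
    "RelationPredictor",
    "NoveltyPredictor",
    "predict_document",
    "kfold_partition",
    "ensemble_vote",
    "run_ensemble",
]


@dataclass
class PredictionSet:
    """Predicted triples for one document.

    ``triples`` maps an unordered entity-id pair to (relation, novelty);
    None-relation pairs are absent.  ``scores`` optionally records, for every
    pair the predictor considered (including None-predicted ones), the
    probability of its predicted relation label.
    """

    doc_id: str
    triples: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    scores: dict[tuple[str, str], tuple[str, float]] = field(default_factory=dict)


class RelationPredictor(Protocol):
    schema: LabelSchema

    def predict_re(self, batch: Sequence[PairSample]) -> tuple[list[str], list[float]]: ...


class NoveltyPredictor(Protocol):
    schema: LabelSchema

    def predict_tnt(self, batch: Sequence[PairSample]) -> tuple[list[str], list[float]]: ...


def predict_document(
    re_model: RelationPredictor,
    tnt_model: NoveltyPredictor,
    doc: AnnotatedDocument,
    schema: LabelSchema,
    encoder_config: EncoderConfig,
) -> PredictionSet:
    """Two-stage prediction for one document.

    The TNT model is invoked only on the pairs the RE model predicts as
    related; constraint-filtered pairs never reach either model.
    """
    if getattr(re_model, "schema", schema).re_classes != schema.re_classes:
        raise ValueError("RE model schema does not match the provided schema")
    if getattr(tnt_model, "schema", schema).tnt_classes != schema.tnt_classes:
        raise ValueError("TNT model schema does not match the provided schema")

    samples = build_samples(doc, schema, encoder_config, keep_unconstrained=False)
    pred = PredictionSet(doc_id=doc.doc_id)
    if not samples:
        return pred
    re_labels, re_probs = re_model.predict_re(samples)
    related = [
        (s, lab) for s, lab in zip(samples, re_labels) if lab != NONE_LABEL
    ]
    for s, lab, p in zip(samples, re_labels, re_probs):
        pred.scores[s.focal_pair] = (lab, p)
    if related:
        tnt_labels, _ = tnt_model.predict_tnt([s for s, _ in related])
        for (s, lab), nov in zip(related, tnt_labels):
            pred.triples[s.focal_pair] = (lab, nov)
    return pred


def kfold_partition(
    docs: Sequence[AnnotatedDocument], k: int, seed: int = 0
) -> list[list[AnnotatedDocument]]:
    """Disjoint document-level folds covering all docs, sizes differing ≤ 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(docs) < k:
        raise ValueError(f"need at least k={k} documents, got {len(docs)}")
    order = np.random.default_rng(seed).permutation(len(docs))
    folds: list[list[AnnotatedDocument]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(docs[idx])
    return folds


def ensemble_vote(
    prediction_sets: Sequence[PredictionSet],
    schema: LabelSchema,
) -> PredictionSet:
    """Combine per-model predictions for one document by plurality voting."""
    if not prediction_sets:
        raise ValueError("ensemble_vote needs at least one prediction set")
    doc_ids = {p.doc_id for p in prediction_sets}
    if len(doc_ids) != 1:
        raise ValueError(f"prediction sets span multiple documents: {doc_ids}")
    doc_id = prediction_sets[0].doc_id

    pairs: set[tuple[str, str]] = set()
    for p in prediction_sets:
        pairs.update(p.triples)
        pairs.update(p.scores)

    label_order = schema.re_classes  # includes None, used for final tie-break
    out = PredictionSet(doc_id=doc_id)
    for pair in sorted(pairs):
        votes: list[tuple[str, float, str | None]] = []  # (label, prob, novelty)
        for p in prediction_sets:
            if pair in p.triples:
                rel, nov = p.triples[pair]
                prob = p.scores.get(pair, (rel, 0.0))[1]
                votes.append((rel, prob, nov))
            elif pair in p.scores:
                rel, prob = p.scores[pair]
                votes.append((NONE_LABEL, prob if rel == NONE_LABEL else 0.0, None))
            else:
                votes.append((NONE_LABEL, 0.0, None))
        counts = Counter(lab for lab, _, _ in votes)
        top = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == top]
        if len(tied) > 1:
            mean_prob = {
                lab: float(np.mean([p for l2, p, _ in votes if l2 == lab]))
                for lab in tied
            }
            best = max(mean_prob.values())
            tied = [lab for lab in tied if mean_prob[lab] == best]
            winner = min(tied, key=label_order.index)
        else:
            winner = tied[0]
        if winner == NONE_LABEL:
            continue
        novs = [nov for lab, _, nov in votes if lab == winner and nov is not None]
        n_novel = sum(1 for n in novs if n == NOVEL)
        novelty = NOVEL if n_novel > len(novs) - n_novel else NOT_NOVEL
        out.triples[pair] = (winner, novelty)
        out.scores[pair] = (
            winner,
            float(np.mean([p for lab, p, _ in votes if lab == winner])),
        )
    return out


def run_ensemble(
    train_docs: Sequence[AnnotatedDocument],
    test_docs: Sequence[AnnotatedDocument],
    schema: LabelSchema,
    encoder_config: EncoderConfig,
    config: TrainConfig,
    k: int = 10,
) -> list[PredictionSet]:
    """Train k (RE, TNT) model pairs on k-fold splits of the merged corpus
    and vote their test predictions."""
    folds = kfold_partition(train_docs, k, seed=config.seed)
    per_model: list[list[PredictionSet]] = []
    for fold_idx in range(k):
        held_out = folds[fold_idx]
        fold_train = [d for i, f in enumerate(folds) if i != fold_idx for d in f]
        train_samples = [
            s for d in fold_train for s in build_samples(d, schema, encoder_config)
        ]
        dev_samples = [
            s for d in held_out for s in build_samples(d, schema, encoder_config)
        ]
        fold_cfg = replace(config, seed=config.seed + fold_idx)
        re_bundle, _ = train_model(
            train_samples, dev_samples, schema, encoder_config,
            replace(fold_cfg, primary_task="RE"),
        )
        tnt_bundle, _ = train_model(
            train_samples, dev_samples, schema, encoder_config,
            replace(fold_cfg, primary_task="TNT"),
        )
        per_model.append(
            [
                predict_document(re_bundle, tnt_bundle, doc, schema, encoder_config)
                for doc in test_docs
            ]
        )
    voted: list[PredictionSet] = []
    for di in range(len(test_docs)):
        voted.append(ensemble_vote([preds[di] for preds in per_model], schema))
    return voted
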