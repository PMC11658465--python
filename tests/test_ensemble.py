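"""Two-stage prediction gating, k-fold partitioning and ensemble voting."""

import numpy as np
import pytest

from jtis import PredictionSet, ensemble_vote, kfold_partition, predict_document
from jtis.corpus import AnnotatedDocument
from jtis.samples import LabelSchema, NONE_LABEL
from jtis.synthetic import (
    BIORED_ENTITY_TYPES,
    BIORED_RELATION_TYPES,
    SynthConfig,
    generate_corpus,
)

SCHEMA = LabelSchema(BIORED_ENTITY_TYPES, BIORED_RELATION_TYPES, {})


class _StubModel:
    """Predictor stub returning fixed labels and counting invocations."""

    def __init__(self, schema, re_label=NONE_LABEL, tnt_label="Novel", prob=0.9):
        self.schema = schema
        self.re_label = re_label
        self.tnt_label = tnt_label
        self.prob = prob
        self.re_calls = 0
        self.tnt_calls = 0

    def predict_re(self, batch):
        self.re_calls += 1
        return [self.re_label] * len(batch), [self.prob] * len(batch)

    def predict_tnt(self, batch):
        self.tnt_calls += 1
        return [self.tnt_label] * len(batch), [self.prob] * len(batch)


@pytest.fixture(scope="module")
def schema_and_doc(request):
    docs = generate_corpus(
        SynthConfig(n_docs=10, seed=9, entities_per_doc=(3, 3), relation_density=0.8)
    )
    from jtis import build_constraint_map, build_vocab
    from jtis.samples import EncoderConfig

    schema = LabelSchema(
        BIORED_ENTITY_TYPES, BIORED_RELATION_TYPES, build_constraint_map(docs)
    )
    enc = EncoderConfig(vocab=build_vocab(docs), max_length=128)
    from jtis import enumerate_pairs

    doc = next(d for d in docs if enumerate_pairs(d, schema.constraint_map))
    return schema, enc, doc


class TestPredictDocument:
    def test_all_none_re_means_zero_tnt_invocations(self, schema_and_doc):
        schema, enc, doc = schema_and_doc
        re_m = _StubModel(schema, re_label=NONE_LABEL)
        tnt_m = _StubModel(schema)
        pred = predict_document(re_m, tnt_m, doc, schema, enc)
        assert pred.triples == {}
        assert tnt_m.tnt_calls == 0

    def test_related_pairs_get_novelty_from_tnt_model(self, schema_and_doc):
        schema, enc, doc = schema_and_doc
        re_m = _StubModel(schema, re_label="Association")
        tnt_m = _StubModel(schema, tnt_label="Novel")
        pred = predict_document(re_m, tnt_m, doc, schema, enc)
        assert pred.triples  # constraint map admits at least one pair
        assert all(v == ("Association", "Novel") for v in pred.triples.values())

    def test_no_pair_appears_twice(self, schema_and_doc):
        schema, enc, doc = schema_and_doc
        pred = predict_document(
            _StubModel(schema, re_label="Bind"), _StubModel(schema), doc, schema, enc
        )
        pairs = list(pred.triples)
        assert len(pairs) == len(set(pairs))
        assert all(a <= b for a, b in pairs)

    def test_output_matches_straight_line_reimplementation(self, schema_and_doc):
        """Two-stage prediction equals calling the heads directly per pair."""
        from jtis.model import ModelBundle
        from jtis.samples import build_samples

        schema, enc, doc = schema_and_doc
        re_b = ModelBundle.create(schema, enc, seed=11)
        tnt_b = ModelBundle.create(schema, enc, seed=22)
        pred = predict_document(re_b, tnt_b, doc, schema, enc)

        expected = {}
        for s in build_samples(doc, schema, enc):
            labels, _ = re_b.predict_re([s])
            if labels[0] == NONE_LABEL:
                continue
            nov, _ = tnt_b.predict_tnt([s])
            expected[s.focal_pair] = (labels[0], nov[0])
        assert pred.triples == expected


class TestKFoldPartition:
    def _docs(self, n):
        return [AnnotatedDocument(str(i), "T.", "A.", [], []) for i in range(n)]

    def test_ten_docs_ten_singleton_folds(self):
        folds = kfold_partition(self._docs(10), 10, seed=0)
        assert [len(f) for f in folds] == [1] * 10

    @pytest.mark.parametrize("n,k", [(23, 10), (10, 2), (11, 5), (25, 10)])
    def test_folds_are_disjoint_balanced_and_cover(self, n, k):
        docs = self._docs(n)
        folds = kfold_partition(docs, k, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == n
        ids = [d.doc_id for f in folds for d in f]
        assert sorted(ids) == sorted(d.doc_id for d in docs)

    def test_too_few_docs_or_k_is_error(self):
        with pytest.raises(ValueError):
            kfold_partition(self._docs(3), 5)
        with pytest.raises(ValueError):
            kfold_partition(self._docs(3), 1)


def _pset(doc_id, entries):
    """entries: pair -> (label, prob, novelty|None); None label = no triple."""
    p = PredictionSet(doc_id=doc_id)
    for pair, (label, prob, nov) in entries.items():
        p.scores[pair] = (label, prob)
        if label != NONE_LABEL:
            p.triples[pair] = (label, nov)
    return p


class TestEnsembleVote:
    def test_plurality_wins(self):
        sets = [
            _pset("1", {("A", "B"): ("Association", 0.8, "Novel")}) for _ in range(6)
        ] + [_pset("1", {("A", "B"): (NONE_LABEL, 0.7, None)}) for _ in range(4)]
        out = ensemble_vote(sets, SCHEMA)
        assert out.triples[("A", "B")][0] == "Association"

    def test_unanimity_reproduces_any_input(self):
        p = _pset("1", {("A", "B"): ("Bind", 0.9, "No"), ("A", "C"): (NONE_LABEL, 0.6, None)})
        out = ensemble_vote([p] * 5, SCHEMA)
        assert out.triples == p.triples

    def test_single_model_vote_is_identity(self):
        p = _pset("1", {("A", "B"): ("Conversion", 0.7, "Novel")})
        assert ensemble_vote([p], SCHEMA).triples == p.triples

    def test_tie_broken_by_mean_probability(self):
        a = _pset("1", {("A", "B"): ("Association", 0.9, "Novel")})
        b = _pset("1", {("A", "B"): (NONE_LABEL, 0.6, None)})
        out = ensemble_vote([a, b], SCHEMA)
        assert out.triples[("A", "B")][0] == "Association"

    def test_probability_tie_falls_back_to_schema_order(self):
        a = _pset("1", {("A", "B"): ("Bind", 0.8, "No")})
        b = _pset("1", {("A", "B"): ("Association", 0.8, "Novel")})
        out = ensemble_vote([a, b], SCHEMA)
        # Association precedes Bind in the schema's relation ordering
        assert out.triples[("A", "B")][0] == "Association"

    def test_novelty_majority_with_no_winning_ties(self):
        sets = [
            _pset("1", {("A", "B"): ("Bind", 0.9, "Novel")}),
            _pset("1", {("A", "B"): ("Bind", 0.9, "No")}),
            _pset("1", {("A", "B"): ("Bind", 0.9, "No")}),
        ]
        assert ensemble_vote(sets, SCHEMA).triples[("A", "B")] == ("Bind", "No")
        tied = sets[:2]
        assert ensemble_vote(tied, SCHEMA).triples[("A", "B")] == ("Bind", "No")

    def test_permutation_invariance_on_random_sets(self):
        rng = np.random.default_rng(5)
        rels = ["Association", "Bind", NONE_LABEL]
        for _ in range(30):
            sets = []
            for _m in range(5):
                entries = {}
                for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
                    lab = rels[rng.integers(3)]
                    entries[pair] = (lab, float(rng.random()), "Novel" if lab != NONE_LABEL else None)
                sets.append(_pset("1", entries))
            base = ensemble_vote(sets, SCHEMA)
            perm = [sets[i] for i in rng.permutation(5)]
            assert ensemble_vote(perm, SCHEMA).triples == base.triples

    def test_vote_of_m_copies_is_idempotent(self):
        p = _pset("1", {("A", "B"): ("Drug_Interaction", 0.5, "Novel")})
        for m in (1, 3, 7):
            assert ensemble_vote([p] * m, SCHEMA).triples == p.triples

    def test_empty_model_list_is_error(self):
        with pytest.raises(ValueError):
            ensemble_vote([], SCHEMA)

    def test_mixed_doc_ids_is_error(self):
        with pytest.raises(ValueError):
            ensemble_vote([_pset("1", {}), _pset("2", {})], SCHEMA)
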