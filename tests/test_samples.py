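"""Pair enumeration, constraint filtering, marker insertion, tokenization
and label construction."""

import pytest

from jtis import (
    EncoderConfig,
    LabelSchema,
    build_constraint_map,
    build_samples,
    build_vocab,
    enumerate_pairs,
    insert_markers,
    make_labels,
    read_pubtator,
    tokenize_sample,
)
from jtis.corpus import AnnotatedDocument, EntityMention, RelationTriple
from jtis.samples import CLOSE_MARKER, NONE_LABEL, OPEN_MARKER

from conftest import TOY_BLOCK


def _mini_schema(cmap=None):
    return LabelSchema(
        ["Gene", "Disease", "Chemical"],
        ["Association", "Bind"],
        cmap or {},
    )


class TestConstraintMap:
    def test_map_collects_observed_relation_types(self, toy_doc):
        cmap = build_constraint_map([toy_doc])
        assert cmap == {("Chemical", "Gene"): frozenset({"Bind"})}

    def test_lookup_is_symmetric(self, toy_doc):
        schema = _mini_schema(build_constraint_map([toy_doc]))
        assert schema.allowed_relations("Gene", "Chemical") == schema.allowed_relations(
            "Chemical", "Gene"
        )

    def test_empty_corpus_gives_empty_map(self):
        assert build_constraint_map([]) == {}

    def test_unresolvable_endpoint_type_is_error(self):
        doc = AnnotatedDocument(
            "1",
            "B binds C.",
            "x",
            [EntityMention("m1", 0, 1, "B", "Gene", "G1")],
            [RelationTriple("G1", "MISSING", "Bind", "No")],
        )
        with pytest.raises(ValueError, match="MISSING"):
            build_constraint_map([doc])


class TestEnumeratePairs:
    def _doc(self, types):
        mentions = [
            EntityMention(f"m{i}", 2 * i, 2 * i + 1, "x", t, f"E{i}")
            for i, t in enumerate(types)
        ]
        title = " ".join("x" for _ in types) + "."
        return AnnotatedDocument("1", title, "y", mentions, [])

    def test_unfiltered_count_is_n_choose_2(self):
        doc = self._doc(["Gene", "Gene", "Disease"])
        assert len(enumerate_pairs(doc, None, keep_unconstrained=True)) == 3

    def test_constraint_filter_drops_unseen_type_pairs(self):
        doc = self._doc(["Chemical", "Disease", "Species"])
        cmap = {("Chemical", "Disease"): frozenset({"Association"})}
        assert enumerate_pairs(doc, cmap) == [("E0", "E1")]

    def test_single_entity_gives_no_pairs(self):
        assert enumerate_pairs(self._doc(["Gene"]), None, True) == []


class TestInsertMarkers:
    def test_direct_construction(self, toy_doc):
        marked, order = insert_markers(toy_doc, ("C1", "G1"))
        assert marked == f"A. {OPEN_MARKER} B {CLOSE_MARKER} binds {OPEN_MARKER} C {CLOSE_MARKER}."
        assert len(order) == 2

    def test_marker_counts_match_focal_mentions(self, small_setup):
        docs, schema, enc, _ = small_setup
        doc = docs[0]
        pairs = enumerate_pairs(doc, None, keep_unconstrained=True)
        pair = pairs[0]
        n_focal = sum(1 for m in doc.mentions if m.entity_id in pair)
        marked, order = insert_markers(doc, pair)
        assert marked.count(OPEN_MARKER) == n_focal
        assert marked.count(CLOSE_MARKER) == n_focal
        assert len(order) == n_focal

    def test_overlapping_focal_mentions_is_error(self):
        mentions = [
            EntityMention("m1", 0, 5, "ABCDE", "Gene", "G1"),
            EntityMention("m2", 3, 8, "DEFGH", "Gene", "G2"),
        ]
        doc = AnnotatedDocument("1", "ABCDEFGHI", "x", mentions, [])
        with pytest.raises(ValueError, match="m1"):
            insert_markers(doc, ("G1", "G2"))


class TestTokenizeSample:
    def _config(self, max_length=512):
        vocab = {
            t: i
            for i, t in enumerate(
                ["[PAD]", "[CLS]", "[SEP]", "[UNK]", OPEN_MARKER, CLOSE_MARKER]
                + list("abcdefghij")
            )
        }
        return EncoderConfig(vocab=vocab, max_length=max_length)

    def test_cls_and_sep_frame_the_sequence(self):
        cfg = self._config()
        ids, _ = tokenize_sample("a b c d e", [], cfg)
        assert len(ids) == 7
        assert ids[0] == cfg.cls_id and ids[-1] == cfg.sep_id

    def test_marker_token_is_atomic(self):
        cfg = self._config()
        ids, pos = tokenize_sample(f"a {OPEN_MARKER} b {CLOSE_MARKER} c", ["m1"], cfg)
        assert ids.count(cfg.open_marker_id) == 1
        assert pos == {"m1": 2}

    def test_truncation_keeps_prefix_with_sep_last(self):
        cfg = self._config(max_length=8)
        ids, _ = tokenize_sample(" ".join("a" for _ in range(20)), [], cfg)
        assert len(ids) == 8
        assert ids[-1] == cfg.sep_id

    def test_truncated_mention_is_dropped_without_orphan_markers(self):
        cfg = self._config(max_length=8)
        text = f"{OPEN_MARKER} a {CLOSE_MARKER} b c d {OPEN_MARKER} e {CLOSE_MARKER}"
        ids, pos = tokenize_sample(text, ["m1", "m2"], cfg)
        assert pos == {"m1": 1}

    def test_open_marker_without_close_in_window_not_reported(self):
        cfg = self._config(max_length=6)
        text = f"a b {OPEN_MARKER} c {CLOSE_MARKER}"
        ids, pos = tokenize_sample(text, ["m1"], cfg)
        # close marker is truncated away -> mention must not be reported
        assert pos == {}


class TestMakeLabels:
    def test_coref_pairs_partition_by_entity_id(self):
        mentions = [
            EntityMention("m1", 0, 1, "a", "Gene", "E1"),
            EntityMention("m2", 2, 3, "b", "Gene", "E1"),
            EntityMention("m3", 4, 5, "c", "Chemical", "E2"),
        ]
        doc = AnnotatedDocument("1", "a b c", "x", mentions, [])
        cr, ept, re_label, tnt = make_labels(doc, ("E1", "E2"), _mini_schema())
        got = {(a, b): y for a, b, y in cr}
        assert got == {("m1", "m2"): 1, ("m1", "m3"): 0, ("m2", "m3"): 0}
        assert ept == ("Chemical", "Gene")
        assert re_label == NONE_LABEL and tnt == NONE_LABEL

    def test_single_mention_per_entity_gives_one_noncoref_pair(self, toy_doc):
        cr, _, re_label, tnt = make_labels(toy_doc, ("C1", "G1"), _mini_schema())
        assert [y for _, _, y in cr] == [0]
        assert re_label == "Bind" and tnt == "Novel"

    def test_re_label_none_iff_tnt_label_none(self, small_setup):
        _, _, _, samples = small_setup
        for s in samples:
            assert (s.re_label == NONE_LABEL) == (s.tnt_label == NONE_LABEL)


class TestBuildSamples:
    def test_sample_count_without_filtering(self, small_setup):
        docs, schema, enc, _ = small_setup
        for doc in docs[:4]:
            n = len(doc.entity_ids)
            samples = build_samples(
                doc, LabelSchema(schema.entity_types, schema.relation_types, {}),
                enc, keep_unconstrained=True,
            )
            assert len(samples) == n * (n - 1) // 2

    def test_marker_positions_point_at_open_markers(self, small_setup):
        _, _, enc, samples = small_setup
        for s in samples:
            for pos in s.open_marker_positions.values():
                assert s.token_ids[pos] == enc.open_marker_id

    def test_cr_pairs_cover_surviving_focal_mentions(self, small_setup):
        _, _, _, samples = small_setup
        for s in samples:
            marked = set(s.open_marker_positions)
            pair_ids = {m for a, b, _ in s.cr_pairs for m in (a, b)}
            assert pair_ids == marked if len(marked) > 1 else pair_ids <= marked

    def test_degenerate_flag_only_when_an_entity_lost_all_mentions(self, small_setup):
        _, _, _, samples = small_setup
        for s in samples:
            covered = {s.mention_entity[m] for m in s.open_marker_positions}
            assert s.degenerate == (covered != set(s.focal_pair))
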