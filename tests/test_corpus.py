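"""Corpus container, format readers and their validation contracts."""

import pytest

from relmine.corpus import (
    AlignmentError,
    AnnotatedSentence,
    ConstituencyTree,
    DependencyGraph,
    EntityMention,
    ParseError,
    Token,
    ValidationError,
    attach_constituents,
    attach_dependencies,
    parse_bracketed,
    read_sentences,
    write_sentences,
)


def _toks(*surfaces):
    return [Token(i, s, s.lower()) for i, s in enumerate(surfaces, start=1)]


class TestSentenceFormat:
    def test_read_record_with_entities_and_gold(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"sid": "s1", "tokens": ["A", "binds", "B"], '
            '"entities": [{"id": "e1", "start": 1, "end": 1, "name": "A"}, '
            '{"id": "e2", "start": 3, "end": 3, "name": "B"}], '
            '"gold": [["e1", "e2"]]}\n'
        )
        (sent,) = read_sentences(path)
        assert sent.sid == "s1"
        assert [t.surface for t in sent.tokens] == ["A", "binds", "B"]
        assert sent.gold_pairs == {frozenset({"e1", "e2"})}

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_sentences(path) == []

    def test_inverted_span_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"sid": "s1", "tokens": ["A", "b", "c", "d", "e"], '
            '"entities": [{"id": "e1", "start": 5, "end": 3, "name": "A"}]}\n'
        )
        with pytest.raises(ValidationError, match="start 5 > end 3"):
            read_sentences(path)

    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"sid": "s1", "tokens": ["A"]}\n{broken\n')
        with pytest.raises(ParseError, match="line 2"):
            read_sentences(path)

    def test_overlapping_distinct_spans_rejected(self):
        with pytest.raises(ValidationError, match="overlaps"):
            AnnotatedSentence(
                "s1",
                _toks("A", "B", "C"),
                [EntityMention("e1", 1, 2, "AB"), EntityMention("e2", 2, 3, "BC")],
            )

    def test_identical_spans_deduplicated(self):
        sent = AnnotatedSentence(
            "s1",
            _toks("A", "B"),
            [EntityMention("e1", 1, 1, "A"), EntityMention("e1b", 1, 1, "A")],
        )
        assert [e.id for e in sent.entities] == ["e1"]

    def test_round_trip_identity(self, tmp_path, small_corpus):
        path = tmp_path / "rt.jsonl"
        write_sentences(small_corpus, path)
        back = read_sentences(path)
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus, back):
            assert a.sid == b.sid
            assert a.tokens == b.tokens
            assert a.entities == b.entities
            assert a.gold_pairs == b.gold_pairs


class TestDependencies:
    def test_star_graph_from_conllu(self, tmp_path):
        path = tmp_path / "d.conllu"
        path.write_text(
            "1\tA\ta\t_\tNN\t_\t2\tnsubj\t_\t_\n"
            "2\tbinds\tbind\t_\tVBZ\t_\t0\troot\t_\t_\n"
            "3\tB\tb\t_\tNN\t_\t2\tdobj\t_\t_\n\n"
        )
        sent = AnnotatedSentence("s1", _toks("A", "binds", "B"), [])
        attach_dependencies([sent], path)
        g = sent.dependencies
        assert sorted(g.undirected.edges()) == [(1, 2), (2, 3)]
        assert g.head(2) == g.ROOT  # attached to the artificial root

    def test_token_count_mismatch(self, tmp_path):
        path = tmp_path / "d.conllu"
        path.write_text("1\tA\ta\t_\tNN\t_\t0\troot\t_\t_\n\n")
        sent = AnnotatedSentence("s1", _toks("A", "B"), [])
        with pytest.raises(AlignmentError):
            attach_dependencies([sent], path)

    def test_cyclic_heads_rejected(self):
        with pytest.raises(ValidationError, match="cyclic"):
            DependencyGraph(2, [(2, 1, "dep"), (1, 2, "dep")])

    def test_multiple_heads_rejected(self):
        with pytest.raises(ValidationError, match="multiple heads"):
            DependencyGraph(3, [(2, 1, "a"), (3, 1, "b"), (0, 2, "root"), (2, 3, "c")])

    def test_undirected_adjacency_is_symmetric(self, small_corpus):
        for sent in small_corpus:
            g = sent.dependencies.undirected
            for u, v in g.edges():
                assert g.has_edge(v, u)


class TestConstituents:
    def test_attach_simple_tree(self, tmp_path):
        path = tmp_path / "t.trees"
        path.write_text("(S (NP (NN A)) (VP (VBZ binds) (NP (NN B))))\n")
        sent = AnnotatedSentence("s1", _toks("A", "binds", "B"), [])
        attach_constituents([sent], path)
        labels = {n.label for n in sent.constituents.root.iter_nodes() if not n.is_leaf}
        assert {"S", "NP", "VP"} <= labels
        assert [l.token_index for l in sent.constituents.root.leaves()] == [1, 2, 3]

    def test_unbalanced_brackets(self):
        with pytest.raises(ParseError):
            parse_bracketed("(S (NP A)")

    def test_leaf_count_mismatch(self, tmp_path):
        path = tmp_path / "t.trees"
        path.write_text("(S (NN A) (NN B))\n")
        sent = AnnotatedSentence("s1", _toks("A", "B", "C"), [])
        with pytest.raises(AlignmentError):
            attach_constituents([sent], path)


class TestEntityPairs:
    def test_pairs_ordered_by_surface(self, erbb_sentence):
        pairs = erbb_sentence.entity_pairs()
        assert len(pairs) == 6
        for pair in pairs:
            assert pair.m1.end < pair.m2.start
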