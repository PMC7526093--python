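import pytest

from subtag.annotation_io import (
    AnnotatedDocument,
    EntitySpan,
    LabelSequence,
    Scheme,
)
from subtag.labeling import (
    bert_to_iob_token,
    bert_to_wp,
    char_iob_from_spans,
    count_straddles,
    decode_entities,
    gold_label_sequence,
    project_bert_labels,
    project_trad_labels,
    token_labels_to_char_iob,
    trad_to_iob_char,
    trad_units,
)
from subtag.tokenization import SubwordToken, tokenize_with_offsets


class TestBertProjection:
    def test_postposition_continuation_gets_o_not_x(self, toy_doc, toy_tokens):
        # "abcd" is the entity; "##e" is a glued particle outside it
        labels = project_bert_labels(toy_doc, toy_tokens)
        assert labels.labels == ("B-BP", "X", "O", "O")

    def test_no_entities_all_o(self, toy_tokens):
        doc = AnnotatedDocument("d", "abcde fg", ())
        assert project_bert_labels(doc, toy_tokens).labels == ("O",) * 4

    def test_word_initial_token_inside_entity_is_inside_tag(self):
        doc = AnnotatedDocument("d", "ab cd", (EntitySpan(0, 5, "BP"),))
        toks = [SubwordToken("ab", 0, 2), SubwordToken("cd", 3, 5)]
        assert project_bert_labels(doc, toks).labels == ("B-BP", "I-BP")

    def test_token_outside_text_rejected(self, toy_doc):
        with pytest.raises(ValueError, match="outside"):
            project_bert_labels(toy_doc, [SubwordToken("xx", 7, 12)])

    def test_straddle_counter(self):
        doc = AnnotatedDocument("d", "abcd", (EntitySpan(0, 2, "DZ"),))
        toks = [SubwordToken("abc", 0, 3), SubwordToken("##d", 3, 4)]
        assert count_straddles(doc, toks) == 1


class TestSchemeConversions:
    def test_wp_replaces_x_with_literal_copy(self, toy_tokens):
        bert = LabelSequence(Scheme.BERT, ("B-BP", "X", "O", "O"))
        assert bert_to_wp(bert, toy_tokens).labels == ("B-BP", "B-BP", "O", "O")

    def test_wp_propagates_through_x_runs(self):
        bert = LabelSequence(Scheme.BERT, ("B-DZ", "X", "X"))
        assert bert_to_wp(bert).labels == ("B-DZ", "B-DZ", "B-DZ")

    def test_wp_no_x_is_identity(self):
        bert = LabelSequence(Scheme.BERT, ("O", "O"))
        assert bert_to_wp(bert).labels == ("O", "O")

    def test_wp_leading_x_rejected(self):
        bert = LabelSequence(Scheme.BERT, ("X", "O"))
        with pytest.raises(ValueError, match="position 0"):
            bert_to_wp(bert)

    def test_wp_idempotent_on_its_output(self, toy_tokens):
        bert = LabelSequence(Scheme.BERT, ("B-BP", "X", "O", "O"))
        wp = bert_to_wp(bert, toy_tokens)
        again = bert_to_wp(LabelSequence(Scheme.BERT, wp.labels), toy_tokens)
        assert again.labels == wp.labels

    def test_iob_token_from_bert(self, toy_tokens):
        bert = LabelSequence(Scheme.BERT, ("B-BP", "X", "O", "O"))
        assert bert_to_iob_token(bert, toy_tokens).labels == ("B-BP", "I-BP", "O", "O")

    def test_iob_token_already_iob_unchanged(self):
        bert = LabelSequence(Scheme.BERT, ("B-DZ", "I-DZ"))
        assert bert_to_iob_token(bert).labels == ("B-DZ", "I-DZ")


class TestCharSchemes:
    def test_trad_labels_cover_internal_whitespace(self):
        doc = AnnotatedDocument("d", "ab cd", (EntitySpan(0, 5, "BP"),))
        labels = project_trad_labels(doc)
        assert labels.labels == ("B-BP", "I-BP", "I-BP", "I-BP", "I-BP")
        assert trad_units(doc.text) == "ab^cd"

    def test_single_char_entity(self):
        doc = AnnotatedDocument("d", "a bc", (EntitySpan(0, 1, "SX"),))
        assert project_trad_labels(doc).labels[0] == "B-SX"

    def test_iob_char_blanks_whitespace(self):
        doc = AnnotatedDocument("d", "ab cd", (EntitySpan(0, 5, "BP"),))
        trad = project_trad_labels(doc)
        iob = trad_to_iob_char(trad, doc.text)
        assert iob.labels == ("B-BP", "I-BP", "O", "I-BP", "I-BP")

    def test_iob_char_no_whitespace_identity(self):
        doc = AnnotatedDocument("d", "abcd", (EntitySpan(0, 4, "DZ"),))
        trad = project_trad_labels(doc)
        assert trad_to_iob_char(trad, doc.text).labels == trad.labels

    def test_length_mismatch_rejected(self):
        labels = LabelSequence(Scheme.TRAD_CHAR, ("O", "O"))
        with pytest.raises(ValueError, match="mismatch"):
            trad_to_iob_char(labels, "abc")

    def test_trad_idempotent_through_iob(self):
        doc = AnnotatedDocument("d", "ab cd ef", (EntitySpan(3, 8, "DZ"),))
        iob = trad_to_iob_char(project_trad_labels(doc), doc.text)
        again = trad_to_iob_char(
            LabelSequence(Scheme.TRAD_CHAR, iob.labels), doc.text)
        assert again.labels == iob.labels


class TestTokenLabelsToCharIob:
    def test_projection_example(self, toy_doc, toy_tokens):
        bert = project_bert_labels(toy_doc, toy_tokens)
        chars = token_labels_to_char_iob(toy_tokens, bert, toy_doc.text)
        assert chars.labels == ("B-BP", "I-BP", "I-BP", "I-BP", "O", "O", "O", "O")

    def test_all_o(self, toy_tokens):
        labels = LabelSequence(Scheme.IOB_TOKEN, ("O",) * 4)
        chars = token_labels_to_char_iob(toy_tokens, labels, "abcde fg")
        assert set(chars.labels) == {"O"}

    def test_adjacent_same_type_entities_stay_separate(self):
        toks = [SubwordToken("ab", 0, 2), SubwordToken("cd", 3, 5)]
        labels = LabelSequence(Scheme.IOB_TOKEN, ("B-DZ", "B-DZ"))
        chars = token_labels_to_char_iob(toks, labels, "ab cd")
        decoded = decode_entities("ab cd", chars)
        assert [ (s.char_start, s.char_end) for s in decoded.spans ] == [(0, 2), (3, 5)]


class TestDecodeEntities:
    def test_bert_inverse_of_projection(self, toy_doc, toy_tokens):
        bert = project_bert_labels(toy_doc, toy_tokens)
        wp = bert_to_wp(bert, toy_tokens)
        decoded = decode_entities(toy_tokens, wp)
        assert decoded.spans == [EntitySpan(0, 4, "BP")]
        assert decoded.repairs == 0

    def test_invalid_start_repaired_and_counted(self):
        toks = [SubwordToken("a", 0, 1), SubwordToken("bc", 2, 4),
                SubwordToken("de", 5, 7)]
        labels = LabelSequence(Scheme.IOB_TOKEN, ("O", "I-DZ", "I-DZ"))
        decoded = decode_entities(toks, labels)
        assert decoded.spans == [EntitySpan(2, 7, "DZ")]
        assert decoded.repairs == 1

    def test_all_o_decodes_empty(self, toy_tokens):
        labels = LabelSequence(Scheme.IOB_TOKEN, ("O",) * 4)
        assert decode_entities(toy_tokens, labels).spans == []

    def test_iob_char_rejoins_across_whitespace(self):
        text = "ab cd"
        labels = LabelSequence(Scheme.IOB_CHAR,
                               ("B-BP", "I-BP", "O", "I-BP", "I-BP"))
        decoded = decode_entities(text, labels)
        assert decoded.spans == [EntitySpan(0, 5, "BP")]

    def test_unknown_scheme_mismatch_rejected(self, toy_tokens):
        labels = LabelSequence(Scheme.WP, ("O",) * 4)
        with pytest.raises(ValueError, match="decode as"):
            decode_entities(toy_tokens, labels, Scheme.IOB_TOKEN)


class TestCorpusWideInvariants:
    def test_token_round_trip_and_scheme_consistency(self, small_corpus, small_vocab):
        for doc in small_corpus:
            toks = tokenize_with_offsets(doc.text, small_vocab)
            bert = project_bert_labels(doc, toks)
            wp = bert_to_wp(bert, toks)
            iob = bert_to_iob_token(bert, toks)
            spans = {scheme: tuple(decode_entities(toks, labs).spans)
                     for scheme, labs in
                     [("bert", bert), ("wp", wp), ("iob", iob)]}
            assert spans["bert"] == doc.spans
            assert spans["wp"] == doc.spans
            assert spans["iob"] == doc.spans

    def test_char_round_trip(self, small_corpus):
        for doc in small_corpus:
            iobc = gold_label_sequence(doc, Scheme.IOB_CHAR)
            assert tuple(decode_entities(doc.text, iobc).spans) == doc.spans
            trad = gold_label_sequence(doc, Scheme.TRAD_CHAR)
            assert tuple(decode_entities(doc.text, trad).spans) == doc.spans

    def test_char_iob_from_spans_matches_trad_route(self, small_corpus):
        for doc in small_corpus[:40]:
            direct = char_iob_from_spans(doc.text, doc.spans, doc.tag_set)
            via_trad = trad_to_iob_char(project_trad_labels(doc), doc.text)
            assert direct.labels == via_trad.labels

    def test_continuation_outside_entities_never_x(self, small_corpus, small_vocab):
        for doc in small_corpus:
            toks = tokenize_with_offsets(doc.text, small_vocab)
            bert = project_bert_labels(doc, toks)
            for tok, lab in zip(toks, bert):
                outside = all(not (sp.char_start <= tok.char_start < sp.char_end)
                              for sp in doc.spans)
                if tok.is_continuation and outside:
                    assert lab == "O"
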