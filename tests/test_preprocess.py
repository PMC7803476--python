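"""Sentence splitting, tokenization, cleaning and BIO conversion."""

import pytest
from hypothesis import given, strategies as st

from famhx.docmodel import Document, Sentence
from famhx.preprocess import (
    WordpieceVocab,
    bio_to_spans,
    clean_sentence,
    default_stop_set,
    is_valid_bio,
    spans_to_bio,
    split_sentences,
    tokenize_subwords,
    tokenize_words,
)


def _sentence(text: str) -> Sentence:
    return Sentence(doc_id="t", index=0, start=0, end=len(text), text=text)


class TestSplitSentences:
    def test_terminal_periods(self):
        sents = split_sentences(Document("d", "A. B."))
        assert [s.text for s in sents] == ["A.", "B."]

    def test_empty_document(self):
        assert split_sentences(Document("d", "")) == []

    def test_spans_index_into_document(self):
        doc = Document("d", "The aunt has cancer. She is well.\nNew line sentence")
        for s in split_sentences(doc):
            assert doc.text[s.start : s.end] == s.text

    def test_hand_labeled_fixture(self):
        # abbreviation-rich fixture; expected segmentation fixed by hand
        text = (
            "Mrs. Smith was seen by Dr. Jones today. "
            "Her mother has diabetes type 2. "
            "The B.P. was 120/80 at 3.5 months. "
            "Family history is notable for cancer! "
            "Is there anything else? "
            "The patient's father died in 1990. "
            "His brother is well. "
            "No known allergies.\n"
            "Plan: follow up in 2 weeks. "
            "Signed by Dr. Smith."
        )
        expected = [
            "Mrs. Smith was seen by Dr. Jones today.",
            "Her mother has diabetes type 2.",
            "The B.P. was 120/80 at 3.5 months.",
            "Family history is notable for cancer!",
            "Is there anything else?",
            "The patient's father died in 1990.",
            "His brother is well.",
            "No known allergies.",
            "Plan: follow up in 2 weeks.",
            "Signed by Dr. Smith.",
        ]
        assert [s.text for s in split_sentences(Document("d", text))] == expected

    def test_sentences_ordered_and_non_overlapping(self):
        doc = Document("d", "One sentence here. Another one. And a third one.")
        sents = split_sentences(doc)
        for a, b in zip(sents, sents[1:]):
            assert a.end <= b.start
            assert a.index + 1 == b.index


class TestTokenizeWords:
    def test_basic_punctuation_split(self, sentence_factory):
        toks = tokenize_words(sentence_factory("has diabetes."))
        assert [t.surface for t in toks] == ["has", "diabetes", "."]

    def test_clitic_split(self, sentence_factory):
        toks = tokenize_words(sentence_factory("patient's"))
        assert [t.surface for t in toks] == ["patient", "'s"]

    def test_empty(self, sentence_factory):
        assert tokenize_words(sentence_factory("")) == []

    def test_spans_and_word_indices(self, sentence_factory):
        s = sentence_factory("the patients' uncle has one son")
        toks = tokenize_words(s)
        for i, t in enumerate(toks):
            assert s.text[t.start : t.end] == t.surface
            assert t.word_index == i


class TestTokenizeSubwords:
    def test_carcinoma_splits_into_three_pieces(self, sentence_factory):
        vocab = WordpieceVocab.default()
        toks = tokenize_subwords(sentence_factory("carcinoma"), vocab)
        assert [t.surface for t in toks] == ["car", "##cin", "##oma"]
        assert len({t.word_index for t in toks}) == 1

    def test_common_word_stays_whole(self, sentence_factory):
        vocab = WordpieceVocab.default()
        toks = tokenize_subwords(sentence_factory("mother"), vocab)
        assert [t.surface for t in toks] == ["mother"]

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=15))
    def test_pieces_concatenate_back_to_word(self, word):
        vocab = WordpieceVocab.default()
        pieces = vocab.segment(word)
        rebuilt = "".join(p[2:] if p.startswith("##") else p for p in pieces)
        assert rebuilt == word

    def test_uncoverable_char_becomes_unk(self, sentence_factory):
        vocab = WordpieceVocab(["a", "##b"])
        toks = tokenize_subwords(sentence_factory("axb"), vocab)
        assert [t.surface for t in toks] == ["a", "[UNK]", "##b"]
        assert len({t.word_index for t in toks}) == 1


class TestCleanSentence:
    def test_worked_example(self, sentence_factory):
        s = sentence_factory("the patients' uncle has one son")
        assert clean_sentence(s, default_stop_set()).text == "patients uncle son"

    def test_empty_stop_set_keeps_all_words(self, sentence_factory):
        s = sentence_factory("uncle son")
        cs = clean_sentence(s, frozenset())
        assert cs.text == "uncle son"

    def test_all_tokens_removed(self, sentence_factory):
        s = sentence_factory("the has one")
        assert clean_sentence(s, frozenset({"the", "has", "one"})).text == ""

    @given(st.lists(st.sampled_from("the aunt has one son cancer died".split()),
                    min_size=0, max_size=12))
    def test_never_reorders_and_never_grows(self, words):
        s = _sentence(" ".join(words))
        cs = clean_sentence(s, default_stop_set())
        original = tokenize_words(s)
        assert len(cs.kept_tokens) <= len(original)
        positions = [original.index(t) for t in cs.kept_tokens]
        assert positions == sorted(positions)


class TestBio:
    def _tokens(self, text, sentence_factory):
        return tokenize_words(sentence_factory(text))

    def test_definition_example(self, sentence_factory):
        s = sentence_factory("my aunt has lung cancer")
        toks = tokenize_words(s)
        entities = [((3, 7), "PFM"), ((12, 23), "Obs")]  # "aunt", "lung cancer"
        assert spans_to_bio(toks, entities) == ["O", "B-PFM", "O", "B-Obs", "I-Obs"]

    def test_no_entities_all_o(self, sentence_factory):
        toks = self._tokens("nothing here", sentence_factory)
        assert spans_to_bio(toks, []) == ["O", "O"]

    def test_overlap_keeps_longer(self, sentence_factory):
        s = sentence_factory("diabetes type 2")
        toks = tokenize_words(s)
        tags = spans_to_bio(toks, [((0, 15), "Obs"), ((0, 8), "Obs")])
        assert tags == ["B-Obs", "I-Obs", "I-Obs"]

    def test_lenient_repair_of_stray_inside_tag(self, sentence_factory):
        toks = self._tokens("cancer", sentence_factory)
        spans = bio_to_spans(toks, ["I-Obs"])
        assert spans == [((0, 6), "Obs")]

    def test_all_o_yields_nothing(self, sentence_factory):
        toks = self._tokens("a b c", sentence_factory)
        assert bio_to_spans(toks, ["O", "O", "O"]) == []

    @given(st.data())
    def test_round_trip_identity(self, data):
        words = data.draw(
            st.lists(st.sampled_from(["aunt", "lung", "cancer", "has", "my"]),
                     min_size=1, max_size=10)
        )
        s = _sentence(" ".join(words))
        toks = tokenize_words(s)
        # build random non-overlapping boundary-aligned entities
        n = len(toks)
        entities = []
        i = 0
        while i < n:
            if data.draw(st.booleans()):
                width = data.draw(st.integers(1, min(3, n - i)))
                cls = data.draw(st.sampled_from(["Obs", "PFM"]))
                entities.append(((toks[i].start, toks[i + width - 1].end), cls))
                i += width + 1
            else:
                i += 1
        tags = spans_to_bio(toks, entities)
        assert is_valid_bio(tags)
        assert sorted(bio_to_spans(toks, tags)) == sorted(entities)
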