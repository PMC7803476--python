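"""Rule-based family-member detection workflow."""

import pytest

from famhx.docmodel import Document
from famhx.preprocess import clean_sentence, default_stop_set, split_sentences
from famhx.rule_engine import (
    PATIENT,
    ComplexRule,
    RuleEngineConfig,
    SentenceContext,
    analyze_document,
    apply_complex_rules,
    detect_partner_scope,
    detect_patient_subject,
    exact_match_relatives,
    extract_family_members,
    link_previous_sentence,
)


def _clean(text, sentence_factory):
    return clean_sentence(sentence_factory(text), default_stop_set())


class TestDetectPatientSubject:
    def test_relative_after_patient_anchor_is_not_patient(self, sentence_factory):
        assert not detect_patient_subject(_clean("the patients' father has cancer", sentence_factory))

    def test_explicit_patient_no_relative(self, sentence_factory):
        assert detect_patient_subject(_clean("the patient is healthy", sentence_factory))

    def test_empty_sentence(self, sentence_factory):
        assert not detect_patient_subject(_clean("", sentence_factory))


class TestComplexRules:
    def test_paternal_grandparent_worked_example(self, sentence_factory):
        cs = _clean("the patient's paternal grandparents are deceased", sentence_factory)
        assert cs.text == "patients paternal grandparents deceased"
        rule = ComplexRule(
            keyword="grandparents",
            before_terms=("patients", "paternal"),
            action="Keep",
            relative="Grandparent",
            side="Paternal",
        )
        m = apply_complex_rules(cs, [rule])
        assert (m.relation, m.side) == ("Grandparent", "Paternal")

    def test_no_keyword_returns_none(self, sentence_factory):
        cs = _clean("the patient is well", sentence_factory)
        rule = ComplexRule(keyword="grandparents", relative="Grandparent")
        assert apply_complex_rules(cs, [rule]) is None

    def test_earlier_rule_wins(self, sentence_factory):
        cs = _clean("the patients' maternal grandparents are well", sentence_factory)
        first = ComplexRule(
            keyword="grandparents", before_terms=("patients",),
            relative="Grandparent", side="Maternal",
        )
        second = ComplexRule(
            keyword="grandparents", before_terms=("patients",),
            relative="Grandparent", side="Paternal",
        )
        m = apply_complex_rules(cs, [first, second])
        assert m.side == "Maternal"

    def test_before_terms_must_appear_in_order(self, sentence_factory):
        cs = _clean("paternal side of the patients' grandparents", sentence_factory)
        rule = ComplexRule(
            keyword="grandparents", before_terms=("patients", "paternal"),
            relative="Grandparent", side="Paternal",
        )
        assert apply_complex_rules(cs, [rule]) is None


class TestExactMatch:
    def test_cascade_composes_to_cousin(self, sentence_factory):
        cs = _clean("the patients' uncle has one son", sentence_factory)
        mentions = exact_match_relatives(cs)
        assert [(m.relation, m.side) for m in mentions] == [("Cousin", "NA")]

    def test_side_word_resolution(self, sentence_factory):
        cs = _clean("the patients' maternal aunt", sentence_factory)
        mentions = exact_match_relatives(cs)
        assert [(m.relation, m.side) for m in mentions] == [("Aunt", "Maternal")]

    def test_no_relatives(self, sentence_factory):
        assert exact_match_relatives(_clean("patient doing well", sentence_factory)) == []

    def test_partner_chain_flagged(self, sentence_factory):
        cs = _clean("his wife's maternal aunt has one son", sentence_factory)
        mentions = exact_match_relatives(cs)
        assert [(m.relation, m.side, m.partner_branch) for m in mentions] == [
            ("Cousin", "Maternal", True)
        ]


class TestLinking:
    def test_carry_previous_subject(self):
        from famhx.docmodel import FamilyMemberMention

        aunt = FamilyMemberMention("Aunt", "Maternal")
        prev = SentenceContext(aunt, False, False)
        ctx = link_previous_sentence(prev, found_now=False)
        assert ctx.current_subject is aunt
        assert ctx.carried_from_previous

    def test_first_sentence_defaults_to_patient(self):
        ctx = link_previous_sentence(None, found_now=False)
        assert ctx.current_subject is PATIENT

    def test_new_subject_replaces_context(self):
        from famhx.docmodel import FamilyMemberMention

        prev = SentenceContext(FamilyMemberMention("Aunt"), False, False)
        son = FamilyMemberMention("Son")
        ctx = link_previous_sentence(prev, found_now=True, new_subject=son)
        assert ctx.current_subject is son
        assert not ctx.carried_from_previous


class TestPartnerScope:
    def test_wife_sentence(self, sentence_factory):
        s = sentence_factory("His wife's maternal aunt has one son.")
        assert detect_partner_scope(s, None)

    def test_patient_sentence(self, sentence_factory):
        s = sentence_factory("The patient's grandmother had cancer")
        assert not detect_partner_scope(s, None)

    def test_patient_term_outweighs_partner_term(self, sentence_factory):
        s = sentence_factory("The patient and his wife were both seen today.")
        assert not detect_partner_scope(s, None)

    def test_carried_partner_context(self, sentence_factory):
        ctx = SentenceContext(None, partner_scope=True, carried_from_previous=True)
        assert detect_partner_scope(sentence_factory("She has a brother."), ctx)


class TestExtractFamilyMembers:
    def test_partner_branch_discarded_end_to_end(self):
        doc = Document("d", "His wife's maternal aunt has one son.")
        assert extract_family_members(doc) == []

    def test_two_relatives_in_one_sentence(self):
        doc = Document(
            "d",
            "The patient's grandmother had cancer in her late 60s but his "
            "grandfather has no history of cancer.",
        )
        assert [(m.relation, m.side) for m in extract_family_members(doc)] == [
            ("Grandmother", "NA"),
            ("Grandfather", "NA"),
        ]

    def test_empty_note(self):
        assert extract_family_members(Document("d", "")) == []

    def test_output_only_eligible_relations(self):
        doc = Document(
            "d",
            "The patient's nephew has asthma. The patient's great grandmother "
            "has diabetes. His wife has arthritis.",
        )
        assert extract_family_members(doc) == []

    def test_deduplication_on_relation_and_side(self):
        doc = Document(
            "d",
            "The patient's brother has asthma. The patient's brother has eczema.",
        )
        assert [(m.relation, m.side) for m in extract_family_members(doc)] == [
            ("Brother", "NA")
        ]

    def test_complex_rules_only_refine_exact_output(self):
        """Removing the rule file never adds family members beyond exact
        matching (rule layering monotonicity)."""
        doc = Document(
            "d",
            "The patient's paternal grandparents are deceased. "
            "The patient's father's children are healthy. "
            "The patient's maternal aunt has cancer.",
        )
        with_rules = {
            (m.relation) for m in extract_family_members(doc)
        }
        bare = RuleEngineConfig(complex_rules=[])
        without_rules = {(m.relation) for m in extract_family_members(doc, bare)}
        # discard rules may remove mentions; keep rules only refine sides
        assert with_rules <= without_rules

    def test_pronoun_continuation_carries_subject(self):
        doc = Document(
            "d",
            "The patient's maternal aunt was seen. She has a son with asthma.",
        )
        analyses = analyze_document(doc)
        subj = analyses[1].subject
        # "her son" composes against the carried aunt context at relation level
        assert analyses[0].subject.relation == "Aunt"
        assert subj is not None
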