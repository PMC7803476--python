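"""Rule-based family-member detection workflow.

Documents are processed sentence by sentence over cleaned text.  Each
sentence runs through: a patient-subject test (is the sentence about the
patient themself?), complex keyword rules (keyword + ordered before/after
context terms, keep-or-discard), exact lexicon matching with cascade
composition ("patients uncle son" -> Cousin), and sentence linking (a
sentence with no detected subject inherits the previous sentence's subject;
the first sentence defaults to the patient).  A partner-scope detector
always runs: sentences governed by the patient's partner ("His wife's
maternal aunt...") have their relatives flagged as partner-branch, which
eligibility filtering later removes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

from famhx.docmodel import Document, FamilyMemberMention, Sentence
from famhx.kinship import (
    SIDE_WORDS,
    CompositionTable,
    RelationLexicon,
    compose,
    default_composition_table,
    default_lexicon,
    is_eligible,
)
from famhx.preprocess import CleanSentence, clean_sentence, default_stop_set, split_sentences
from famhx.resources import load_tsv

logger = logging.getLogger(__name__)


class _Patient:
    """Sentinel subject: the patient themself."""

    def __repr__(self) -> str:  # pragma: no cover
        return "Patient"


PATIENT = _Patient()

Subject = Union[FamilyMemberMention, _Patient, None]

PATIENT_TERMS = frozenset({"patients", "pt"})
PARTNER_TERMS = frozenset({"wife", "husband", "partner", "spouse"})
# co-occurrence weighting: explicit patient terms outweigh partner terms
PATIENT_WEIGHT = 2
PARTNER_WEIGHT = 1


@dataclass(frozen=True)
class ComplexRule:
    """Six-part rule: trigger keyword, ordered before/after context terms,
    keep-or-discard action, and the emitted relative + side."""

    keyword: str
    before_terms: Tuple[str, ...] = ()
    after_terms: Tuple[str, ...] = ()
    action: str = "Keep"  # Keep | Discard
    relative: str = "Parent"
    side: str = "NA"

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("complex rule keyword must be non-empty")
        if self.action not in ("Keep", "Discard"):
            raise ValueError(f"unknown rule action: {self.action!r}")


def load_complex_rules() -> list[ComplexRule]:
    rules = []
    for row in load_tsv("complex_rules.tsv"):
        keyword, before, after, action, relative, side = (row + [""] * 6)[:6]
        rules.append(
            ComplexRule(
                keyword=keyword.lower(),
                before_terms=tuple(t for t in before.lower().split(",") if t),
                after_terms=tuple(t for t in after.lower().split(",") if t),
                action=action,
                relative=relative or "Parent",
                side=side or "NA",
            )
        )
    return rules


@dataclass(frozen=True)
class SentenceContext:
    current_subject: Subject = None
    partner_scope: bool = False
    carried_from_previous: bool = False


@dataclass
class RuleEngineConfig:
    stop_set: frozenset[str] = field(default_factory=default_stop_set)
    lexicon: RelationLexicon = field(default_factory=default_lexicon)
    composition: CompositionTable = field(default_factory=default_composition_table)
    complex_rules: Sequence[ComplexRule] = field(default_factory=load_complex_rules)


@dataclass
class SentenceAnalysis:
    """Per-sentence result: detected mentions and the resolved subject."""

    sentence: Sentence
    clean: CleanSentence
    mentions: list[FamilyMemberMention]
    subject: Subject
    partner_scope: bool
    context: SentenceContext


# --- lexicon scanning -----------------------------------------------------


@dataclass(frozen=True)
class _Hit:
    start: int  # word index in the cleaned sentence, inclusive
    end: int  # exclusive
    relation: str
    side: str


def _scan_hits(words: Sequence[str], lexicon: RelationLexicon) -> list[_Hit]:
    """Longest-match-first lexicon scan; a directly preceding side word
    ("maternal"/"paternal") is absorbed into the hit."""
    hits: list[_Hit] = []
    i = 0
    n = len(words)
    while i < n:
        side = None
        start = i
        j = i
        if words[j] in SIDE_WORDS and j + 1 < n:
            side = SIDE_WORDS[words[j]]
            j += 1
        matched = None
        for width in range(min(lexicon.max_words, n - j), 0, -1):
            entry = lexicon.lookup(" ".join(words[j : j + width]))
            if entry is not None:
                matched = (entry, j + width)
                break
        if matched is None:
            i += 1
            continue
        (relation, implied_side), end = matched
        hits.append(_Hit(start if side else j, end, relation, side or implied_side))
        i = end
    return hits


@dataclass(frozen=True)
class _ChainMention:
    mention: FamilyMemberMention
    word_start: int  # word range covered in the cleaned sentence
    word_end: int
    n_hits: int  # >1 means a composed cascade

    def covers(self, word_index: int) -> bool:
        return self.word_start <= word_index < self.word_end


def _chain_mentions(
    cs: CleanSentence,
    hits: Sequence[_Hit],
    table: CompositionTable,
    discard_positions: frozenset[int] = frozenset(),
) -> list[_ChainMention]:
    """Group adjacent hits into cascade chains and compose them.

    A chain headed by a partner term resolves the remaining chain normally
    but flags the mention as partner-branch.
    """
    mentions: list[_ChainMention] = []
    chain: list[_Hit] = []

    def flush() -> None:
        if not chain:
            return
        items = list(chain)
        chain.clear()
        if any(h.start in discard_positions for h in items):
            logger.debug("discarding chain at %s by complex rule", items[0].start)
            return
        partner = items[0].relation == "Partner"
        n_hits = len(items)
        word_start, word_end = items[0].start, items[-1].end
        if partner:
            items = items[1:]
        if not items:  # bare partner term: not a reportable relative
            return
        relation, side = items[0].relation, items[0].side
        for h in items[1:]:
            relation, side = compose((relation, side), h.relation, table)
            if side == "NA" and h.side != "NA":
                side = h.side
        first_tok = cs.kept_tokens[items[0].start]
        last_tok = cs.kept_tokens[items[-1].end - 1]
        mentions.append(
            _ChainMention(
                mention=FamilyMemberMention(
                    relation=relation,
                    side=side,
                    span=(cs.original.index, first_tok.start, last_tok.end),
                    partner_branch=partner,
                ),
                word_start=word_start,
                word_end=word_end,
                n_hits=n_hits,
            )
        )

    prev_end = None
    for hit in hits:
        if prev_end is not None and hit.start != prev_end:
            flush()
        chain.append(hit)
        prev_end = hit.end
    flush()
    return mentions


# --- workflow components --------------------------------------------------


def detect_patient_subject(
    cs: CleanSentence, lexicon: Optional[RelationLexicon] = None
) -> bool:
    """True iff a patient-reference term heads the cleaned sentence and no
    relative is mentioned (a leading "patients" before a relative is a
    possessive anchor, not the subject)."""
    lexicon = lexicon or default_lexicon()
    if not cs.words or cs.words[0] not in PATIENT_TERMS:
        return False
    return not _scan_hits(cs.words, lexicon)


def apply_complex_rules(
    cs: CleanSentence, rules: Sequence[ComplexRule]
) -> Optional[FamilyMemberMention]:
    mention, _rule, _pos = _apply_complex_rules(cs, rules)
    return mention


def _apply_complex_rules(
    cs: CleanSentence, rules: Sequence[ComplexRule]
) -> Tuple[Optional[FamilyMemberMention], Optional[ComplexRule], Optional[int]]:
    """First rule (file order) whose keyword and ordered context terms all
    occur fires; returns (mention, rule, keyword position)."""
    words = cs.words
    for rule in rules:
        for k, word in enumerate(words):
            if word != rule.keyword:
                continue
            if not _in_order(words[:k], rule.before_terms):
                continue
            if not _in_order(words[k + 1 :], rule.after_terms):
                continue
            if rule.action == "Discard":
                logger.debug("complex rule discards %r at %d", rule.keyword, k)
                return None, rule, k
            tok = cs.kept_tokens[k]
            mention = FamilyMemberMention(
                relation=rule.relative,
                side=rule.side,
                span=(cs.original.index, tok.start, tok.end),
            )
            logger.debug("complex rule keeps %r -> %s", rule.keyword, mention)
            return mention, rule, k
    return None, None, None


def _in_order(words: Sequence[str], terms: Sequence[str]) -> bool:
    it = iter(words)
    return all(term in it for term in terms)


def exact_match_relatives(
    cs: CleanSentence,
    lexicon: Optional[RelationLexicon] = None,
    table: Optional[CompositionTable] = None,
    discard_positions: frozenset[int] = frozenset(),
) -> list[FamilyMemberMention]:
    """Lexicon hits in the cleaned sentence, with adjacent side resolution
    and composition of consecutive relatives ("patients uncle son" ->
    Cousin)."""
    lexicon = lexicon or default_lexicon()
    table = table or default_composition_table()
    hits = _scan_hits(cs.words, lexicon)
    return [
        c.mention for c in _chain_mentions(cs, hits, table, discard_positions)
    ]


def link_previous_sentence(
    ctx_prev: Optional[SentenceContext],
    found_now: bool,
    new_subject: Subject = None,
    partner_now: bool = False,
) -> SentenceContext:
    """Carry the previous subject into a subject-less sentence.

    The first sentence of a document (no previous context) defaults to the
    patient."""
    if found_now:
        return SentenceContext(new_subject, partner_now, carried_from_previous=False)
    if ctx_prev is None:
        return SentenceContext(PATIENT, partner_now, carried_from_previous=False)
    return SentenceContext(
        ctx_prev.current_subject,
        ctx_prev.partner_scope or partner_now,
        carried_from_previous=True,
    )


def detect_partner_scope(s: Sentence, ctx: Optional[SentenceContext]) -> bool:
    """Is this sentence governed by the patient's partner?

    Partner terms flip the scope unless explicit patient terms co-occur
    (patient terms are weighted double and win ties); with no partner term
    the carried context decides.
    """
    words = [w.lower().rstrip("'s") for w in s.text.split()]
    words = [w.strip(".,;:!?()\"'") for w in words]
    partner_score = PARTNER_WEIGHT * sum(w in PARTNER_TERMS for w in words)
    patient_score = PATIENT_WEIGHT * sum(
        w in ("patient", "patients", "pt") for w in words
    )
    if partner_score == 0:
        return bool(ctx and ctx.partner_scope and patient_score == 0)
    return partner_score > patient_score


# --- document-level driver ------------------------------------------------


def analyze_document(
    doc: Document, config: Optional[RuleEngineConfig] = None
) -> list[SentenceAnalysis]:
    """Run the full per-sentence workflow and return sentence analyses with
    all detected mentions (including ineligible ones) and resolved subjects."""
    config = config or RuleEngineConfig()
    analyses: list[SentenceAnalysis] = []
    ctx: Optional[SentenceContext] = None
    for sentence in split_sentences(doc):
        cs = clean_sentence(sentence, config.stop_set)
        partner_now = detect_partner_scope(sentence, ctx)

        rule_mention, fired_rule, keyword_pos = _apply_complex_rules(
            cs, config.complex_rules
        )
        discard = (
            frozenset({keyword_pos})
            if fired_rule is not None and fired_rule.action == "Discard"
            else frozenset()
        )
        hits = _scan_hits(cs.words, config.lexicon)
        chains = _chain_mentions(cs, hits, config.composition, discard)

        # A Keep rule yields to an exact-match chain covering its keyword
        # when that chain composed a cascade or belongs to a partner branch;
        # otherwise the rule's (usually more specific) side wins.
        if rule_mention is not None:
            covering = next(
                (c for c in chains if c.covers(keyword_pos)), None
            )
            if covering is not None and (
                covering.n_hits > 1 or covering.mention.partner_branch
            ):
                rule_mention = None
        mentions = []
        rule_inserted = False
        for c in chains:
            if rule_mention is not None and c.covers(keyword_pos):
                mentions.append(rule_mention)
                rule_inserted = True
            else:
                mentions.append(c.mention)
        if rule_mention is not None and not rule_inserted:
            mentions.insert(0, rule_mention)

        if partner_now:
            mentions = [
                dataclasses.replace(m, partner_branch=True) for m in mentions
            ]

        subject: Subject
        found = True
        if detect_patient_subject(cs, config.lexicon):
            subject = PATIENT
        elif rule_mention is not None:
            subject = next(
                m for m in mentions if m.relation == rule_mention.relation
            )
        elif fired_rule is not None and fired_rule.action == "Discard" and not mentions:
            subject = None  # relative present but explicitly discarded
        elif mentions:
            subject = mentions[0]
        else:
            subject = None
            found = False

        ctx = link_previous_sentence(ctx, found, subject, partner_now)
        analyses.append(
            SentenceAnalysis(
                sentence=sentence,
                clean=cs,
                mentions=mentions,
                subject=ctx.current_subject,
                partner_scope=ctx.partner_scope,
                context=ctx,
            )
        )
    return analyses


def extract_family_members(
    doc: Document, config: Optional[RuleEngineConfig] = None
) -> list[FamilyMemberMention]:
    """Eligible family members of a document, deduplicated on
    (relation, side) in first-occurrence order."""
    seen: set[Tuple[str, str]] = set()
    out: list[FamilyMemberMention] = []
    for analysis in analyze_document(doc, config):
        for m in analysis.mentions:
            if not is_eligible(m):
                continue
            key = (m.relation, m.side)
            if key not in seen:
                seen.add(key)
                out.append(m)
    return out
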