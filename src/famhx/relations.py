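"""Hybrid end-to-end assembly: subjects + observations + living status.

For each sentence the rule engine resolves a subject (a family member, the
patient, or nothing); observations come either from the dictionary matcher
(pure-rule mode) or from a trained neural labeler (hybrid mode — family
members always come from the rule engine, so both modes agree on task-1
family-member output).  Observations found in a sentence attach to that
sentence's (possibly carried-over) subject when it is an eligible family
member; observations with no eligible subject are retained as task-1
entities but yield no relation.  Negation is flagged by clause-scoped cue
matching before the observation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

from famhx.docmodel import (
    Document,
    FamilyMemberMention,
    LivingStatusAssertion,
    ObservationMention,
    RelationRecord,
    Sentence,
)
from famhx.kinship import is_eligible
from famhx.living_status import StatusLexicon, detect_status
from famhx.observation import (
    DiseaseDictionary,
    FalsePositiveList,
    annotate_dictionary,
    filter_false_positives,
)
from famhx.rule_engine import PATIENT, RuleEngineConfig, Subject, analyze_document
from famhx.resources import load_terms


@dataclass(frozen=True)
class NegationLexicon:
    """Pre-entity negation cues ("no", "denies", "no history of", ...)."""

    cues: frozenset[str]

    @classmethod
    def default(cls) -> "NegationLexicon":
        return cls(frozenset(load_terms("negation.txt")))


# clause separators that reset negation scope ("no cancer, but has diabetes")
_CLAUSE_BREAKERS = {";", "but", "however", "although"}


def detect_negation(
    s: Sentence, obs: ObservationMention, lexicon: Optional[NegationLexicon] = None
) -> bool:
    """True iff a negation cue precedes the observation inside its clause."""
    lexicon = lexicon or NegationLexicon.default()
    if obs.span is None:
        raise ValueError("observation has no span within the sentence")
    prefix = s.text[: obs.span[1]].lower()
    words: list[str] = []
    for raw in prefix.split():
        if ";" in raw:
            words.append(";")
            raw = raw.split(";")[-1]
        word = raw.strip(".,;:!?()\"'")
        if word:
            words.append(word)
    # restrict to the current clause
    for i in range(len(words) - 1, -1, -1):
        if words[i] in _CLAUSE_BREAKERS:
            words = words[i + 1 :]
            break
    max_len = max((len(c.split()) for c in lexicon.cues), default=1)
    for i in range(len(words)):
        for width in range(1, min(max_len, len(words) - i) + 1):
            if " ".join(words[i : i + width]) in lexicon.cues:
                return True
    return False


def attach_to_subject(
    subject: Subject,
    items: Sequence[Union[ObservationMention, LivingStatusAssertion]],
    doc_id: str,
) -> list[RelationRecord]:
    """One relation per item when the subject is an eligible family member;
    patient/unresolved/ineligible subjects yield no relations (the
    observations themselves are still reported as task-1 entities)."""
    if subject is None or subject is PATIENT:
        return []
    if not isinstance(subject, FamilyMemberMention) or not is_eligible(subject):
        return []
    member = dataclasses.replace(subject, span=None)
    return [RelationRecord(doc_id=doc_id, member=member, payload=item) for item in items]


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline (both modes)."""

    engine: RuleEngineConfig = field(default_factory=RuleEngineConfig)
    dictionary: DiseaseDictionary = field(default_factory=DiseaseDictionary.default)
    fp_list: FalsePositiveList = field(default_factory=FalsePositiveList.default)
    status_lexicon: StatusLexicon = field(default_factory=StatusLexicon.default)
    negation_lexicon: NegationLexicon = field(default_factory=NegationLexicon.default)


def run_hybrid(
    doc: Document,
    config: Optional[PipelineConfig] = None,
    model=None,
) -> Tuple[
    Tuple[list[FamilyMemberMention], list[ObservationMention]], list[RelationRecord]
]:
    """Process one note end to end.

    Returns ``((family_members, observations), relations)``.  With a model,
    observations come from the neural labeler (hybrid mode); without one,
    from dictionary matching (pure-rule mode).  Family members always come
    from the rule engine.
    """
    config = config or PipelineConfig()
    analyses = analyze_document(doc, config.engine)

    members: list[FamilyMemberMention] = []
    seen_members: set[Tuple[str, str]] = set()
    observations: list[ObservationMention] = []
    seen_obs: set[str] = set()
    relations: list[RelationRecord] = []

    if model is not None:
        from famhx.ner_model import predict_observations

        model_obs = predict_observations(model, [a.sentence for a in analyses])
    else:
        model_obs = None

    for idx, analysis in enumerate(analyses):
        sentence = analysis.sentence
        for m in analysis.mentions:
            if is_eligible(m):
                key = (m.relation, m.side)
                if key not in seen_members:
                    seen_members.add(key)
                    members.append(m)

        if model_obs is not None:
            sentence_obs = model_obs[idx]
        else:
            sentence_obs = filter_false_positives(
                annotate_dictionary(sentence, config.dictionary), config.fp_list
            )
        sentence_obs = [
            dataclasses.replace(
                o, negated=detect_negation(sentence, o, config.negation_lexicon)
            )
            for o in sentence_obs
        ]
        for o in sentence_obs:
            key = o.text.lower()
            if key not in seen_obs:
                seen_obs.add(key)
                observations.append(o)

        items: list[Union[ObservationMention, LivingStatusAssertion]] = list(
            sentence_obs
        )
        status = detect_status(sentence, config.status_lexicon)
        if status is not None:
            items.append(status)
        relations.extend(attach_to_subject(analysis.subject, items, doc.doc_id))

    # deduplicate relations preserving order
    seen_rel = set()
    unique_relations = []
    for rec in relations:
        if isinstance(rec.payload, LivingStatusAssertion):
            key = (rec.member.relation, rec.member.side, "LS", rec.payload.score)
        else:
            key = (
                rec.member.relation,
                rec.member.side,
                "OBS",
                rec.payload.text.lower(),
                rec.payload.negated,
            )
        if key not in seen_rel:
            seen_rel.add(key)
            unique_relations.append(rec)
    return (members, observations), unique_relations


def run_corpus(
    docs: Iterable[Document],
    config: Optional[PipelineConfig] = None,
    model=None,
) -> Tuple[dict, dict]:
    """Run the pipeline over a corpus; returns the (entities, relations)
    maps accepted by :func:`famhx.docmodel.write_submission`."""
    config = config or PipelineConfig()
    entities = {}
    relations = {}
    for doc in docs:
        (members, observations), recs = run_hybrid(doc, config, model)
        entities[doc.doc_id] = (members, observations)
        relations[doc.doc_id] = recs
    return entities, relations
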