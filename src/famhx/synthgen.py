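"""Seeded generator of synthetic family-history notes with exact gold.

The generator emulates the structure of family-history narratives from the
shared task it mirrors: patient relatives with maternal/paternal sides,
partner relatives (whose whole branch is ineligible), cascaded
relative-of-relative mentions, ineligible relatives (nephew,
great-grandparents), multi-word and negated disease observations, and
living-status phrases.  Gold annotations come from generation-time ground
truth — including hard-coded resolutions for cascades — never from running
the extractor, so the generator remains an independent oracle for it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Tuple

from famhx.docmodel import Document, GoldStandard
from famhx.observation import DiseaseDictionary

# (surface, relation, side) for simple eligible relatives
_SIMPLE_RELATIVES = [
    ("mother", "Mother", "NA"),
    ("father", "Father", "NA"),
    ("brother", "Brother", "NA"),
    ("sister", "Sister", "NA"),
    ("son", "Son", "NA"),
    ("daughter", "Daughter", "NA"),
    ("maternal aunt", "Aunt", "Maternal"),
    ("paternal aunt", "Aunt", "Paternal"),
    ("maternal uncle", "Uncle", "Maternal"),
    ("paternal uncle", "Uncle", "Paternal"),
    ("maternal grandmother", "Grandmother", "Maternal"),
    ("paternal grandfather", "Grandfather", "Paternal"),
    ("grandmother", "Grandmother", "NA"),
    ("grandfather", "Grandfather", "NA"),
    ("cousin", "Cousin", "NA"),
]

_INELIGIBLE_RELATIVES = [
    "nephew",
    "niece",
    "great grandmother",
    "great grandfather",
    "half brother",
    "half sister",
]

# fixed cascade resolutions (outer surface, inner surface, relation, side);
# these are generation-time ground truth, independent of the kinship tables
_CASCADES = [
    ("father", "brother", "Uncle", "Paternal"),
    ("father", "sister", "Aunt", "Paternal"),
    ("mother", "brother", "Uncle", "Maternal"),
    ("mother", "sister", "Aunt", "Maternal"),
    ("mother", "mother", "Grandmother", "Maternal"),
    ("father", "father", "Grandfather", "Paternal"),
    ("maternal aunt", "son", "Cousin", "Maternal"),
    ("paternal uncle", "daughter", "Cousin", "Paternal"),
]

_STATUS_PHRASES = [
    ("passed away", 0),
    ("died", 0),
    ("is deceased", 0),
    ("is alive and well", 4),
    ("is doing well", 4),
    ("is healthy", 4),
    ("is living and well", 4),
    ("is otherwise healthy", 4),
]

_NEGATION_TEMPLATES = [
    "The patient's {rel} has no history of {obs}.",
    "The patient's {rel} was negative for {obs}.",
]

_OBS_TEMPLATES = [
    "The patient's {rel} has {obs}.",
    "The patient's {rel} was diagnosed with {obs}.",
    "The patient's {rel} suffers from {obs}.",
]


@dataclass
class GenConfig:
    """Generation parameters; generation is a pure function of this config.

    Probabilities select sentence phenomena; defaults produce a corpus where
    most sentences concern eligible patient relatives, with partner
    branches, cascades, ineligible relatives and negations appearing at
    rates a family-history narrative plausibly shows.
    """

    n_docs: int = 100
    seed: int = 0
    sentences_per_doc: Tuple[int, int] = (3, 7)
    p_partner_branch: float = 0.10
    p_negation: float = 0.20
    p_cascade: float = 0.15
    p_ineligible: float = 0.10
    p_living_status: float = 0.30
    p_continuation: float = 0.10
    p_patient_sentence: float = 0.10
    disease_vocab: DiseaseDictionary = field(default_factory=DiseaseDictionary.default)

    def validate(self) -> None:
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid sentences_per_doc range: {self.sentences_per_doc}")
        for name in (
            "p_partner_branch",
            "p_negation",
            "p_cascade",
            "p_ineligible",
            "p_living_status",
            "p_continuation",
            "p_patient_sentence",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {p}")
        if not self.disease_vocab.terms:
            raise ValueError("disease vocabulary must be non-empty")


def generate_corpus(cfg: GenConfig) -> Tuple[list[Document], GoldStandard]:
    docs, gold, _stats = generate_corpus_with_stats(cfg)
    return docs, gold


def generate_corpus_with_stats(
    cfg: GenConfig,
) -> Tuple[list[Document], GoldStandard, dict]:
    """Generate notes, their gold standard, and the generator's own tally
    of phenomena (the bookkeeping oracle for :func:`difficulty_report`)."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    diseases = sorted(cfg.disease_vocab.terms)
    docs: list[Document] = []
    gold = GoldStandard()
    stats = {
        "documents": cfg.n_docs,
        "sentences": 0,
        "partner_sentences": 0,
        "cascade_sentences": 0,
        "negation_sentences": 0,
        "ineligible_sentences": 0,
        "living_status_sentences": 0,
    }

    for d in range(cfg.n_docs):
        doc_id = f"synth-{d:04d}"
        n_sentences = rng.randint(*cfg.sentences_per_doc)
        sentences: list[str] = []
        # the subject of the last eligible-relative sentence, for continuations
        last_member: Optional[Tuple[str, str]] = None

        for _ in range(n_sentences):
            roll = rng.random()
            if roll < cfg.p_partner_branch:
                sentences.append(_partner_sentence(rng, diseases, gold, doc_id))
                stats["partner_sentences"] += 1
                last_member = None
            elif roll < cfg.p_partner_branch + cfg.p_ineligible:
                sentences.append(_ineligible_sentence(rng, diseases, gold, doc_id))
                stats["ineligible_sentences"] += 1
                last_member = None
            elif roll < cfg.p_partner_branch + cfg.p_ineligible + cfg.p_cascade:
                sentences.append(_cascade_sentence(rng, diseases, gold, doc_id))
                stats["cascade_sentences"] += 1
                last_member = None
            elif (
                roll
                < cfg.p_partner_branch
                + cfg.p_ineligible
                + cfg.p_cascade
                + cfg.p_patient_sentence
            ):
                sentences.append(_patient_sentence(rng, diseases, gold, doc_id))
                last_member = None
            elif last_member is not None and rng.random() < cfg.p_continuation:
                text, used_status, used_negation = _continuation_sentence(
                    rng, diseases, gold, doc_id, last_member, cfg
                )
                sentences.append(text)
                stats["living_status_sentences"] += used_status
                stats["negation_sentences"] += used_negation
            else:
                text, member, used_status, used_negation = _relative_sentence(
                    rng, diseases, gold, doc_id, cfg
                )
                sentences.append(text)
                last_member = member
                stats["living_status_sentences"] += used_status
                stats["negation_sentences"] += used_negation
        stats["sentences"] += len(sentences)
        docs.append(Document(doc_id=doc_id, text=" ".join(sentences)))
    return docs, gold, stats


def _pick_obs(rng: random.Random, diseases: list[str]) -> str:
    return rng.choice(diseases)


def _relative_sentence(rng, diseases, gold: GoldStandard, doc_id, cfg: GenConfig):
    surface, relation, side = rng.choice(_SIMPLE_RELATIVES)
    gold.add_member(doc_id, relation, side)
    use_status = rng.random() < cfg.p_living_status
    if use_status:
        phrase, score_value = rng.choice(_STATUS_PHRASES)
        gold.add_living_status(doc_id, relation, side, score_value)
        if score_value == 0 and rng.random() < 0.5:
            obs = _pick_obs(rng, diseases)
            gold.add_observation(doc_id, obs)
            gold.add_obs_relation(doc_id, relation, side, obs, False)
            return (
                f"The patient's {surface} {phrase} from {obs}.",
                (relation, side),
                1,
                0,
            )
        return f"The patient's {surface} {phrase}.", (relation, side), 1, 0
    obs = _pick_obs(rng, diseases)
    gold.add_observation(doc_id, obs)
    negated = rng.random() < cfg.p_negation
    gold.add_obs_relation(doc_id, relation, side, obs, negated)
    template = rng.choice(_NEGATION_TEMPLATES if negated else _OBS_TEMPLATES)
    return (
        template.format(rel=surface, obs=obs),
        (relation, side),
        0,
        int(negated),
    )


def _continuation_sentence(rng, diseases, gold, doc_id, member, cfg: GenConfig):
    relation, side = member
    pronoun = rng.choice(["She", "He"])
    if rng.random() < cfg.p_living_status:
        phrase, score_value = rng.choice(_STATUS_PHRASES)
        gold.add_living_status(doc_id, relation, side, score_value)
        return f"{pronoun} {phrase}.", 1, 0
    obs = _pick_obs(rng, diseases)
    gold.add_observation(doc_id, obs)
    negated = rng.random() < cfg.p_negation
    gold.add_obs_relation(doc_id, relation, side, obs, negated)
    if negated:
        return f"{pronoun} has no history of {obs}.", 0, 1
    return f"{pronoun} also has {obs}.", 0, 0


def _cascade_sentence(rng, diseases, gold, doc_id):
    outer, inner, relation, side = rng.choice(_CASCADES)
    gold.add_member(doc_id, relation, side)
    obs = _pick_obs(rng, diseases)
    gold.add_observation(doc_id, obs)
    gold.add_obs_relation(doc_id, relation, side, obs, False)
    return f"The patient's {outer}'s {inner} has {obs}."


def _partner_sentence(rng, diseases, gold, doc_id):
    partner = rng.choice(["wife", "husband"])
    surface, _relation, _side = rng.choice(_SIMPLE_RELATIVES)
    obs = _pick_obs(rng, diseases)
    # partner-branch relatives are ineligible; the observation remains a
    # reportable task-1 entity
    gold.add_observation(doc_id, obs)
    template = rng.choice(
        [
            "The patient's {p}'s {rel} has {obs}.",
            "His {p}'s {rel} has {obs}.",
        ]
    )
    return template.format(p=partner, rel=surface, obs=obs)


def _ineligible_sentence(rng, diseases, gold, doc_id):
    surface = rng.choice(_INELIGIBLE_RELATIVES)
    obs = _pick_obs(rng, diseases)
    gold.add_observation(doc_id, obs)
    return f"The patient's {surface} has {obs}."


def _patient_sentence(rng, diseases, gold, doc_id):
    if rng.random() < 0.5:
        obs = _pick_obs(rng, diseases)
        gold.add_observation(doc_id, obs)
        return f"The patient has {obs}."
    return "The patient is in good health."


def difficulty_report(corpus: list[Document], gold: GoldStandard) -> dict:
    """Counts per phenomenon, recomputed by scanning the generated text.

    The template inventory makes these scans unambiguous: partner terms,
    the fixed cascade possessive patterns, the two negation cues, the
    living-status phrases and the ineligible surfaces only ever come from
    their own templates.
    """
    partner_terms = ("wife", "husband")
    cascade_patterns = [f"{outer}'s {inner}" for outer, inner, _, _ in _CASCADES]
    negation_cues = ("no history of", "negative for")
    status_phrases = [p for p, _ in _STATUS_PHRASES]
    report = {
        "documents": len(corpus),
        "sentences": 0,
        "partner_sentences": 0,
        "cascade_sentences": 0,
        "negation_sentences": 0,
        "ineligible_sentences": 0,
        "living_status_sentences": 0,
        "gold_members": sum(len(v) for v in gold.members.values()),
        "gold_observations": sum(len(v) for v in gold.observations.values()),
    }
    for doc in corpus:
        sentences = [s for s in doc.text.split(". ") if s.strip()]
        report["sentences"] += len(sentences)
        for sent in sentences:
            low = sent.lower()
            if any(t in low.split("'")[0].split() or f"{t}'s" in low for t in partner_terms):
                report["partner_sentences"] += 1
            if any(pat in low for pat in cascade_patterns):
                report["cascade_sentences"] += 1
            if any(cue in low for cue in negation_cues):
                report["negation_sentences"] += 1
            if any(f"patient's {surf} " in low for surf in _INELIGIBLE_RELATIVES):
                report["ineligible_sentences"] += 1
            if any(phrase in low for phrase in status_phrases):
                report["living_status_sentences"] += 1
    return report
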