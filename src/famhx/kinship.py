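"""Family-relation lexicon, normalization, composition and eligibility.

Kinship handling has three layers: a surface lexicon mapping lexical
variants and plurals ("grandma", "mothers", "half-uncle", "wife") to
canonical relations; side resolution from explicit "maternal"/"paternal"
modifiers; and a composition (disambiguation) table resolving cascaded
relative-of-relative mentions — the patient's father's brother is the
patient's paternal uncle, and a maternal aunt's son is a maternal cousin
(the composed relative inherits the family side).

Extended relatives (nephew, great-grandparent, half-siblings, partner
relatives) are deliberately present in the lexicon: they must be recognized
so cascades and partner branches resolve correctly, and are then removed by
:func:`is_eligible` filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

from famhx.docmodel import (
    ELIGIBLE_RELATIONS,
    KNOWN_RELATIONS,
    FamilyMemberMention,
)
from famhx.resources import load_tsv

logger = logging.getLogger(__name__)

SIDE_WORDS = {"maternal": "Maternal", "paternal": "Paternal"}


class RelationLexicon:
    """Map from lower-cased surface variants to (relation, implied side)."""

    def __init__(self, entries: Dict[str, Tuple[str, str]]):
        for surface, (relation, side) in entries.items():
            if relation not in KNOWN_RELATIONS:
                raise ValueError(f"lexicon maps {surface!r} to unknown {relation!r}")
        self.entries = dict(entries)
        self.max_words = max(len(s.split()) for s in self.entries) if entries else 1

    @classmethod
    def default(cls) -> "RelationLexicon":
        entries = {}
        for row in load_tsv("relation_lexicon.tsv"):
            surface, relation, side = row
            entries[surface.lower()] = (relation, side)
        return cls(entries)

    def lookup(self, surface: str) -> Optional[Tuple[str, str]]:
        return self.entries.get(" ".join(surface.lower().split()))


@dataclass(frozen=True)
class CompositionRule:
    first_relative: str
    second_relative: str
    resolved_relative: str
    resolved_side: str  # Maternal | Paternal | NA | Inherit


class CompositionTable:
    """Relative-of-relative disambiguation rules (a total lookup with a
    conservative fallback for unlisted pairs)."""

    def __init__(self, rules: Sequence[CompositionRule]):
        self.rules = {(r.first_relative, r.second_relative): r for r in rules}

    @classmethod
    def default(cls) -> "CompositionTable":
        rules = [
            CompositionRule(*row) for row in load_tsv("composition.tsv")
        ]
        return cls(rules)


_DEFAULT_LEXICON: Optional[RelationLexicon] = None
_DEFAULT_TABLE: Optional[CompositionTable] = None


def default_lexicon() -> RelationLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = RelationLexicon.default()
    return _DEFAULT_LEXICON


def default_composition_table() -> CompositionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CompositionTable.default()
    return _DEFAULT_TABLE


def normalize_mention(
    surface: str, lexicon: Optional[RelationLexicon] = None
) -> Optional[Tuple[str, str]]:
    """Normalize a lower-cased surface to (relation, side), or None.

    An adjacent leading "maternal"/"paternal" modifier sets the side;
    conflicting double markers ("maternal/paternal great-aunt") resolve to
    side NA rather than guessing.
    """
    lexicon = lexicon or default_lexicon()
    words = surface.lower().replace("/", " ").split()
    sides = []
    while words and words[0] in SIDE_WORDS:
        sides.append(SIDE_WORDS[words.pop(0)])
    hit = lexicon.lookup(" ".join(words))
    if hit is None:
        # the whole surface (e.g. "maternal grandfather") may be a lexicon entry
        hit = lexicon.lookup(" ".join(surface.lower().split()))
        if hit is None:
            return None
        return hit
    relation, implied_side = hit
    if len(set(sides)) == 1:
        return relation, sides[0]
    if len(set(sides)) > 1:
        return relation, "NA"  # conflicting markers: do not guess
    return relation, implied_side


def compose(
    outer: Tuple[str, str],
    inner: str,
    table: Optional[CompositionTable] = None,
) -> Tuple[str, str]:
    """Resolve a cascaded mention: outer (relation, side) of inner relation.

    (Father, NA) of Brother -> (Uncle, Paternal); (Aunt, Maternal) of Son ->
    (Cousin, Maternal) because "Inherit" rules carry over the outer side.
    Pairs absent from the table fall back to (inner, NA) with a log record.
    """
    table = table or default_composition_table()
    outer_rel, outer_side = outer
    if outer_rel not in KNOWN_RELATIONS or inner not in KNOWN_RELATIONS:
        raise ValueError(f"unknown relation in composition: {outer_rel}/{inner}")
    rule = table.rules.get((outer_rel, inner))
    if rule is None:
        logger.debug("no composition rule for %s of %s; fallback", outer_rel, inner)
        return inner, "NA"
    side = outer_side if rule.resolved_side == "Inherit" else rule.resolved_side
    return rule.resolved_relative, side


def is_eligible(m: FamilyMemberMention) -> bool:
    """True iff the relation is one of the 15 valid relations and the
    mention does not belong to the patient's partner's family."""
    return m.relation in ELIGIBLE_RELATIONS and not m.partner_branch
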