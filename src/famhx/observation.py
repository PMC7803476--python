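"""Dictionary-based disease-mention annotation with false-positive filtering.

A stand-in for an external concept-annotation service: case-insensitive
longest-match-first dictionary matching at word boundaries, followed by
suppression of terms from a false-positive list.  Used directly in the
pure-rule pipeline and as the external-annotation feature channel for the
neural labeler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from famhx.docmodel import ObservationMention, Sentence
from famhx.preprocess import tokenize_words
from famhx.resources import load_terms


@dataclass(frozen=True)
class DiseaseDictionary:
    """Lower-cased, whitespace-normalized disease terms."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        normalized = frozenset(" ".join(t.lower().split()) for t in self.terms)
        if any(not t for t in normalized):
            raise ValueError("empty term in disease dictionary")
        object.__setattr__(self, "terms", normalized)

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "DiseaseDictionary":
        return cls(frozenset(terms))

    @classmethod
    def default(cls) -> "DiseaseDictionary":
        return cls.from_terms(load_terms("diseases.txt"))


@dataclass(frozen=True)
class FalsePositiveList:
    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms", frozenset(" ".join(t.lower().split()) for t in self.terms)
        )

    @classmethod
    def default(cls) -> "FalsePositiveList":
        return cls(frozenset(load_terms("fp_list.txt")))


def annotate_dictionary(
    s: Sentence, dictionary: DiseaseDictionary
) -> list[ObservationMention]:
    """Longest-match-first, left-to-right, non-overlapping dictionary
    matching at word boundaries ("diabetes type 2" beats "diabetes";
    "art" never fires inside "heart")."""
    tokens = [t for t in tokenize_words(s) if any(c.isalnum() for c in t.surface)]
    words = [t.surface.lower() for t in tokens]
    max_len = max((len(t.split()) for t in dictionary.terms), default=1)
    out: list[ObservationMention] = []
    i = 0
    while i < len(words):
        matched = False
        for width in range(min(max_len, len(words) - i), 0, -1):
            candidate = " ".join(words[i : i + width])
            if candidate in dictionary.terms:
                out.append(
                    ObservationMention(
                        text=candidate,
                        span=(s.index, tokens[i].start, tokens[i + width - 1].end),
                    )
                )
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return out


def filter_false_positives(
    mentions: Sequence[ObservationMention], fp: FalsePositiveList
) -> list[ObservationMention]:
    """Drop mentions whose normalized text is on the false-positive list."""
    return [m for m in mentions if m.text.lower() not in fp.terms]
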