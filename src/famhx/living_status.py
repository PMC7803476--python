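"""Living-status detection and scoring.

Two rule sets: one targets deceased subjects ("passed away", "stillborn"
-> alive=0, healthy=0, score 0) and one targets healthy-and-alive subjects
("alive and well", "otherwise healthy" -> alive=2, healthy=2, score 4).
The score is the product of the alive and healthy components, each on a
0 (no) / 1 (not applicable) / 2 (yes) scale.  The alive-but-unhealthy case
is deliberately unmodeled; no rule ever emits (alive=2, healthy=0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from famhx.docmodel import LivingStatusAssertion, Sentence
from famhx.resources import load_terms


@dataclass(frozen=True)
class StatusLexicon:
    deceased_terms: frozenset[str]
    alive_healthy_terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.deceased_terms & self.alive_healthy_terms:
            raise ValueError("status term sets must be disjoint")

    @classmethod
    def default(cls) -> "StatusLexicon":
        return cls(
            deceased_terms=frozenset(load_terms("status_deceased.txt")),
            alive_healthy_terms=frozenset(load_terms("status_alive.txt")),
        )


def detect_status(
    s: Sentence, lexicon: Optional[StatusLexicon] = None
) -> Optional[LivingStatusAssertion]:
    """Detect a living-status phrase; the longest matching phrase wins
    ("alive and well" beats "alive" and "well")."""
    lexicon = lexicon or StatusLexicon.default()
    words = [
        w.strip(".,;:!?()\"'") for w in s.text.lower().split()
    ]
    best: Optional[tuple[int, LivingStatusAssertion]] = None
    for terms, assertion in (
        (lexicon.deceased_terms, LivingStatusAssertion(alive=0, healthy=0)),
        (lexicon.alive_healthy_terms, LivingStatusAssertion(alive=2, healthy=2)),
    ):
        for term in terms:
            term_words = term.split()
            n = len(term_words)
            for i in range(len(words) - n + 1):
                if words[i : i + n] == term_words:
                    if best is None or n > best[0]:
                        best = (n, assertion)
    return best[1] if best else None


def score(ls: LivingStatusAssertion) -> int:
    """alive x healthy; components outside {0,1,2} are fatal (the
    LivingStatusAssertion constructor already enforces this)."""
    if ls.alive not in (0, 1, 2) or ls.healthy not in (0, 1, 2):
        raise ValueError("living-status component out of range")
    return ls.alive * ls.healthy
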