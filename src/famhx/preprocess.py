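"""Sentence splitting, tokenization, sentence cleaning and BIO conversion.

Two tokenizations are supported because static word embeddings and
contextual-style subword embeddings segment text differently: word
tokenization assigns each token its own ``word_index``, while wordpiece
tokenization (greedy longest-match with ``##`` continuation pieces) shares
the ``word_index`` across the pieces of one word so entities predicted on
pieces can be reconstructed to whole words.

Sentence cleaning strips a configurable stop set (common verbs and their
conjugations, adjectives, first names) and possessive markers so that
kinship chains sit adjacent in the cleaned text: ``the patients' uncle has
one son`` cleans to ``patients uncle son``, where the cascaded relative
(uncle's son = cousin) is trivially visible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from famhx.docmodel import Document, Sentence, Token
from famhx.resources import load_term_set

logger = logging.getLogger(__name__)

TAGSET: Tuple[str, ...] = ("O", "B-Obs", "I-Obs", "B-PFM", "I-PFM")
ENTITY_CLASSES: Tuple[str, ...] = ("Obs", "PFM")

UNK_PIECE = "[UNK]"

# words after which a period does not end a sentence
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr", "vs", "etc",
    "approx", "fig", "e.g", "i.e", "yo", "y.o",
}

_WORD_RE = re.compile(r"\d+(?:\.\d+)?|[A-Za-z]+|'[A-Za-z]+|[^\w\s]")


def split_sentences(doc: Document) -> list[Sentence]:
    """Split a note into sentences with character spans into the note text.

    Boundaries are sentence-final punctuation (``.!?`` plus trailing quotes
    or parentheses) followed by whitespace, and hard newlines — clinical
    notes frequently hold one statement per line.  Periods after common
    abbreviations and inside decimal numbers do not split.
    """
    text = doc.text
    sentences: list[Sentence] = []
    start: Optional[int] = None
    i = 0
    n = len(text)

    def emit(lo: int, hi: int) -> None:
        while hi > lo and text[hi - 1].isspace():
            hi -= 1
        if hi > lo:
            sentences.append(
                Sentence(doc.doc_id, len(sentences), lo, hi, text[lo:hi])
            )

    while i < n:
        ch = text[i]
        if start is None:
            if not ch.isspace():
                start = i
            i += 1
            continue
        if ch == "\n":
            emit(start, i)
            start = None
            i += 1
            continue
        if ch in ".!?":
            j = i + 1
            while j < n and text[j] in ".!?\"')]":
                j += 1
            if _is_boundary(text, i, j):
                emit(start, j)
                start = None
            i = j
            continue
        i += 1
    if start is not None:
        emit(start, n)
    return sentences


def _is_boundary(text: str, i: int, j: int) -> bool:
    if j < len(text) and not text[j].isspace():
        return False
    if text[i] == ".":
        # decimal number
        if 0 < i and text[i - 1].isdigit() and j < len(text) and text[j].isdigit():
            return False
        k = i
        while k > 0 and (text[k - 1].isalpha() or text[k - 1] == "."):
            k -= 1
        word = text[k:i].lower().rstrip(".")
        # known abbreviations and dotted initialisms ("B.P.", "e.g.") do not split
        if word in _ABBREVIATIONS or "." in word:
            return False
    return True


def tokenize_words(s: Sentence) -> list[Token]:
    """Word-level tokenization with clitic splitting (``patient's`` →
    ``patient``, ``'s``).  Token spans index into the sentence text and each
    token is its own word (``word_index`` == position)."""
    return [
        Token(s.index, m.start(), m.end(), m.group(), idx)
        for idx, m in enumerate(_WORD_RE.finditer(s.text))
    ]


class WordpieceVocab:
    """A wordpiece vocabulary: word-initial pieces plus ``##`` continuations."""

    def __init__(self, pieces: Iterable[str]):
        self.pieces = frozenset(p for p in pieces if p and not p.startswith("#!"))
        if not self.pieces:
            raise ValueError("empty wordpiece vocabulary")

    @classmethod
    def default(cls) -> "WordpieceVocab":
        from famhx.resources import read_data_text

        pieces = [
            line.strip()
            for line in read_data_text("wordpiece_vocab.txt").splitlines()
            # "# " marks comments; bare "##..." lines are continuation pieces
            if line.strip() and not line.startswith("# ")
        ]
        return cls(pieces)

    def segment(self, word: str) -> list[str]:
        """Greedy longest-match-first segmentation of a lower-cased word.

        Characters not coverable by any piece become the UNK piece (one
        character each) so the rest of the word still segments.
        """
        word = word.lower()
        out: list[str] = []
        i = 0
        while i < len(word):
            for j in range(len(word), i, -1):
                cand = word[i:j] if i == 0 else "##" + word[i:j]
                if cand in self.pieces:
                    out.append(cand)
                    i = j
                    break
            else:
                out.append(UNK_PIECE)
                i += 1
        return out


def tokenize_subwords(s: Sentence, vocab: WordpieceVocab) -> list[Token]:
    """Wordpiece tokenization; pieces of one word share its ``word_index``.

    Piece surfaces carry the ``##`` continuation prefix exactly as stored in
    the vocabulary (``carcinoma`` → ``car``, ``##cin``, ``##oma``), so
    stripping the prefix and concatenating reconstructs the (lower-cased)
    word.
    """
    tokens: list[Token] = []
    for word in tokenize_words(s):
        offset = word.start
        for piece in vocab.segment(word.surface):
            plain = piece[2:] if piece.startswith("##") else piece
            width = 1 if piece == UNK_PIECE else len(plain)
            tokens.append(
                Token(s.index, offset, offset + width, piece, word.word_index)
            )
            offset += width
    return tokens


@dataclass(frozen=True)
class CleanSentence:
    """A sentence after stop-set removal and possessive normalization.

    ``kept_tokens`` is a subsequence of the original word tokens;
    ``words`` holds their normalized lower-cased surfaces, and ``text``
    joins them with single spaces.
    """

    original: Sentence
    kept_tokens: Tuple[Token, ...]
    words: Tuple[str, ...]

    @property
    def text(self) -> str:
        return " ".join(self.words)


_POSSESSIVE = {"'s", "'"}


def default_stop_set() -> frozenset[str]:
    """The bundled stop set: common verbs/conjugations, adjectives, names."""
    return frozenset(load_term_set("stopwords.txt") | load_term_set("names.txt"))


def clean_sentence(s: Sentence, stop_set: frozenset[str] | set[str]) -> CleanSentence:
    """Drop stop-set and punctuation tokens, normalize possessives.

    ``patient's`` / ``patients'`` normalize to ``patients``; other
    possessive markers are simply dropped.  Token order is preserved and no
    token is ever introduced.
    """
    kept: list[Token] = []
    words: list[str] = []
    for tok in tokenize_words(s):
        low = tok.surface.lower()
        if low in _POSSESSIVE:
            continue
        if not any(c.isalnum() for c in low):
            continue
        if low in stop_set:
            continue
        if low == "patient":
            low = "patients"
        kept.append(tok)
        words.append(low)
    return CleanSentence(original=s, kept_tokens=tuple(kept), words=tuple(words))


# --- BIO tagging ----------------------------------------------------------


def is_valid_bio(tags: Sequence[str]) -> bool:
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev == "O" or prev[2:] != cls:
                return False
        prev = tag
    return True


def spans_to_bio(
    tokens: Sequence[Token],
    entities: Sequence[Tuple[Tuple[int, int], str]],
) -> list[str]:
    """Convert character-span entities to per-token BIO tags.

    Spans misaligned with token boundaries snap outward to every overlapped
    token.  Overlapping entities keep the longer span (warning logged).
    """
    chosen: list[Tuple[Tuple[int, int], str]] = []
    for span, cls in sorted(entities, key=lambda e: (e[0][0], -(e[0][1] - e[0][0]))):
        if any(span[0] < c_end and c_start < span[1] for (c_start, c_end), _ in chosen):
            logger.warning("dropping overlapping entity %s (%s)", span, cls)
            continue
        chosen.append((span, cls))
    tags = ["O"] * len(tokens)
    for (start, end), cls in chosen:
        covered = [
            i for i, t in enumerate(tokens) if t.start < end and start < t.end
        ]
        for rank, i in enumerate(covered):
            tags[i] = ("B-" if rank == 0 else "I-") + cls
    return tags


def bio_to_spans(
    tokens: Sequence[Token], tags: Sequence[str]
) -> list[Tuple[Tuple[int, int], str]]:
    """Convert BIO tags back to character-span entities.

    A stray ``I-x`` with no open ``x`` entity opens a new one (lenient
    repair), so any tag sequence — valid BIO or not — decodes.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have equal length")
    spans: list[Tuple[Tuple[int, int], str]] = []
    open_cls: Optional[str] = None
    open_start = 0
    open_end = 0
    for tok, tag in zip(tokens, tags):
        if tag == "O":
            if open_cls is not None:
                spans.append(((open_start, open_end), open_cls))
                open_cls = None
            continue
        prefix, cls = tag.split("-", 1)
        if prefix == "B" or open_cls != cls:
            if open_cls is not None:
                spans.append(((open_start, open_end), open_cls))
            open_cls, open_start = cls, tok.start
        open_end = tok.end
    if open_cls is not None:
        spans.append(((open_start, open_end), open_cls))
    return spans
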