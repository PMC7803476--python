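"""Core document/annotation data model and note, gold and submission file IO.

The unit of input is a plain-text clinical note (one UTF-8 ``.txt`` file per
document).  Annotations are document-level sets: family members are
(relation, side) pairs, observations are normalized strings, and relations
carry either a living-status score or an observation with a negation flag.
Gold-standard and system-submission files share one TSV dialect (see
:func:`write_submission`); files contain no character spans, mirroring the
span-free gold files of the family-history shared task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple, Union

#: The 15 family relations that are valid in system output.  Anything else
#: (nephew, great-grandparent, partner-branch relatives, ...) is recognized
#: during processing but must be filtered before serialization.
ELIGIBLE_RELATIONS: frozenset[str] = frozenset(
    {
        "Father",
        "Mother",
        "Parent",
        "Brother",
        "Sister",
        "Son",
        "Daughter",
        "Child",
        "Grandfather",
        "Grandmother",
        "Grandparent",
        "Cousin",
        "Sibling",
        "Uncle",
        "Aunt",
    }
)

#: Extended relatives: recognized by the lexicon so cascades and partner
#: branches resolve correctly, then discarded by eligibility filtering.
EXTENDED_RELATIONS: frozenset[str] = frozenset(
    {
        "Partner",
        "Nephew",
        "Niece",
        "GreatGrandfather",
        "GreatGrandmother",
        "GreatGrandparent",
        "GreatAunt",
        "GreatUncle",
        "HalfBrother",
        "HalfSister",
        "HalfSibling",
        "HalfUncle",
        "HalfAunt",
        "Grandson",
        "Granddaughter",
        "Grandchild",
        "GreatGrandchild",
        "Stepfather",
        "Stepmother",
        "Stepsibling",
        "ThirdDegreeCousin",
    }
)

KNOWN_RELATIONS: frozenset[str] = ELIGIBLE_RELATIONS | EXTENDED_RELATIONS

SIDES: Tuple[str, ...] = ("Maternal", "Paternal", "NA")


@dataclass(frozen=True)
class Document:
    """A clinical note; ``text`` is preserved byte-for-byte from the file."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """A sentence with character offsets into its document's text.

    Offsets are 0-based, half-open: ``Document.text[start:end] == text``.
    """

    doc_id: str
    index: int
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class Token:
    """A token with offsets into its sentence's text.

    ``word_index`` identifies the whole word a token belongs to: for
    word-level tokenization it equals the token's own position; subword
    pieces of one word share the same ``word_index``.
    """

    sentence_index: int
    start: int
    end: int
    surface: str
    word_index: int


@dataclass(frozen=True)
class FamilyMemberMention:
    relation: str
    side: str = "NA"
    span: Optional[Tuple[int, int, int]] = None  # (sentence_index, start, end)
    partner_branch: bool = False

    def __post_init__(self) -> None:
        if self.relation not in KNOWN_RELATIONS:
            raise ValueError(f"unknown relation: {self.relation!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side: {self.side!r}")

    @property
    def eligible(self) -> bool:
        return self.relation in ELIGIBLE_RELATIONS and not self.partner_branch


@dataclass(frozen=True)
class ObservationMention:
    """A disease/condition mention with whitespace-normalized text."""

    text: str
    span: Optional[Tuple[int, int, int]] = None
    negated: bool = False

    def __post_init__(self) -> None:
        normalized = " ".join(self.text.split())
        if not normalized:
            raise ValueError("observation text empty after normalization")
        object.__setattr__(self, "text", normalized)


@dataclass(frozen=True)
class LivingStatusAssertion:
    """Living status on the 0/1/2 scale per component.

    Each of ``alive`` and ``healthy`` is 0 (no), 1 (not applicable) or
    2 (yes); the reported score is their product, hence in {0, 1, 2, 4}.
    """

    alive: int
    healthy: int

    def __post_init__(self) -> None:
        for name in ("alive", "healthy"):
            v = getattr(self, name)
            if v not in (0, 1, 2):
                raise ValueError(f"{name} component out of range: {v!r}")

    @property
    def score(self) -> int:
        return self.alive * self.healthy


@dataclass(frozen=True)
class RelationRecord:
    doc_id: str
    member: FamilyMemberMention
    payload: Union[LivingStatusAssertion, ObservationMention]

    def __post_init__(self) -> None:
        if not self.member.eligible:
            raise ValueError(
                f"relation record member not eligible: {self.member.relation}"
            )


@dataclass
class GoldStandard:
    """Document-level annotation sets (gold or system output).

    All sets are deduplicated; observation text is compared case-insensitively
    and stored lower-cased.
    """

    members: dict[str, set[Tuple[str, str]]] = field(default_factory=dict)
    observations: dict[str, set[str]] = field(default_factory=dict)
    living_status: dict[str, set[Tuple[str, str, int]]] = field(default_factory=dict)
    obs_relations: dict[str, set[Tuple[str, str, str, bool]]] = field(
        default_factory=dict
    )

    def doc_ids(self) -> set[str]:
        return (
            set(self.members)
            | set(self.observations)
            | set(self.living_status)
            | set(self.obs_relations)
        )

    def add_member(self, doc_id: str, relation: str, side: str) -> None:
        _check_eligible(relation)
        self.members.setdefault(doc_id, set()).add((relation, side))

    def add_observation(self, doc_id: str, text: str) -> None:
        self.observations.setdefault(doc_id, set()).add(_norm_obs(text))

    def add_living_status(
        self, doc_id: str, relation: str, side: str, score: int
    ) -> None:
        _check_eligible(relation)
        self.living_status.setdefault(doc_id, set()).add((relation, side, score))

    def add_obs_relation(
        self, doc_id: str, relation: str, side: str, text: str, negated: bool
    ) -> None:
        _check_eligible(relation)
        self.obs_relations.setdefault(doc_id, set()).add(
            (relation, side, _norm_obs(text), negated)
        )

    # -- serialization -----------------------------------------------------

    def task1_lines(self) -> list[str]:
        lines = []
        for doc_id in sorted(self.members):
            for relation, side in sorted(self.members[doc_id]):
                lines.append(f"{doc_id}\tFamilyMember\t{relation}\t{side}")
        for doc_id in sorted(self.observations):
            for text in sorted(self.observations[doc_id]):
                lines.append(f"{doc_id}\tObservation\t{text}")
        return lines

    def task2_lines(self) -> list[str]:
        lines = []
        for doc_id in sorted(self.living_status):
            for relation, side, score in sorted(self.living_status[doc_id]):
                lines.append(f"{doc_id}\t{relation}\t{side}\tLivingStatus\t{score}")
        for doc_id in sorted(self.obs_relations):
            for relation, side, text, negated in sorted(self.obs_relations[doc_id]):
                flag = "Negated" if negated else "NonNegated"
                lines.append(
                    f"{doc_id}\t{relation}\t{side}\tObservation\t{text}\t{flag}"
                )
        return lines

    def write(
        self, task1: Union[str, Path], task2: Union[str, Path], header: str = ""
    ) -> None:
        for path, lines in ((task1, self.task1_lines()), (task2, self.task2_lines())):
            body = "".join(line + "\n" for line in lines)
            if header:
                body = "".join(f"# {h}\n" for h in header.splitlines()) + body
            Path(path).write_text(body, encoding="utf-8")


def _norm_obs(text: str) -> str:
    return " ".join(text.split()).lower()


def _check_eligible(relation: str) -> None:
    if relation not in ELIGIBLE_RELATIONS:
        raise ValueError(f"ineligible relation in output: {relation!r}")


def read_corpus(dir_path: Union[str, Path]) -> list[Document]:
    """Read every ``*.txt`` file in ``dir_path`` (non-recursive) as a Document.

    Files are ordered lexicographically by name; doc_id is the filename stem.
    Non-UTF-8 content is a fatal error naming the offending file.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {dir_path}")
    docs = []
    for path in sorted(dir_path.glob("*.txt")):
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise ValueError(f"non-UTF-8 note file: {path}") from exc
        docs.append(Document(doc_id=path.stem, text=text))
    return docs


def write_submission(
    entities: Mapping[str, Tuple[Iterable[FamilyMemberMention], Iterable[ObservationMention]]],
    relations: Mapping[str, Iterable[RelationRecord]],
    out_task1: Union[str, Path],
    out_task2: Union[str, Path],
    header: str = "",
) -> GoldStandard:
    """Serialize per-document entities and relations to the two TSV files.

    Returns the :class:`GoldStandard` view that was written (useful for
    in-process evaluation without a filesystem round trip).
    """
    gs = GoldStandard()
    for doc_id, (members, observations) in entities.items():
        for m in members:
            if not m.eligible:
                raise ValueError(
                    f"ineligible family member in submission: {m.relation}"
                )
            gs.add_member(doc_id, m.relation, m.side)
        for obs in observations:
            gs.add_observation(doc_id, obs.text)
    for doc_id, records in relations.items():
        for rec in records:
            if isinstance(rec.payload, LivingStatusAssertion):
                gs.add_living_status(
                    doc_id, rec.member.relation, rec.member.side, rec.payload.score
                )
            else:
                gs.add_obs_relation(
                    doc_id,
                    rec.member.relation,
                    rec.member.side,
                    rec.payload.text,
                    rec.payload.negated,
                )
    gs.write(out_task1, out_task2, header=header)
    return gs


def read_gold(task1: Union[str, Path], task2: Union[str, Path]) -> GoldStandard:
    """Parse a task1/task2 file pair into a deduplicated :class:`GoldStandard`.

    Lines starting with ``#`` are provenance comments and are skipped.
    Malformed lines and ineligible relations are fatal, reported with the
    file name and 1-based line number.
    """
    gs = GoldStandard()
    for lineno, fields in _tsv_lines(task1):
        try:
            if len(fields) == 4 and fields[1] == "FamilyMember":
                doc_id, _, relation, side = fields
                if side not in SIDES:
                    raise ValueError(f"unknown side {side!r}")
                gs.add_member(doc_id, relation, side)
            elif len(fields) == 3 and fields[1] == "Observation":
                gs.add_observation(fields[0], fields[2])
            else:
                raise ValueError("unrecognized task-1 record")
        except ValueError as exc:
            raise ValueError(f"{task1}:{lineno}: {exc}") from None
    for lineno, fields in _tsv_lines(task2):
        try:
            if len(fields) == 5 and fields[3] == "LivingStatus":
                doc_id, relation, side, _, score = fields
                if side not in SIDES:
                    raise ValueError(f"unknown side {side!r}")
                score_i = int(score)
                if score_i not in (0, 1, 2, 4):
                    raise ValueError(f"living-status score out of range: {score}")
                gs.add_living_status(doc_id, relation, side, score_i)
            elif len(fields) == 6 and fields[3] == "Observation":
                doc_id, relation, side, _, text, flag = fields
                if side not in SIDES:
                    raise ValueError(f"unknown side {side!r}")
                if flag not in ("Negated", "NonNegated"):
                    raise ValueError(f"unknown negation flag {flag!r}")
                gs.add_obs_relation(doc_id, relation, side, text, flag == "Negated")
            else:
                raise ValueError("unrecognized task-2 record")
        except ValueError as exc:
            raise ValueError(f"{task2}:{lineno}: {exc}") from None
    return gs


def _tsv_lines(path: Union[str, Path]):
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip() or raw.startswith("#"):
            continue
        yield lineno, raw.split("\t")
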