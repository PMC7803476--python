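"""Precision/recall/F1 scoring for both subtasks, lenient and strict.

Task 1 scores family members on exact (relation, side) pairs — a wrong
side costs one false positive *and* one false negative — and observations
leniently: a prediction matches a gold observation if either one's token
sequence is a contiguous subsequence of the other's ("diabetes" matches
"diabetes type 2").

Task 2 scores living-status triples (member, side, score) exactly in both
modes.  Observation relations differ by mode: the lenient (original)
evaluator accepts a relation when member and side match and *either* the
observation *or* the negation status is correct; the strict (modified)
evaluator requires member, side, the (possibly partial) observation *and*
the negation status to all be correct, so strict F1 never exceeds lenient
F1.

Non-exact categories are counted via maximum bipartite matching so counts
do not depend on input order.  Matching is document-scoped and "overall"
is the micro-average over pooled category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import networkx as nx

from famhx.docmodel import GoldStandard


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def add(self, other: "Counts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn


@dataclass
class EvalReport:
    categories: dict[str, Counts] = field(default_factory=dict)

    @property
    def overall(self) -> Counts:
        total = Counts()
        for name, counts in self.categories.items():
            if name != "overall":
                total.add(counts)
        return total

    def finalize(self) -> "EvalReport":
        self.categories["overall"] = self.overall
        return self

    def as_dict(self) -> dict:
        return {
            name: {
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": c.precision,
                "recall": c.recall,
                "f1": c.f1,
            }
            for name, c in self.categories.items()
        }


def observations_match(pred: str, gold: str) -> bool:
    """Lenient observation match: equal, or one token sequence is a
    contiguous subsequence of the other."""
    p = pred.lower().split()
    g = gold.lower().split()
    if p == g:
        return True
    shorter, longer = (p, g) if len(p) <= len(g) else (g, p)
    n = len(shorter)
    return any(longer[i : i + n] == shorter for i in range(len(longer) - n + 1))


def _match_counts(
    pred: Sequence[Hashable],
    gold: Sequence[Hashable],
    matches: Callable[[Hashable, Hashable], bool],
) -> Counts:
    """tp/fp/fn via maximum bipartite matching under the given predicate."""
    graph = nx.Graph()
    p_nodes = [("p", i) for i in range(len(pred))]
    g_nodes = [("g", j) for j in range(len(gold))]
    graph.add_nodes_from(p_nodes, bipartite=0)
    graph.add_nodes_from(g_nodes, bipartite=1)
    for i, p in enumerate(pred):
        for j, g in enumerate(gold):
            if matches(p, g):
                graph.add_edge(("p", i), ("g", j))
    matching = nx.algorithms.bipartite.hopcroft_karp_matching(graph, top_nodes=p_nodes)
    tp = sum(1 for node in p_nodes if node in matching)
    return Counts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def _exact_counts(pred: set, gold: set) -> Counts:
    tp = len(pred & gold)
    return Counts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def _per_doc(pred_map: dict, gold_map: dict):
    for doc_id in sorted(set(pred_map) | set(gold_map)):
        yield pred_map.get(doc_id, set()), gold_map.get(doc_id, set())


def eval_task1(pred: GoldStandard, gold: GoldStandard) -> EvalReport:
    """Entity scoring: exact (relation, side) family members, lenient
    observations."""
    report = EvalReport(categories={"family_member": Counts(), "observation": Counts()})
    for p, g in _per_doc(pred.members, gold.members):
        report.categories["family_member"].add(_exact_counts(p, g))
    for p, g in _per_doc(pred.observations, gold.observations):
        report.categories["observation"].add(
            _match_counts(sorted(p), sorted(g), observations_match)
        )
    return report.finalize()


def _obs_relation_match_lenient(p, g) -> bool:
    p_rel, p_side, p_obs, p_neg = p
    g_rel, g_side, g_obs, g_neg = g
    if (p_rel, p_side) != (g_rel, g_side):
        return False
    return observations_match(p_obs, g_obs) or p_neg == g_neg


def _obs_relation_match_strict(p, g) -> bool:
    p_rel, p_side, p_obs, p_neg = p
    g_rel, g_side, g_obs, g_neg = g
    return (
        (p_rel, p_side) == (g_rel, g_side)
        and observations_match(p_obs, g_obs)
        and p_neg == g_neg
    )


def _eval_task2(pred: GoldStandard, gold: GoldStandard, obs_match) -> EvalReport:
    report = EvalReport(
        categories={"living_status": Counts(), "obs_relation": Counts()}
    )
    for p, g in _per_doc(pred.living_status, gold.living_status):
        report.categories["living_status"].add(_exact_counts(p, g))
    for p, g in _per_doc(pred.obs_relations, gold.obs_relations):
        report.categories["obs_relation"].add(
            _match_counts(sorted(p), sorted(g), obs_match)
        )
    return report.finalize()


def eval_task2_lenient(pred: GoldStandard, gold: GoldStandard) -> EvalReport:
    """Original relation scoring: a correct observation *or* a correct
    negation flag suffices (member and side always required)."""
    return _eval_task2(pred, gold, _obs_relation_match_lenient)


def eval_task2_strict(pred: GoldStandard, gold: GoldStandard) -> EvalReport:
    """Modified relation scoring: member, side, (possibly partial)
    observation and negation status must all be correct."""
    return _eval_task2(pred, gold, _obs_relation_match_strict)
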