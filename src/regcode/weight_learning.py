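"""Rule-weight estimation from training journeys via a co-occurrence graph.

For every coding type a directed graph is built over the rule base: one
vertex per distinct antecedent (a fact-variable's condition set) and per
distinct consequence assertion, plus a paired *non-match* vertex (displayed
with a ``-`` prefix) for every consequence.  Within a rule, every antecedent
pair is connected both ways; every antecedent is connected to each of the
rule's consequences and to their non-match twins.

Training accumulates an integer co-occurrence matrix Β: antecedent pairs that
are both matched by a journey's (forward-chained) facts increment their
symmetric cells; a fired rule increments the antecedent→consequence cells
when its asserted code equals the registrar-assigned gold code for the coding
type, and the antecedent→non-match cells otherwise.  Row-normalising Β gives
the adjacency matrix Α (rows with zero mass get a 1 on the diagonal), and one
message-passing step

    w_i = Σ_{j ∈ N(v_i)} Α_{ji}

over each vertex's in-neighbourhood yields vertex weights; a rule inherits
the weight of its consequence vertex.  Α_{ji} is the fraction of antecedent
j's co-occurrence mass that flowed to i, so a consequence that was usually
correct when asserted accumulates weight close to the number of antecedents
feeding it, while one that usually disagreed with gold drains its mass into
the non-match twin and scores near zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError
from .rule_engine import (
    INTERMEDIATE,
    Antecedent,
    Fact,
    FactDatabase,
    Rule,
    coding_fact_type,
    fire_detailed,
    forward_chain,
)

_OP_SYMBOL = {"eq": "=", "ne": "!=", "ge": ">=", "le": "<=", "present": "?"}


def antecedent_label(conditions: Sequence[Antecedent]) -> str:
    """Canonical vertex label for one fact-variable's condition set."""
    parts = sorted(
        f"{c.attribute}{_OP_SYMBOL[c.op]}{'' if c.op == 'present' else c.value}"
        for c in conditions
    )
    return "&".join(parts)


def assertion_label(template: Mapping[str, Any]) -> str:
    """Canonical vertex label for a consequence assertion template.

    Rendered exactly like an all-``eq`` antecedent, so an intermediate
    consequence (asserted by one rule, tested by another) maps to a single
    shared vertex.
    """
    return "&".join(sorted(f"{k}={v}" for k, v in template.items()))


def nonmatch_label(label: str) -> str:
    return "-" + label


@dataclass
class RuleGraph:
    """Per-coding-type antecedent/consequence graph with Β, Α and w."""

    coding_type: str
    rules: list[Rule]
    graph: nx.DiGraph
    vertices: list[str]  # antecedent-only, then consequences, then non-match
    index: dict[str, int]
    ant_vertices: list[str]
    con_vertices: list[str]
    nonmatch_vertices: list[str]
    conditions: dict[str, list[Antecedent]]  # antecedent label → condition set
    B: np.ndarray
    A: np.ndarray | None = None
    w: dict[str, float] = field(default_factory=dict)

    def in_neighbors(self, label: str) -> list[str]:
        return sorted(self.graph.predecessors(label))

    def to_json(self) -> dict:
        return {
            "coding_type": self.coding_type,
            "vertices": self.vertices,
            "edges": sorted(self.graph.edges()),
            "B": self.B.tolist(),
            "A": None if self.A is None else self.A.tolist(),
            "w": dict(sorted(self.w.items())),
        }


def _rule_structure(rule: Rule) -> tuple[list[str], list[tuple[str, Mapping]], dict[str, list[Antecedent]]]:
    """(antecedent labels, [(consequence label, template)], label→conditions)."""
    groups = rule.conditions_by_var()
    ant_labels: list[str] = []
    conds: dict[str, list[Antecedent]] = {}
    for var, cs in groups.items():
        label = antecedent_label(cs)
        if label not in conds:
            ant_labels.append(label)
            conds[label] = list(cs)
    cons = [(assertion_label(t), t) for t in rule.consequent.assertions]
    return ant_labels, cons, conds


def build_skeleton(rules: Sequence[Rule], coding_type: str | None = None) -> RuleGraph:
    """Build the graph skeleton for a rule base of one coding type.

    Vertices are deduplicated across rules; intermediate consequences that
    reappear as antecedents share a single vertex.  Non-match twins receive
    incoming edges only — no rule consumes a non-match, so they act purely as
    count sinks.
    """
    rules = list(rules)
    if not rules:
        raise ValidationError("build_skeleton: empty rule list")
    if coding_type is None:
        items = [r.coding_item for r in rules if r.coding_item != INTERMEDIATE]
        coding_type = items[0] if items else INTERMEDIATE

    graph = nx.DiGraph()
    ant_order: list[str] = []
    con_order: list[str] = []
    conditions: dict[str, list[Antecedent]] = {}

    per_rule = []
    for rule in rules:
        ant_labels, cons, conds = _rule_structure(rule)
        per_rule.append((ant_labels, cons))
        for label in ant_labels:
            if label not in conditions:
                conditions[label] = conds[label]
            if label not in ant_order:
                ant_order.append(label)
        for clabel, _tmpl in cons:
            if clabel not in con_order:
                con_order.append(clabel)

    non_order = [nonmatch_label(c) for c in con_order]
    # a consequence may double as an antecedent: it belongs to the
    # consequence block, not the antecedent-only block
    ant_only = [a for a in ant_order if a not in set(con_order)]
    vertices = ant_only + con_order + non_order
    graph.add_nodes_from(vertices)

    for ant_labels, cons in per_rule:
        for i, vi in enumerate(ant_labels):
            for vj in ant_labels[i + 1 :]:
                if vi != vj:
                    graph.add_edge(vi, vj)
                    graph.add_edge(vj, vi)
        for vi in ant_labels:
            for clabel, _tmpl in cons:
                graph.add_edge(vi, clabel)
                graph.add_edge(vi, nonmatch_label(clabel))

    n = len(vertices)
    return RuleGraph(
        coding_type=coding_type,
        rules=rules,
        graph=graph,
        vertices=vertices,
        index={v: i for i, v in enumerate(vertices)},
        ant_vertices=ant_only,
        con_vertices=con_order,
        nonmatch_vertices=non_order,
        conditions=conditions,
        B=np.zeros((n, n), dtype=np.int64),
    )


TrainingRecord = tuple[Iterable[Fact] | FactDatabase, Mapping[str, str]]


def accumulate_cooccurrence(
    graph: RuleGraph,
    training: Iterable[TrainingRecord],
    *,
    chain_rules: Sequence[Rule] | None = None,
) -> RuleGraph:
    """Accumulate the co-occurrence matrix Β over training records.

    A record is one patient journey's facts plus the registrar-assigned gold
    codes; patients without a gold value for the graph's coding type are
    skipped.  Matching is evaluated against the forward-chained closure of
    the record (so intermediate consequences asserted by other rules of the
    graph can satisfy antecedents).  Counting per record:

    * for every within-rule antecedent pair with both antecedents matched,
      the two symmetric antecedent cells gain 1 (a full rule firing is not
      required);
    * for every fired rule and each of its coding consequences, the
      antecedent→consequence cells gain 1 when an asserted code equals the
      gold code, and the antecedent→non-match cells otherwise;
    * consequences that do not carry this coding type (intermediates) count
      as matched whenever the rule fires.
    """
    rules = graph.rules
    chain = list(chain_rules) if chain_rules is not None else rules
    ftype = coding_fact_type(graph.coding_type)
    B = graph.B
    idx = graph.index
    structures = [(r, *_rule_structure(r)[:2]) for r in rules]

    for facts, gold in training:
        if graph.coding_type != INTERMEDIATE and graph.coding_type not in gold:
            continue
        gold_code = gold.get(graph.coding_type)
        db = facts if isinstance(facts, FactDatabase) else FactDatabase(facts)
        closure = forward_chain(db, chain)

        for rule, ant_labels, cons in structures:
            matched = [
                lab
                for lab in ant_labels
                if closure.satisfying(graph.conditions[lab])
            ]
            mset = set(matched)
            for i, vi in enumerate(ant_labels):
                for vj in ant_labels[i + 1 :]:
                    if vi in mset and vj in mset and vi != vj:
                        B[idx[vi], idx[vj]] += 1
                        B[idx[vj], idx[vi]] += 1
            fired = len(mset) == len(set(ant_labels))
            if not fired:
                continue
            asserted = [f for f, _sup in fire_detailed(rule, closure)]
            for clabel, tmpl in cons:
                if tmpl.get("type") == ftype:
                    values = {
                        str(f.get("value"))
                        for f in asserted
                        if f["type"] == ftype
                    }
                    hit = str(gold_code) in values
                else:
                    hit = True  # intermediate assertion: nothing to disagree with
                target = clabel if hit else nonmatch_label(clabel)
                for vi in set(ant_labels):
                    B[idx[vi], idx[target]] += 1
    return graph


def compute_adjacency(graph: RuleGraph) -> RuleGraph:
    """Row-normalise Β into Α with the three-case rule: Α_ii = 0 when the row
    has mass, 1 when it is empty; off-diagonal Α_ij = Β_ij / q_i."""
    B = graph.B.astype(float)
    q = B.sum(axis=1)
    n = len(graph.vertices)
    A = np.zeros((n, n))
    nz = q > 0
    A[nz] = B[nz] / q[nz, None]
    for i in range(n):
        A[i, i] = 0.0 if q[i] > 0 else 1.0
    graph.A = A
    return graph


def message_pass(graph: RuleGraph, *, phases: int = 1) -> RuleGraph:
    """Vertex weights by neighbourhood aggregation: w_i = Σ_{j∈N(v_i)} Α_ji.

    ``N(v_i)`` is the in-neighbourhood under the skeleton's directed edges
    (non-match vertices have no outgoing edges and therefore never appear in
    a neighbourhood).  With ``phases > 1`` the literal one-hop sum is
    iterated with the previous weights normalised to unit mass:
    w_i ← Σ_j Α_ji · ŵ_j.
    """
    if graph.A is None:
        raise ValidationError("message_pass: adjacency not computed")
    if phases < 1:
        raise ValidationError("message_pass: phases must be ≥ 1")
    A = graph.A
    idx = graph.index
    n = len(graph.vertices)
    w = np.zeros(n)
    for v in graph.vertices:
        i = idx[v]
        w[i] = sum(A[idx[j], i] for j in graph.graph.predecessors(v))
    for _ in range(phases - 1):
        total = w.sum()
        wn = w / total if total > 0 else w
        nxt = np.zeros(n)
        for v in graph.vertices:
            i = idx[v]
            nxt[i] = sum(A[idx[j], i] * wn[idx[j]] for j in graph.graph.predecessors(v))
        w = nxt
    graph.w = {v: float(w[idx[v]]) for v in graph.vertices}
    return graph


def assign_rule_weights(graph: RuleGraph, rules: Sequence[Rule]) -> list[Rule]:
    """Each rule of the graph's coding type inherits the weight of its
    consequence vertex (max over its coding assertions when several);
    other rules pass through unchanged, order preserved."""
    ftype = coding_fact_type(graph.coding_type)
    out: list[Rule] = []
    for rule in rules:
        if rule.coding_item != graph.coding_type:
            out.append(rule)
            continue
        labels = [
            assertion_label(t)
            for t in rule.consequent.assertions
            if t.get("type") == ftype
        ]
        if not labels:
            labels = [assertion_label(t) for t in rule.consequent.assertions]
        missing = [l for l in labels if l not in graph.w]
        if missing:
            raise RuntimeError(
                f"rule {rule.rule_id!r}: consequence vertex {missing[0]!r} "
                "missing from graph (skeleton bug)"
            )
        from dataclasses import replace

        out.append(replace(rule, weight=max(graph.w[l] for l in labels)))
    return out


def _feeding_intermediates(rules: Sequence[Rule], item_rules: list[Rule]) -> list[Rule]:
    """Intermediate-asserting rules whose consequences (transitively) feed the
    antecedents of the item's rules."""
    inters = [r for r in rules if r.coding_item == INTERMEDIATE]
    selected: list[Rule] = []
    needed: set[str] = set()
    for r in item_rules:
        labels, _, _ = _rule_structure(r)
        needed.update(labels)
    changed = True
    while changed:
        changed = False
        for r in inters:
            if r in selected:
                continue
            _, cons, _ = _rule_structure(r)
            if any(c in needed for c, _t in cons):
                selected.append(r)
                labels, _, _ = _rule_structure(r)
                needed.update(labels)
                changed = True
    return selected


def learn_weights(
    training: Sequence[TrainingRecord],
    rules: Sequence[Rule],
    *,
    phases: int = 1,
) -> tuple[list[Rule], dict[str, RuleGraph]]:
    """Learn a weight for every coding rule from training journeys.

    One graph per coding item (plus any intermediate rules feeding it);
    returns the re-weighted rule list (order preserved) and the trained
    graphs for audit.
    """
    training = list(training)
    items = sorted({r.coding_item for r in rules if r.coding_item != INTERMEDIATE})
    weighted = list(rules)
    graphs: dict[str, RuleGraph] = {}
    for item in items:
        item_rules = [r for r in rules if r.coding_item == item]
        item_rules += _feeding_intermediates(rules, item_rules)
        graph = build_skeleton(item_rules, coding_type=item)
        accumulate_cooccurrence(graph, training)
        compute_adjacency(graph)
        message_pass(graph, phases=phases)
        weighted = assign_rule_weights(graph, weighted)
        graphs[item] = graph
    return weighted, graphs


def dump_graphs(graphs: Mapping[str, RuleGraph], path: str | Path) -> None:
    payload = {item: g.to_json() for item, g in sorted(graphs.items())}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
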