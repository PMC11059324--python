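"""Weight-learning tests, anchored by an independent brute-force oracle that
re-implements the co-occurrence counting, row normalisation and neighbourhood
sums with literal loops over propositional rule bases."""

import numpy as np
import pytest

from regcode.errors import ValidationError
from regcode.rule_engine import Consequent, Rule
from regcode.weight_learning import (
    accumulate_cooccurrence,
    assign_rule_weights,
    build_skeleton,
    compute_adjacency,
    learn_weights,
    message_pass,
)
from tests.conftest import naive_closure, prop_fact, prop_rule

CODING = "X"
FTYPE = "X_CODING"


def fig1_rules():
    """A∧B→C, C∧D∧E→F, C∧D→G."""
    return [
        prop_rule("r1", "AB", "C"),
        prop_rule("r2", "CDE", "F"),
        prop_rule("r3", "CD", "G"),
    ]


# ---------------------------------------------------------------------------
# independent oracle


def _ant_label(letter):
    return f"type={letter}"


def _con_label(rule):
    tmpl = rule.consequent.assertions[0]
    return "&".join(sorted(f"{k}={v}" for k, v in tmpl.items()))


def oracle_graph(rules, training):
    """Literal reimplementation: vertices, edges, Β, Α, w by nested loops."""
    vertices = []
    edges = set()
    for rule in rules:
        ants = [_ant_label(a.value) for a in rule.antecedents]
        con = _con_label(rule)
        for v in ants + [con, "-" + con]:
            if v not in vertices:
                vertices.append(v)
        for i, vi in enumerate(ants):
            for vj in ants[i + 1 :]:
                edges.add((vi, vj))
                edges.add((vj, vi))
        for vi in ants:
            edges.add((vi, con))
            edges.add((vi, "-" + con))

    B = {u: {v: 0 for v in vertices} for u in vertices}
    inter = [r for r in rules if r.coding_item == "intermediate"]
    for observed, gold in training:
        if CODING not in gold:
            continue
        known = naive_closure(observed, inter)
        for rule in rules:
            ants = [a.value for a in rule.antecedents]
            matched = [a for a in ants if a in known]
            for i, vi in enumerate(ants):
                for vj in ants[i + 1 :]:
                    if vi in matched and vj in matched:
                        B[_ant_label(vi)][_ant_label(vj)] += 1
                        B[_ant_label(vj)][_ant_label(vi)] += 1
            if len(matched) < len(ants):
                continue
            con = _con_label(rule)
            tmpl = rule.consequent.assertions[0]
            if tmpl["type"] == FTYPE:
                hit = str(tmpl.get("value")) == str(gold[CODING])
            else:
                hit = True
            target = con if hit else "-" + con
            for vi in ants:
                B[_ant_label(vi)][target] += 1

    A = {u: {v: 0.0 for v in vertices} for u in vertices}
    for u in vertices:
        q = sum(B[u].values())
        for v in vertices:
            if u == v:
                A[u][v] = 0.0 if q != 0 else 1.0
            elif q != 0:
                A[u][v] = B[u][v] / q
    w = {}
    for v in vertices:
        w[v] = sum(A[u][v] for (u, t) in edges if t == v)
    return vertices, edges, B, A, w


def random_base_and_training(rng):
    """Small random rule base (≤ 8 vertices) and training stream."""
    letters = list("ABCDE")[: int(rng.integers(3, 6))]
    values = ["a", "b"]
    rules = []
    n_inter = int(rng.integers(0, 3))
    for i in range(n_inter):
        body_size = int(rng.integers(1, min(3, len(letters))))
        body = list(rng.choice(letters, size=body_size, replace=False))
        head_options = [l for l in letters if l not in body]
        if not head_options:
            continue
        head = head_options[int(rng.integers(len(head_options)))]
        rules.append(prop_rule(f"i{i}", body, head))
    n_coding = int(rng.integers(1, 4))
    for i in range(n_coding):
        body_size = int(rng.integers(1, min(4, len(letters) + 1)))
        body = list(rng.choice(letters, size=body_size, replace=False))
        value = values[int(rng.integers(2))]
        rules.append(prop_rule(f"c{i}", body, FTYPE, coding_item=CODING, value=value))
    training = []
    for _ in range(int(rng.integers(1, 20))):
        observed = {l for l in letters if rng.random() < 0.5}
        gold = {CODING: values[int(rng.integers(2))]}
        training.append((observed, gold))
    return rules, training


def run_package(rules, training, phases=1):
    graph = build_skeleton(rules, coding_type=CODING)
    records = [([prop_fact(l) for l in obs], gold) for obs, gold in training]
    accumulate_cooccurrence(graph, records)
    compute_adjacency(graph)
    message_pass(graph, phases=phases)
    return graph


class TestBuildSkeleton:
    def test_fig1_neighborhoods(self):
        graph = build_skeleton(fig1_rules(), coding_type="FigDemo")
        n = lambda v: set(graph.in_neighbors(f"type={v}"))
        assert n("F") == {"type=C", "type=D", "type=E"}
        assert n("C") == {"type=A", "type=B", "type=D", "type=E"}
        assert n("A") == {"type=B"}
        assert n("D") == {"type=C", "type=E"}

    def test_fig1_nonmatch_vertices_present(self):
        graph = build_skeleton(fig1_rules(), coding_type="FigDemo")
        assert {"-type=C", "-type=F", "-type=G"} <= set(graph.vertices)
        for nm in graph.nonmatch_vertices:
            assert graph.graph.out_degree(nm) == 0  # pure count sinks

    def test_single_antecedent_rule_has_no_pair_edges(self):
        graph = build_skeleton([prop_rule("r", "X", "Y")], coding_type="FigDemo")
        assert set(graph.graph.edges()) == {("type=X", "type=Y"), ("type=X", "-type=Y")}

    def test_intermediate_consequence_shares_vertex(self):
        graph = build_skeleton(fig1_rules(), coding_type="FigDemo")
        assert graph.vertices.count("type=C") == 1
        assert "type=C" in graph.con_vertices
        assert "type=C" not in graph.ant_vertices

    def test_matches_brute_force_pairwise_construction(self, rng):
        for _ in range(20):
            rules, _ = random_base_and_training(rng)
            vertices, edges, _, _, _ = oracle_graph(rules, [])
            graph = build_skeleton(rules, coding_type=CODING)
            assert set(graph.vertices) == set(vertices)
            assert set(graph.graph.edges()) == edges

    def test_zero_antecedent_rule_rejected(self):
        with pytest.raises(ValidationError):
            Rule("r", CODING, (), Consequent(({"type": FTYPE, "value": "a"},)))


class TestAccumulate:
    def _single_rule(self):
        return [prop_rule("c0", "AB", FTYPE, coding_item=CODING, value="a")]

    def test_match_increments_consequence_cells(self):
        graph = run_package(self._single_rule(), [({"A", "B"}, {CODING: "a"})])
        i = graph.index
        B = graph.B
        con = "type=X_CODING&value=a"
        assert B[i["type=A"], i["type=B"]] == 1
        assert B[i["type=B"], i["type=A"]] == 1
        assert B[i["type=A"], i[con]] == 1
        assert B[i["type=B"], i[con]] == 1
        assert B[:, i["-" + con]].sum() == 0

    def test_mismatch_increments_nonmatch_cells(self):
        graph = run_package(self._single_rule(), [({"A", "B"}, {CODING: "b"})])
        i = graph.index
        con = "type=X_CODING&value=a"
        assert graph.B[i["type=A"], i["-" + con]] == 1
        assert graph.B[i["type=A"], i[con]] == 0

    def test_pair_counted_without_full_fire(self):
        rules = [prop_rule("c0", "ABC", FTYPE, coding_item=CODING, value="a")]
        graph = run_package(rules, [({"A", "B"}, {CODING: "a"})])
        i = graph.index
        assert graph.B[i["type=A"], i["type=B"]] == 1
        assert graph.B[i["type=A"], i["type=C"]] == 0
        con = "type=X_CODING&value=a"
        assert graph.B[:, i[con]].sum() == 0  # rule did not fire

    def test_empty_training_leaves_B_zero(self):
        graph = run_package(self._single_rule(), [])
        assert graph.B.sum() == 0

    def test_patient_without_gold_for_type_skipped(self):
        graph = run_package(self._single_rule(), [({"A", "B"}, {"Other": "z"})])
        assert graph.B.sum() == 0


class TestAdjacency:
    def test_three_case_formula(self):
        rules = [
            prop_rule("c0", "A", FTYPE, coding_item=CODING, value="a"),
            prop_rule("c1", "A", FTYPE, coding_item=CODING, value="b"),
        ]
        graph = build_skeleton(rules, coding_type=CODING)
        i = graph.index
        graph.B[i["type=A"], i["type=X_CODING&value=a"]] = 3
        graph.B[i["type=A"], i["type=X_CODING&value=b"]] = 1
        compute_adjacency(graph)
        assert graph.A[i["type=A"], i["type=X_CODING&value=a"]] == 0.75
        assert graph.A[i["type=A"], i["type=X_CODING&value=b"]] == 0.25
        assert graph.A[i["type=A"], i["type=A"]] == 0.0

    def test_isolated_vertex_gets_unit_diagonal(self):
        graph = run_package([prop_rule("c0", "A", FTYPE, coding_item=CODING,
                                       value="a")], [])
        # no counts anywhere: every row is empty
        assert np.allclose(np.diag(graph.A), 1.0)

    def test_rows_with_mass_sum_to_one(self, rng):
        for _ in range(30):
            rules, training = random_base_and_training(rng)
            graph = run_package(rules, training)
            q = graph.B.sum(axis=1)
            rows = graph.A[q > 0]
            assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        rules, training = random_base_and_training(rng)
        graph = run_package(rules, training)
        scaled = build_skeleton(rules, coding_type=CODING)
        scaled.B = graph.B * 7
        compute_adjacency(scaled)
        message_pass(scaled)
        assert np.allclose(graph.A, scaled.A, atol=1e-12)
        assert graph.w == pytest.approx(scaled.w, abs=1e-12)


class TestMessagePass:
    def test_fig1_target_sum(self):
        graph = build_skeleton(fig1_rules(), coding_type="FigDemo")
        rng = np.random.default_rng(0)
        graph.A = rng.random((len(graph.vertices), len(graph.vertices)))
        message_pass(graph)
        i = graph.index
        expected = sum(
            graph.A[i[f"type={v}"], i["type=F"]] for v in "CDE"
        )
        assert graph.w["type=F"] == pytest.approx(expected)

    def test_vertex_without_incoming_edges_gets_zero(self):
        graph = run_package([prop_rule("c0", "A", FTYPE, coding_item=CODING,
                                       value="a")],
                            [({"A"}, {CODING: "a"})])
        assert graph.w["type=A"] == 0.0

    def test_four_vertex_hand_sums(self):
        rules = [prop_rule("c0", "AB", FTYPE, coding_item=CODING, value="a")]
        graph = build_skeleton(rules, coding_type=CODING)
        i = graph.index
        A = np.zeros((4, 4))
        A[i["type=A"], i["type=B"]] = 0.4
        A[i["type=B"], i["type=A"]] = 0.7
        A[i["type=A"], i["type=X_CODING&value=a"]] = 0.6
        A[i["type=B"], i["type=X_CODING&value=a"]] = 0.3
        graph.A = A
        message_pass(graph)
        assert graph.w["type=A"] == pytest.approx(0.7)
        assert graph.w["type=B"] == pytest.approx(0.4)
        assert graph.w["type=X_CODING&value=a"] == pytest.approx(0.9)
        assert graph.w["-type=X_CODING&value=a"] == pytest.approx(0.0)

    def test_multi_phase_normalises_previous_weights(self):
        rules, training = random_base_and_training(np.random.default_rng(11))
        g1 = run_package(rules, training, phases=1)
        g2 = run_package(rules, training, phases=2)
        w1 = np.array([g1.w[v] for v in g1.vertices])
        total = w1.sum()
        wn = w1 / total if total > 0 else w1
        i = g1.index
        for v in g1.vertices:
            expected = sum(
                g1.A[i[u], i[v]] * wn[i[u]] for u in g1.graph.predecessors(v)
            )
            assert g2.w[v] == pytest.approx(expected, abs=1e-12)


class TestOracleEquivalence:
    def test_B_A_w_match_brute_force_on_random_bases(self, rng):
        """100 seeded random (rule base, training stream) pairs: Β, Α and w
        agree with the literal counting oracle to 1e-12."""
        for trial in range(100):
            rules, training = random_base_and_training(rng)
            vertices, _, B_o, A_o, w_o = oracle_graph(rules, training)
            graph = run_package(rules, training)
            assert set(graph.vertices) == set(vertices)
            i = graph.index
            for u in vertices:
                for v in vertices:
                    assert graph.B[i[u], i[v]] == B_o[u][v], (trial, u, v)
                    assert graph.A[i[u], i[v]] == pytest.approx(A_o[u][v], abs=1e-12)
            for v in vertices:
                assert graph.w[v] == pytest.approx(w_o[v], abs=1e-12)


class TestAssignWeights:
    def test_rules_sharing_consequence_get_equal_weight(self):
        rules = [
            prop_rule("c0", "A", FTYPE, coding_item=CODING, value="a"),
            prop_rule("c1", "B", FTYPE, coding_item=CODING, value="a"),
        ]
        graph = run_package(rules, [({"A", "B"}, {CODING: "a"})])
        weighted = assign_rule_weights(graph, rules)
        assert weighted[0].weight == weighted[1].weight

    def test_order_preserved_and_other_items_untouched(self):
        rules = [
            prop_rule("other", "A", "Y_CODING", coding_item="Y", value="z"),
            prop_rule("c0", "A", FTYPE, coding_item=CODING, value="a"),
        ]
        graph = run_package([rules[1]], [({"A"}, {CODING: "a"})])
        weighted = assign_rule_weights(graph, rules)
        assert [r.rule_id for r in weighted] == ["other", "c0"]
        assert weighted[0].weight == 1.0

    def test_majority_code_rule_outweighs_minority(self):
        """9:1 match ratio: the rule asserting the majority gold code ends up
        strictly heavier (hand-traceable through Β→Α→w)."""
        rules = [
            prop_rule("maj", "A", FTYPE, coding_item=CODING, value="a"),
            prop_rule("min", "A", FTYPE, coding_item=CODING, value="b"),
        ]
        training = [({"A"}, {CODING: "a"})] * 9 + [({"A"}, {CODING: "b"})]
        graph = run_package(rules, training)
        weighted = assign_rule_weights(graph, rules)
        w = {r.rule_id: r.weight for r in weighted}
        assert w["maj"] > w["min"]
        # hand trace: both rules fire in all 10 records; row of A has mass
        # 9/20 toward value=a, 1/20 toward value=b (plus non-match mass)
        assert w["maj"] == pytest.approx(9 / 20)
        assert w["min"] == pytest.approx(1 / 20)

    def test_match_monotonicity(self, rng):
        """Appending a record where a rule fires and matches gold never
        lowers that rule's recomputed weight."""
        for _ in range(10):
            rules, training = random_base_and_training(rng)
            coding_rules = [r for r in rules if r.coding_item == CODING]
            target = coding_rules[0]
            letters = {a.value for a in target.antecedents}
            good = (set(letters), {CODING: target.consequent.assertions[0]["value"]})
            w_before = {
                r.rule_id: r.weight
                for r in assign_rule_weights(run_package(rules, training), rules)
            }
            w_after = {
                r.rule_id: r.weight
                for r in assign_rule_weights(
                    run_package(rules, training + [good]), rules)
            }
            assert w_after[target.rule_id] >= w_before[target.rule_id] - 1e-12

    def test_planted_rule_ranked_first(self, rng):
        """Synthetic cohorts where one code dominates 80-90% of gold: its
        rule is ranked first for the item."""
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            rules = [
                prop_rule("planted", "A", FTYPE, coding_item=CODING, value="a"),
                prop_rule("decoy", "B", FTYPE, coding_item=CODING, value="b"),
            ]
            training = []
            for _ in range(40):
                gold = "a" if local.random() < 0.85 else "b"
                training.append(({"A", "B"}, {CODING: gold}))
            weighted = assign_rule_weights(run_package(rules, training), rules)
            w = {r.rule_id: r.weight for r in weighted}
            hits += w["planted"] > w["decoy"]
        assert hits >= 19


def test_learn_weights_driver_includes_feeding_intermediates():
    rules = [
        prop_rule("i0", "AB", "C"),
        prop_rule("c0", "CD", FTYPE, coding_item=CODING, value="a"),
    ]
    records = [([prop_fact(l) for l in "ABD"], {CODING: "a"})]
    weighted, graphs = learn_weights(records, rules)
    graph = graphs[CODING]
    # the intermediate C was derived via i0, so c0 fired and matched
    assert "type=C" in graph.vertices
    i = graph.index
    assert graph.B[i["type=C"], i["type=X_CODING&value=a"]] == 1
    w = {r.rule_id: r.weight for r in weighted}
    assert w["c0"] > 0
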