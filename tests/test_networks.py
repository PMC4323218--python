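"""Food/target network construction, top-k display, enrichment, annotation."""

import itertools
import random

import networkx as nx
import pytest

from dfi import PipelineConfig
from dfi.networks import (
    EnrichmentInput,
    annotate_strongest_binder,
    build_food_network,
    build_target_network,
    category_enrichment,
    top_k_edges,
)
from dfi.records import (
    ActivityBasis,
    ActivityCall,
    DrugRecord,
    FoodRecord,
    ProteinCategory,
    ProteinRecord,
)

CFG = PipelineConfig()


def _call(cid, pid, active=True, affinity=10.0):
    return ActivityCall(cid, pid, active, ActivityBasis.DRUG_RANGE, representative_affinity=affinity)


def _foods(mapping):
    return {f: FoodRecord(f, frozenset(cs)) for f, cs in mapping.items()}


def test_disjoint_protein_sets_make_no_edge():
    foods = _foods({"A": {"c1"}, "B": {"c2"}})
    calls = [_call("c1", "p1"), _call("c2", "p2")]
    g = build_food_network(calls, foods)
    assert g.number_of_edges() == 0


def test_edge_weight_is_shared_protein_count():
    foods = _foods({"A": {"c1"}, "B": {"c2"}})
    calls = [_call("c1", p) for p in ("p1", "p2", "p3", "p4")] + [
        _call("c2", p) for p in ("p1", "p2", "p3", "p9")
    ]
    g = build_food_network(calls, foods)
    assert g.edges["A", "B"]["weight"] == 3
    assert g.nodes["A"]["n_bioactive_compounds"] == 1
    assert g.nodes["A"]["n_interacting_proteins"] == 4


@pytest.mark.parametrize("trial", range(10))
def test_food_network_weights_match_pairwise_intersections(trial):
    rnd = random.Random(400 + trial)
    compounds = [f"c{i}" for i in range(40)]
    proteins = [f"p{i}" for i in range(15)]
    foods = _foods(
        {f"F{i}": set(rnd.sample(compounds, rnd.randint(1, 8))) for i in range(12)}
    )
    calls = [
        _call(c, p, active=rnd.random() < 0.6)
        for c in compounds
        for p in rnd.sample(proteins, 3)
    ]
    g = build_food_network(calls, foods)
    active = {}
    for c in calls:
        if c.is_active:
            active.setdefault(c.compound_id, set()).add(c.protein_id)
    prot_of = {
        f: set().union(*(active.get(c, set()) for c in foods[f].compound_ids))
        for f in foods
    }
    for f1, f2 in itertools.combinations(sorted(foods), 2):
        w = len(prot_of[f1] & prot_of[f2])
        if w:
            assert g.edges[f1, f2]["weight"] == w
        else:
            assert not g.has_edge(f1, f2)


def _target_setup(pair_counts):
    """Build foods/drugs/calls so each target pair shares a chosen number of
    (drug, food) pairs: one drug targets every protein, and k foods carry a
    compound active against both members of the pair."""
    proteins, foods, calls = {}, {}, []
    targets = sorted({t for pair in pair_counts for t in pair})
    for t in targets:
        proteins[t] = ProteinRecord(t, ProteinCategory.DRUG_TARGET, frozenset({"cancer"}))
    drugs = {"D0": DrugRecord("D0", "dc0", tuple((t, ProteinCategory.DRUG_TARGET) for t in targets))}
    n = max(pair_counts.values(), default=0)
    for i in range(n):
        foods[f"F{i}"] = FoodRecord(f"F{i}", frozenset({f"c{i}"}))
    for (t1, t2), k in pair_counts.items():
        for i in range(k):
            calls.append(_call(f"c{i}", t1))
            calls.append(_call(f"c{i}", t2))
    return proteins, drugs, foods, calls


def test_target_edge_threshold_boundary():
    proteins, drugs, foods, calls = _target_setup({("t1", "t2"): 3})
    g = build_target_network(calls, drugs, proteins, foods, "cancer", CFG)
    assert g.has_edge("t1", "t2") and g.edges["t1", "t2"]["weight"] >= 3

    proteins, drugs, foods, calls = _target_setup({("t1", "t2"): 2})
    g = build_target_network(calls, drugs, proteins, foods, "cancer", CFG)
    assert not g.has_edge("t1", "t2")


def test_unknown_disease_class_yields_empty_network():
    proteins, drugs, foods, calls = _target_setup({("t1", "t2"): 3})
    g = build_target_network(calls, drugs, proteins, foods, "nonexistent", CFG)
    assert g.number_of_nodes() == 0 and g.graph["n_targets"] == 0


def test_top_k_keeps_all_edges_when_fewer_than_k():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1), ("a", "c", 2), ("a", "d", 3)])
    out = top_k_edges(g, 5)
    assert set(out.edges) == set(g.edges)


def test_star_edges_survive_via_leaf_endpoints():
    # an edge survives when it is top-k for either endpoint, and every
    # star edge is its leaf's single heaviest edge
    g = nx.Graph()
    for x in "bcdefgh":
        g.add_edge("a", x, weight=1)
    out = top_k_edges(g, 5)
    assert set(out.edges) == set(g.edges)


def test_tie_break_is_lexical_where_hub_choice_decides():
    # each leaf's own top-1 edge is its heavy side edge, so survival of the
    # equal-weight hub edges is decided by the hub's lexical tie-break
    g = nx.Graph()
    for i, x in enumerate("bcdefgh"):
        g.add_edge("a", x, weight=1)
        g.add_edge(x, f"z{i}", weight=10)
    out = top_k_edges(g, 1)
    assert sorted(v for _, v in out.edges("a")) == ["b"]


def test_top_k_is_idempotent():
    rnd = random.Random(12)
    g = nx.gnm_random_graph(15, 60, seed=12)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = rnd.randint(1, 9)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    once = top_k_edges(g, 3)
    twice = top_k_edges(once, 3)
    assert set(once.edges) == set(twice.edges)


@pytest.mark.parametrize("trial", range(10))
def test_top_k_equals_per_node_sort_union(trial):
    rnd = random.Random(500 + trial)
    g = nx.gnm_random_graph(12, 40, seed=trial)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = rnd.randint(1, 6)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    k = 3
    out = top_k_edges(g, k)
    expect = set()
    for node in g.nodes:
        ranked = sorted(
            g.edges(node, data="weight"),
            key=lambda e: (-e[2], tuple(sorted((e[0], e[1])))),
        )
        expect |= {tuple(sorted((u, v))) for u, v, _ in ranked[:k]}
    assert {tuple(sorted(e)) for e in out.edges} == expect


def test_single_candidate_is_selected_regardless_of_affinity():
    proteins = {"t": ProteinRecord("t", ProteinCategory.DRUG_TARGET)}
    foods = _foods({"F": {"c1"}})
    drugs = {"D": DrugRecord("D", "dc", (("t", ProteinCategory.DRUG_TARGET),))}
    calls = [_call("c1", "t", affinity=99_000.0)]
    ann = annotate_strongest_binder("t", "pd", calls, foods, drugs, proteins)
    assert ann.best_phytochemical == "c1" and ann.best_affinity == 99_000.0
    assert ann.foods == {"F"} and ann.drugs == {"D"}


def test_annotation_absent_without_active_phytochemical():
    proteins = {"t": ProteinRecord("t", ProteinCategory.DRUG_TARGET)}
    calls = [_call("c1", "t", active=False)]
    assert annotate_strongest_binder("t", "pd", calls, _foods({}), {}, proteins) is None
    # wrong role context: a drug target has no pharmacokinetics reading
    calls = [_call("c1", "t")]
    assert annotate_strongest_binder("t", "pk", calls, _foods({}), {}, proteins) is None


def test_expected_count_formula():
    ins = [
        EnrichmentInput("zero", 0, 1806, 186),
        EnrichmentInput("all", 1806, 1806, 186),
        EnrichmentInput("signal", 100, 1806, 186),
    ]
    res = {r.category: r for r in category_enrichment(ins, {"zero": 0, "all": 186, "signal": 30})}
    assert res["zero"].expected == 0.0
    assert res["all"].expected == pytest.approx(186.0)
    assert res["signal"].expected == pytest.approx(100 * 186 / 1806)
    assert res["signal"].expected == pytest.approx(10.30, abs=0.005)


def test_expected_counts_sum_to_tpa_for_partition():
    rnd = random.Random(8)
    sizes = [rnd.randint(10, 400) for _ in range(6)]
    tdt = sum(sizes)
    tpa = 150
    ins = [EnrichmentInput(f"cat{i}", s, tdt, tpa) for i, s in enumerate(sizes)]
    res = category_enrichment(ins, {f"cat{i}": 10 for i in range(6)})
    assert sum(r.expected for r in res) == pytest.approx(tpa)


def test_enrichment_requires_positive_tdt():
    with pytest.raises(ValueError):
        category_enrichment([EnrichmentInput("x", 0, 0, 5)], {"x": 1})


def test_disease_class_target_counts_sum_to_at_least_distinct_targets():
    # disease classes overlap, so summing per-class counts >= distinct targets
    pair_counts = {("t1", "t2"): 3}
    proteins, drugs, foods, calls = _target_setup(pair_counts)
    proteins["t1"] = ProteinRecord("t1", ProteinCategory.DRUG_TARGET, frozenset({"cancer", "neurological"}))
    per_class = {
        dc: build_target_network(calls, drugs, proteins, foods, dc, CFG).graph["n_targets"]
        for dc in ("cancer", "neurological")
    }
    distinct = len({p for p in proteins})
    assert sum(per_class.values()) >= distinct


def test_overrepresented_category_flagged_by_both_tests():
    ins = [EnrichmentInput(f"c{i}", 100, 1000, 100) for i in range(5)]
    obs = {f"c{i}": 10 for i in range(5)}
    obs["c0"] = 40  # 4x expected
    res = {r.category: r for r in category_enrichment(ins, obs)}
    assert res["c0"].t_significant
    assert res["c0"].binomial_p < 0.05
    assert not res["c1"].t_significant
    assert res["c1"].binomial_p > 0.05
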