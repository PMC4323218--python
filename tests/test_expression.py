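"""Moderated t-test, tag lists, KS connectivity and the DE/non-DE comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dfi import PipelineConfig
from dfi.expression import (
    DEResult,
    TagLists,
    build_tag_lists,
    connectivity_score,
    de_vs_nonde_affinity,
    differential_expression,
    ks_enrichment,
)

CFG = PipelineConfig()


def _matrix(rng, n_genes, n_per_group, shift_idx=(), shift=0.0, sigma=1.0):
    X = rng.normal(8.0, sigma, size=(n_genes, 2 * n_per_group))
    for i in shift_idx:
        X[i, :n_per_group] += shift
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"T{j}" for j in range(n_per_group)] + [f"C{j}" for j in range(n_per_group)]
    groups = pd.Series(
        ["treatment"] * n_per_group + ["control"] * n_per_group, index=samples
    )
    return pd.DataFrame(X, index=genes, columns=samples), groups


def test_null_data_keeps_raw_type_one_error_near_nominal():
    rng = np.random.default_rng(42)
    mat, groups = _matrix(rng, 10_000, 5)
    res = differential_expression(mat, groups)
    frac = float((res.table["p_value"] < 0.05).mean())
    assert frac == pytest.approx(0.05, abs=0.01)
    # essentially nothing survives FDR on null data
    assert int((res.table["direction"] != "ns").sum()) <= 5


def test_planted_two_fold_shift_recovered_with_controlled_fdr():
    rng = np.random.default_rng(7)
    planted = list(range(200))
    mat, groups = _matrix(rng, 4000, 5, shift_idx=planted, shift=2.0, sigma=0.7)
    res = differential_expression(mat, groups)
    called = set(np.flatnonzero((res.table["direction"] != "ns").to_numpy()))
    sensitivity = len(called & set(planted)) / len(planted)
    false_calls = len(called - set(planted))
    fdr = false_calls / max(len(called), 1)
    assert sensitivity > 0.8
    assert fdr < 0.15  # nominal 0.05 plus simulation tolerance


def test_bh_step_up_arithmetic():
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(np.array([0.01, 0.02, 0.03, 0.04]), method="fdr_bh")
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_zero_variance_gene_flagged_p_one():
    rng = np.random.default_rng(1)
    mat, groups = _matrix(rng, 50, 3)
    mat.iloc[0] = 5.0  # constant gene, zero difference and zero variance
    res = differential_expression(mat, groups)
    assert res.table.iloc[0]["p_value"] == 1.0


def test_fdr_alpha_extremes_mark_all_or_none():
    rng = np.random.default_rng(3)
    mat, groups = _matrix(rng, 100, 3)
    all_sig = differential_expression(mat, groups, CFG.replace(fdr_alpha=1.0 + 1e-12))
    assert (all_sig.table["direction"] != "ns").all()
    none_sig = differential_expression(mat, groups, CFG.replace(fdr_alpha=0.0))
    assert (none_sig.table["direction"] == "ns").all()


def _de_result(directions_p):
    """directions_p: list of (gene, direction, p)."""
    tab = pd.DataFrame(
        {
            "log_fc": [1.0 if d == "up" else -1.0 for _, d, _ in directions_p],
            "t": 0.0,
            "p_value": [p for _, _, p in directions_p],
            "fdr_q": [p for _, _, p in directions_p],
            "direction": [d for _, d, _ in directions_p],
        },
        index=[g for g, _, _ in directions_p],
    )
    return DEResult(tab, 1.0, 1.0)


def test_tag_lists_sizes_and_unmapped_accounting():
    rows = [(f"u{i}", "up", 0.001 * (i + 1)) for i in range(10)]
    rows += [(f"d{i}", "down", 0.001 * (i + 1)) for i in range(5)]
    rows += [(f"n{i}", "ns", 0.5) for i in range(5)]
    de = _de_result(rows)
    tl = build_tag_lists(de, None, "food")
    assert (len(tl.up_tags), len(tl.down_tags)) == (10, 5)
    id_map = {g: f"probe_{g}" for g, d, _ in rows if d != "ns"}
    for drop in ("u0", "u1", "d0"):  # 20% of the 15 tags unmappable
        del id_map[drop]
    tl2 = build_tag_lists(de, id_map, "food")
    assert (len(tl2.up_tags), len(tl2.down_tags)) == (8, 4)
    assert tl2.n_unmapped == 3


def test_all_ns_is_an_error():
    de = _de_result([("g1", "ns", 0.9), ("g2", "ns", 0.8)])
    with pytest.raises(ValueError, match="nothing to score"):
        build_tag_lists(de, None, "food")


def _reference(n, order):
    """Rank matrix with one instance: order[i] = probe at rank i+1."""
    probes = [f"p{i:03d}" for i in range(n)]
    ranks = np.empty(n, dtype=int)
    for pos, probe_idx in enumerate(order):
        ranks[probe_idx] = pos + 1
    return pd.DataFrame({"inst0": ranks}, index=probes)


def test_extremal_tags_reach_score_one():
    n = 100
    ref = _reference(n, list(range(n)))
    up = [f"p{i:03d}" for i in range(5)]  # the very top of the ranking
    down = [f"p{i:03d}" for i in range(n - 5, n)]  # the very bottom
    tl = TagLists("f", up, down)
    cfg = CFG.replace(n_permutations=200)
    (res,) = connectivity_score(tl, ref, {"drug": ["inst0"]}, cfg, np.random.default_rng(0))
    assert res.enrichment_score == pytest.approx(1.0)
    assert res.nonnull_pct == 100.0


def test_up_down_swap_flips_the_sign_exactly():
    rng = np.random.default_rng(5)
    n = 200
    ref = _reference(n, list(rng.permutation(n)))
    probes = list(ref.index)
    up = [probes[i] for i in rng.choice(n, 10, replace=False)]
    rest = [p for p in probes if p not in up]
    down = [rest[i] for i in rng.choice(len(rest), 10, replace=False)]
    cfg = CFG.replace(n_permutations=50)
    (a,) = connectivity_score(TagLists("f", up, down), ref, {"d": ["inst0"]}, cfg, np.random.default_rng(1))
    (b,) = connectivity_score(TagLists("f", down, up), ref, {"d": ["inst0"]}, cfg, np.random.default_rng(1))
    assert a.enrichment_score == pytest.approx(-b.enrichment_score)


def test_scaling_puts_strongest_instance_at_unit_magnitude():
    rng = np.random.default_rng(11)
    n = 150
    probes = [f"p{i:03d}" for i in range(n)]
    cols = {}
    for j in range(4):
        cols[f"i{j}"] = rng.permutation(n) + 1
    ref = pd.DataFrame(cols, index=probes)
    up = [probes[i] for i in rng.choice(n, 8, replace=False)]
    down = [probes[i] for i in rng.choice(n, 8, replace=False) if probes[i] not in up]
    cfg = CFG.replace(n_permutations=20)
    results = connectivity_score(
        TagLists("f", up, down), ref, {f"i{j}": [f"i{j}"] for j in range(4)}, cfg, np.random.default_rng(2)
    )
    scores = [r.enrichment_score for r in results]
    if any(s != 0 for s in scores):
        assert max(abs(s) for s in scores) == pytest.approx(1.0)


def test_ks_enrichment_matches_direct_formula():
    # tags at 1-based ranks {2, 5, 9} of a 10-item list
    pos = np.array([2.0, 5.0, 9.0])
    t, n = 3, 10
    j = np.arange(1, t + 1)
    a = max(j / t - pos / n)
    b = max(pos / n - (j - 1) / t)
    expect = a if a > b else -b
    assert ks_enrichment(pos, n) == pytest.approx(expect)


def test_tag_list_longer_than_ranking_is_error():
    ref = _reference(10, list(range(10)))
    tl = TagLists("f", [f"p{i:03d}" for i in range(10)] + ["px"], [])
    with pytest.raises(ValueError):
        connectivity_score(tl, ref, {"d": ["inst0"]}, CFG.replace(n_permutations=10))


def test_classification_boundary_requires_strict_thresholds():
    # synthesize results directly through the public scorer on an extremal
    # profile, then check the boundary logic on the emitted classification
    n = 60
    rng = np.random.default_rng(3)
    probes = [f"p{i:03d}" for i in range(n)]
    cols = {}
    for j in range(3):  # three near-identical extremal instances
        order = np.arange(n)
        a, b = 20 + j, 30 + j  # a small interior swap per instance
        order[a], order[b] = order[b], order[a]
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        cols[f"inst{j}"] = ranks
    for j in range(6):  # unrelated instances from two other reference sets
        cols[f"null{j}"] = rng.permutation(n) + 1
    ref = pd.DataFrame(cols, index=probes)
    up = probes[:4]
    down = probes[-4:]
    cfg = CFG.replace(n_permutations=400)
    sets = {
        "d": ["inst0", "inst1", "inst2"],
        "x": ["null0", "null1", "null2"],
        "y": ["null3", "null4", "null5"],
    }
    results = {r.reference_id: r for r in connectivity_score(TagLists("f", up, down), ref, sets, cfg, np.random.default_rng(3))}
    res = results["d"]
    assert res.enrichment_score > 0.75 and res.permutation_p < 0.01
    assert res.classification == "correlated"
    # a score at the cutoff must classify null (strictly 'higher than')
    strict_cfg = cfg.replace(es_min=res.enrichment_score)
    results2 = {r.reference_id: r for r in connectivity_score(TagLists("f", up, down), ref, sets, strict_cfg, np.random.default_rng(3))}
    assert results2["d"].classification == "null"


def test_identical_affinity_distributions_give_large_p():
    links = pd.DataFrame(
        {
            "compound_id": ["c"] * 8,
            "protein_id": [f"g{i}" for i in range(8)],
            "affinity_nM": [10, 20, 30, 40, 10, 20, 30, 40],
        }
    )
    res = de_vs_nonde_affinity(links, {"g0", "g1", "g2", "g3"})
    assert res.p_value > 0.5


def test_planted_lower_nonde_affinities_reject():
    rng = np.random.default_rng(21)
    rows = []
    for ci in range(10):
        for gi in range(6):
            de = gi < 3
            aff = 10 ** rng.normal(3 if de else 2, 0.2)  # non-DE 10x lower
            rows.append(
                {"compound_id": f"c{ci}", "protein_id": f"{'de' if de else 'nd'}{ci}_{gi}", "affinity_nM": aff}
            )
    links = pd.DataFrame(rows)
    de_genes = {r["protein_id"] for r in rows if r["protein_id"].startswith("de")}
    res = de_vs_nonde_affinity(links, de_genes)
    assert res.p_value < 0.05
    assert np.median(res.nonde_affinities) < np.median(res.de_affinities)


def test_small_sample_rank_sum_matches_exhaustive_enumeration():
    x = [1.0, 5.0, 9.0]
    y = [2.0, 3.0, 11.0]
    links = pd.DataFrame(
        {
            "compound_id": ["c"] * 6,
            "protein_id": [f"d{i}" for i in range(3)] + [f"n{i}" for i in range(3)],
            "affinity_nM": x + y,
        }
    )
    res = de_vs_nonde_affinity(links, {"d0", "d1", "d2"})
    # enumerate all C(6,3) assignments of the pooled values to group 1
    pooled = x + y
    ranks = {v: r for r, v in enumerate(sorted(pooled), 1)}
    obs = sum(ranks[v] for v in x)
    null = [sum(ranks[pooled[i]] for i in comb) for comb in itertools.combinations(range(6), 3)]
    center = 3 * 7 / 2
    p_exact = sum(abs(s - center) >= abs(obs - center) for s in null) / len(null)
    assert res.p_value == pytest.approx(p_exact)


def test_missing_both_group_compounds_is_informative_error():
    links = pd.DataFrame(
        {"compound_id": ["c"], "protein_id": ["g1"], "affinity_nM": [10.0]}
    )
    with pytest.raises(ValueError, match="both"):
        de_vs_nonde_affinity(links, {"g1"})
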