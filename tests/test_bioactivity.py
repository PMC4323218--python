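"""Measurement filtering, frequency aggregation and activity calls."""

import math
import random

import pytest

from dfi import PipelineConfig
from dfi.bioactivity import (
    DrugAffinityIndex,
    aggregate_interactions,
    classify_activity,
    filter_measurements,
    flag_measurement,
    food_protein_profile,
    geometric_mean,
)
from dfi.records import (
    ActivityBasis,
    ConfidentInteraction,
    Endpoint,
    FoodRecord,
    MeasurementRecord,
    ProteinCategory,
    ProteinRecord,
)

CFG = PipelineConfig()


def M(endpoint, value=None, pchembl=None, cid="c", pid="p"):
    return MeasurementRecord(cid, pid, Endpoint(endpoint), value, pchembl)


@pytest.mark.parametrize(
    "measurement,positive",
    [
        (M("IC50", pchembl=6.5), True),
        (M("IC50", pchembl=6.0), False),  # strict 'larger than 6'
        (M("Ki", value=100.0), True),  # pchembl derived: 7 > 6
        (M("Kd", value=5000.0), False),  # derived 5.3
        (M("inhibition", value=30.0), False),  # strict 'greater than 30%'
        (M("inhibition", value=30.1), True),
        (M("potency", value=49_000.0), True),  # 49 uM < 50 uM
        (M("potency", value=51_000.0), False),
        (M("potency", value=50_000.0), False),  # strict 'lower than'
        (M("IC50"), False),  # nothing to judge by
    ],
)
def test_endpoint_specific_positivity_rules(measurement, positive):
    assert flag_measurement(measurement, CFG).positive is positive


def test_frequency_boundary_cases():
    two_of_three = [M("IC50", value=10.0), M("IC50", value=20.0), M("IC50", value=5000.0)]
    kept = aggregate_interactions(filter_measurements(two_of_three, CFG), CFG)
    assert len(kept) == 1 and kept[0].positive_frequency == pytest.approx(2 / 3)

    one_of_two = [M("IC50", value=10.0), M("IC50", value=5000.0)]
    assert aggregate_interactions(filter_measurements(one_of_two, CFG), CFG) == []


def test_representative_affinity_is_geometric_mean_of_positives():
    ms = [M("IC50", value=10.0), M("IC50", value=1000.0, pchembl=6.5), M("IC50", value=40.0)]
    (it,) = aggregate_interactions(filter_measurements(ms, CFG), CFG)
    assert it.representative_affinity == pytest.approx((10 * 1000 * 40) ** (1 / 3))


def _brute_force(rows, cfg):
    """Independent oracle: group raw rows, apply the endpoint rules inline."""
    groups = {}
    for cid, pid, ep, value, pchembl in rows:
        groups.setdefault((cid, pid), []).append((ep, value, pchembl))
    kept = {}
    for key, ms in groups.items():
        pos = 0
        for ep, value, pchembl in ms:
            if ep in ("Ki", "Kd", "IC50", "EC50"):
                p = pchembl if pchembl is not None else (
                    9 - math.log10(value) if value else None
                )
                ok = p is not None and p > cfg.pchembl_min
            elif ep == "inhibition":
                ok = value is not None and value > cfg.inhibition_min_pct
            else:
                ok = value is not None and value < cfg.potency_max_nM
            pos += ok
        if pos / len(ms) > cfg.frequency_min:
            kept[key] = pos / len(ms)
    return kept


@pytest.mark.parametrize("trial", range(20))
def test_aggregation_matches_brute_force_on_random_tables(trial):
    rnd = random.Random(1000 + trial)
    rows = []
    for _ in range(rnd.randint(50, 300)):
        cid = f"c{rnd.randint(0, 20)}"
        pid = f"p{rnd.randint(0, 10)}"
        ep = rnd.choice(["Ki", "Kd", "IC50", "EC50", "inhibition", "potency"])
        if ep == "inhibition":
            value, pchembl = rnd.uniform(0, 100), None
        else:
            value = 10 ** rnd.uniform(0, 6)
            pchembl = rnd.uniform(4, 9) if rnd.random() < 0.3 else None
        rows.append((cid, pid, ep, value, pchembl))
    ms = [M(ep, value, pchembl, cid, pid) for cid, pid, ep, value, pchembl in rows]
    got = {
        (i.compound_id, i.protein_id): i.positive_frequency
        for i in aggregate_interactions(filter_measurements(ms, CFG), CFG)
    }
    expect = _brute_force(rows, CFG)
    assert got.keys() == expect.keys()
    for k in got:
        assert got[k] == pytest.approx(expect[k])


def test_adding_positive_measurement_never_drops_interaction():
    base = [M("IC50", value=10.0), M("IC50", value=5000.0), M("IC50", value=20.0)]
    kept_before = aggregate_interactions(filter_measurements(base, CFG), CFG)
    kept_after = aggregate_interactions(
        filter_measurements(base + [M("IC50", value=15.0)], CFG), CFG
    )
    before_keys = {(i.compound_id, i.protein_id) for i in kept_before}
    after_keys = {(i.compound_id, i.protein_id) for i in kept_after}
    assert before_keys <= after_keys


def test_tightening_pchembl_threshold_never_adds_interactions():
    rnd = random.Random(5)
    ms = [M("IC50", value=10 ** rnd.uniform(0, 5), cid=f"c{i%7}", pid=f"p{i%3}") for i in range(60)]
    loose = {(i.compound_id, i.protein_id) for i in aggregate_interactions(filter_measurements(ms, CFG), CFG)}
    tight_cfg = CFG.replace(pchembl_min=7.0)
    tight = {
        (i.compound_id, i.protein_id)
        for i in aggregate_interactions(filter_measurements(ms, tight_cfg), tight_cfg)
    }
    assert tight <= loose


def _interaction(affinity, cid="c", pid="p"):
    return ConfidentInteraction(cid, pid, 1.0, 1, affinity, frozenset({Endpoint.IC50}))


def test_activity_inside_drug_range():
    idx = DrugAffinityIndex(per_protein={"p": (10.0, 500.0)})
    call = classify_activity(_interaction(100.0), idx, {}, CFG)
    assert call.is_active and call.basis is ActivityBasis.DRUG_RANGE
    assert call.drug_range == (10.0, 500.0)


def test_activity_weaker_than_weakest_drug_is_inactive():
    idx = DrugAffinityIndex(per_protein={"p": (10.0, 500.0)})
    assert not classify_activity(_interaction(5000.0), idx, {}, CFG).is_active


def test_stronger_than_every_drug_is_active_unless_strict():
    idx = DrugAffinityIndex(per_protein={"p": (10.0, 500.0)})
    assert classify_activity(_interaction(1.0), idx, {}, CFG).is_active
    strict = CFG.replace(strict_two_sided_range=True)
    assert not classify_activity(_interaction(1.0), idx, {}, strict).is_active


def test_category_mean_fallback_only_without_drug_data():
    proteins = {"p": ProteinRecord("p", ProteinCategory.ENZYME)}
    idx = DrugAffinityIndex(category_mean={ProteinCategory.ENZYME: 200.0})
    call = classify_activity(_interaction(100.0), idx, proteins, CFG)
    assert call.is_active and call.basis is ActivityBasis.CATEGORY_MEAN_FALLBACK
    assert call.category_mean == 200.0
    # drug data present -> always the range branch, never the fallback
    idx.per_protein["p"] = (50.0, 60.0)
    call2 = classify_activity(_interaction(100.0), idx, proteins, CFG)
    assert call2.basis is ActivityBasis.DRUG_RANGE and not call2.is_active


def test_no_basis_at_all_yields_inactive_fallback():
    call = classify_activity(_interaction(100.0), DrugAffinityIndex(), {}, CFG)
    assert not call.is_active and call.basis is ActivityBasis.CATEGORY_MEAN_FALLBACK


def test_food_profile_counts_compounds_and_proteins_per_category():
    from dfi.records import ActivityCall

    foods = {"f": FoodRecord("f", frozenset({"c1", "c2"}))}
    proteins = {
        "t1": ProteinRecord("t1", ProteinCategory.DRUG_TARGET),
        "t2": ProteinRecord("t2", ProteinCategory.DRUG_TARGET),
        "e1": ProteinRecord("e1", ProteinCategory.ENZYME),
    }
    calls = [
        ActivityCall("c1", "t1", True, ActivityBasis.DRUG_RANGE),
        ActivityCall("c1", "t2", True, ActivityBasis.DRUG_RANGE),
        ActivityCall("c1", "e1", True, ActivityBasis.DRUG_RANGE),
        ActivityCall("c2", "t1", False, ActivityBasis.DRUG_RANGE),
    ]
    (prof,) = food_protein_profile(foods, calls, proteins)
    assert prof.n_bioactive_compounds == 1
    assert prof.n_interacting_proteins == 3
    assert prof.per_category == {ProteinCategory.DRUG_TARGET: 2, ProteinCategory.ENZYME: 1}


def test_profile_all_zero_without_active_compounds():
    foods = {"f": FoodRecord("f", frozenset({"c1"}))}
    (prof,) = food_protein_profile(foods, [], {})
    assert (prof.n_bioactive_compounds, prof.n_interacting_proteins) == (0, 0)


def test_geometric_mean_matches_log_average():
    vals = [1.0, 10.0, 100.0]
    assert geometric_mean(vals) == pytest.approx(10.0)
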