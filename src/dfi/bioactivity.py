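"""Bioassay filtering, aggregation and activity classification.

The stage turns raw bioassay measurements into confident compound-protein
interactions and then decides, for each food compound, whether it is
*active* against a protein in the sense relevant to drug interference:

1. Each measurement is flagged positive by an endpoint-specific rule
   (pchembl > 6 for Ki/Kd/IC50/EC50; inhibition > 30%; potency < 50 uM).
2. Replicated measurements of one (compound, protein) pair are summarized
   by their fraction of positive flags; pairs with frequency > 0.5 are
   kept as confident interactions. The representative affinity is the
   geometric mean of the positive affinity values (affinities span orders
   of magnitude, so means are taken on the log scale).
3. A food compound is called active against a protein when its
   representative affinity is at least as potent as the weakest drug
   binding the same protein (the drug activity range). When no drug
   affinity exists for the protein, the compound is compared to the mean
   drug affinity over all proteins of the same category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import fmean

from .config import PipelineConfig
from .records import (
    AFFINITY_ENDPOINTS,
    ActivityBasis,
    ActivityCall,
    ConfidentInteraction,
    DrugRecord,
    Endpoint,
    FoodRecord,
    MeasurementRecord,
    ProteinCategory,
    ProteinRecord,
)

logger = logging.getLogger("dfi")


@dataclass(frozen=True)
class FlaggedMeasurement:
    measurement: MeasurementRecord
    positive: bool
    reason: str  # which rule fired, or why the flag is negative


def flag_measurement(m: MeasurementRecord, config: PipelineConfig) -> FlaggedMeasurement:
    """Apply the endpoint-specific positivity rule to one measurement."""
    if m.endpoint in AFFINITY_ENDPOINTS:
        p = m.derived_pchembl()
        if p is None:
            return FlaggedMeasurement(m, False, "missing_pchembl")
        return FlaggedMeasurement(m, p > config.pchembl_min, f"pchembl={p:.3g}")
    if m.endpoint is Endpoint.INHIBITION:
        if m.value is None:
            return FlaggedMeasurement(m, False, "missing_value")
        return FlaggedMeasurement(m, m.value > config.inhibition_min_pct, f"inhibition={m.value:.3g}%")
    # potency, nM scale after normalization
    if m.value is None:
        return FlaggedMeasurement(m, False, "missing_value")
    return FlaggedMeasurement(m, m.value < config.potency_max_nM, f"potency={m.value:.3g}nM")


def filter_measurements(
    measurements: list[MeasurementRecord], config: PipelineConfig
) -> list[FlaggedMeasurement]:
    """Flag every measurement positive/negative; total over valid records."""
    flagged = [flag_measurement(m, config) for m in measurements]
    n_missing = sum(1 for f in flagged if not f.positive and f.reason.startswith("missing"))
    if n_missing:
        logger.info("%d measurements lacked the field needed for their endpoint", n_missing)
    return flagged


def geometric_mean(values: list[float]) -> float:
    if len(values) == 1:  # avoid log/exp round-trip noise on singletons
        return values[0]
    return 10 ** fmean(math.log10(v) for v in values)


def aggregate_interactions(
    flagged: list[FlaggedMeasurement], config: PipelineConfig
) -> list[ConfidentInteraction]:
    """Collapse flags to per-pair positive frequencies; keep freq > 0.5.

    Representative affinity is the geometric mean over the positive
    affinity-endpoint values (absent if no affinity endpoint contributed).
    """
    groups: dict[tuple[str, str], list[FlaggedMeasurement]] = {}
    for f in flagged:
        groups.setdefault((f.measurement.compound_id, f.measurement.protein_id), []).append(f)

    out: list[ConfidentInteraction] = []
    for (cid, pid), fs in sorted(groups.items()):
        n = len(fs)
        n_pos = sum(f.positive for f in fs)
        freq = n_pos / n
        if freq <= config.frequency_min:
            continue
        pos_affinities = [
            f.measurement.value
            for f in fs
            if f.positive
            and f.measurement.endpoint in AFFINITY_ENDPOINTS
            and f.measurement.value is not None
        ]
        out.append(
            ConfidentInteraction(
                compound_id=cid,
                protein_id=pid,
                positive_frequency=freq,
                n_measurements=n,
                representative_affinity=geometric_mean(pos_affinities) if pos_affinities else None,
                endpoint_mix=frozenset(f.measurement.endpoint for f in fs),
            )
        )
    return out


@dataclass
class DrugAffinityIndex:
    """Per-protein drug affinity ranges and per-category means.

    Built from the drugs' own measurements pushed through the same
    filter/aggregate path as the food compounds (positive-only evidence).
    """

    per_protein: dict[str, tuple[float, float]] = field(default_factory=dict)  # (min, max) nM
    per_protein_endpoint: dict[tuple[str, Endpoint], tuple[float, float]] = field(
        default_factory=dict
    )
    category_mean: dict[ProteinCategory, float] = field(default_factory=dict)  # geometric, nM


def build_drug_affinity_index(
    drug_interactions: list[ConfidentInteraction],
    drugs: dict[str, DrugRecord],
    proteins: dict[str, ProteinRecord],
    flagged: list[FlaggedMeasurement] | None = None,
) -> DrugAffinityIndex:
    """Index drug binding evidence by protein and by protein category.

    ``drug_interactions`` are confident interactions whose compound is a
    drug ingredient. The per-category mean is a macro average: the
    geometric mean over per-protein geometric means of drug affinities.
    """
    drug_compound_ids = {d.compound_id for d in drugs.values()}
    idx = DrugAffinityIndex()
    per_protein_values: dict[str, list[float]] = {}
    per_pe_values: dict[tuple[str, Endpoint], list[float]] = {}

    if flagged is not None:
        # endpoint-resolved ranges need the raw positive values
        for f in flagged:
            m = f.measurement
            if (
                f.positive
                and m.compound_id in drug_compound_ids
                and m.endpoint in AFFINITY_ENDPOINTS
                and m.value is not None
            ):
                per_pe_values.setdefault((m.protein_id, m.endpoint), []).append(m.value)

    for it in drug_interactions:
        if it.compound_id in drug_compound_ids and it.representative_affinity is not None:
            per_protein_values.setdefault(it.protein_id, []).append(it.representative_affinity)

    for pid, vals in per_protein_values.items():
        idx.per_protein[pid] = (min(vals), max(vals))
    for key, vals in per_pe_values.items():
        idx.per_protein_endpoint[key] = (min(vals), max(vals))

    by_category: dict[ProteinCategory, list[float]] = {}
    for pid, vals in per_protein_values.items():
        prot = proteins.get(pid)
        if prot is None:
            continue
        by_category.setdefault(prot.category, []).append(geometric_mean(vals))
    for cat, means in by_category.items():
        idx.category_mean[cat] = geometric_mean(means)
    return idx


def classify_activity(
    interaction: ConfidentInteraction,
    drug_index: DrugAffinityIndex,
    proteins: dict[str, ProteinRecord],
    config: PipelineConfig,
) -> ActivityCall:
    """Decide active/inactive for one confident interaction.

    With drug affinity data on the protein the compound is active iff it is
    at least as potent as the weakest drug (representative affinity <= the
    range maximum); requiring it also to be no stronger than the most
    potent drug would reject phytochemicals that out-bind every drug, so
    the two-sided reading is opt-in (``strict_two_sided_range``). Without
    drug data the compound is compared to the category-level mean drug
    affinity. Interactions with no affinity value (inhibition/potency-only
    evidence) are active by the frequency rule alone.
    """
    cid, pid = interaction.compound_id, interaction.protein_id
    rep = interaction.representative_affinity

    if rep is None:
        # confident evidence without a binding constant: the range rule is
        # undefined, the frequency rule already vouched for the interaction
        return ActivityCall(cid, pid, True, ActivityBasis.DRUG_RANGE, None, None, None)

    rng = drug_index.per_protein.get(pid)
    if rng is not None:
        lo, hi = rng
        active = rep <= hi if not config.strict_two_sided_range else lo <= rep <= hi
        return ActivityCall(cid, pid, active, ActivityBasis.DRUG_RANGE, rng, None, rep)

    prot = proteins.get(pid)
    cat_mean = drug_index.category_mean.get(prot.category) if prot is not None else None
    if cat_mean is None:
        logger.warning(
            "protein %s has neither drug affinities nor a category mean; %s called inactive",
            pid,
            cid,
        )
        return ActivityCall(cid, pid, False, ActivityBasis.CATEGORY_MEAN_FALLBACK, None, None, rep)
    return ActivityCall(
        cid, pid, rep <= cat_mean, ActivityBasis.CATEGORY_MEAN_FALLBACK, None, cat_mean, rep
    )


def classify_all(
    food_interactions: list[ConfidentInteraction],
    drug_index: DrugAffinityIndex,
    proteins: dict[str, ProteinRecord],
    config: PipelineConfig,
) -> list[ActivityCall]:
    return [classify_activity(it, drug_index, proteins, config) for it in food_interactions]


@dataclass(frozen=True)
class FoodProfile:
    food_id: str
    n_bioactive_compounds: int
    n_interacting_proteins: int
    per_category: dict[ProteinCategory, int]


def food_protein_profile(
    foods: dict[str, FoodRecord],
    calls: list[ActivityCall],
    proteins: dict[str, ProteinRecord],
) -> list[FoodProfile]:
    """Per-food counts of active compounds and proteins hit, by category.

    Sorted by (proteins desc, compounds desc, food_id) so the head of the
    list is the most-interacting-foods ranking.
    """
    active_by_compound: dict[str, set[str]] = {}
    for c in calls:
        if c.is_active:
            active_by_compound.setdefault(c.compound_id, set()).add(c.protein_id)

    profiles = []
    for food in foods.values():
        compounds = {c for c in food.compound_ids if c in active_by_compound}
        prots: set[str] = set()
        for c in compounds:
            prots |= active_by_compound[c]
        per_cat: dict[ProteinCategory, int] = {}
        for pid in prots:
            p = proteins.get(pid)
            if p is not None:
                per_cat[p.category] = per_cat.get(p.category, 0) + 1
        profiles.append(FoodProfile(food.food_id, len(compounds), len(prots), per_cat))
    profiles.sort(key=lambda p: (-p.n_interacting_proteins, -p.n_bioactive_compounds, p.food_id))
    return profiles
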