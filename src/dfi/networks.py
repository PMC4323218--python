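"""Food-food, target-target and tripartite drug-target-food networks.

Three network families are built from the activity calls:

* **Food network** — foods are nodes; two foods are connected with weight
  equal to the number of proteins both interact with through active
  phytochemicals.
* **Target network** (per disease class) — drug targets are nodes; two
  targets are connected when at least 3 (drug, food) pairs have biological
  activity against both.
* **Tripartite annotation** — for each protein, the phytochemical with the
  strongest binding (minimal affinity in nM) among its active food
  compounds, with the foods containing it and the drugs linked to the
  protein in the matching role.

A display-layer top-k edge filter reproduces the "top 5 edges per node"
convention; it never feeds back into any statistic. Biological-system
overrepresentation uses the expectation exp = (tpc / tdt) * tpa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy import stats

from .config import PipelineConfig
from .records import (
    ActivityCall,
    DrugRecord,
    Endpoint,
    FoodRecord,
    PK_CATEGORIES,
    ProteinCategory,
    ProteinRecord,
)

logger = logging.getLogger("dfi")


def _active_protein_sets(
    calls: list[ActivityCall], foods: dict[str, FoodRecord]
) -> dict[str, set[str]]:
    """Proteins each food interacts with via >=1 active phytochemical."""
    active: dict[str, set[str]] = {}
    for c in calls:
        if c.is_active:
            active.setdefault(c.compound_id, set()).add(c.protein_id)
    out: dict[str, set[str]] = {}
    for fid, food in foods.items():
        prots: set[str] = set()
        for cid in food.compound_ids:
            prots |= active.get(cid, set())
        out[fid] = prots
    return out


def build_food_network(calls: list[ActivityCall], foods: dict[str, FoodRecord]) -> nx.Graph:
    """Foods connected by the number of shared interacting proteins.

    Node attributes: ``n_bioactive_compounds``, ``n_interacting_proteins``.
    Edge attribute: ``weight`` = |proteins(f1) ∩ proteins(f2)|. No
    self-edges; zero-weight pairs get no edge.
    """
    protein_sets = _active_protein_sets(calls, foods)
    active_compounds: dict[str, set[str]] = {}
    for c in calls:
        if c.is_active:
            active_compounds.setdefault(c.compound_id, set()).add(c.protein_id)

    g = nx.Graph()
    for fid in sorted(foods):
        n_comp = sum(1 for cid in foods[fid].compound_ids if cid in active_compounds)
        g.add_node(
            fid,
            n_bioactive_compounds=n_comp,
            n_interacting_proteins=len(protein_sets[fid]),
        )
    fids = sorted(foods)
    for i, f1 in enumerate(fids):
        for f2 in fids[i + 1 :]:
            w = len(protein_sets[f1] & protein_sets[f2])
            if w > 0:
                g.add_edge(f1, f2, weight=w)
    return g


def shared_drug_food_pairs(
    calls: list[ActivityCall],
    foods: dict[str, FoodRecord],
    drugs: dict[str, DrugRecord],
    role: ProteinCategory = ProteinCategory.DRUG_TARGET,
) -> dict[str, set[tuple[str, str]]]:
    """Per protein, the set of (drug, food) pairs active against it.

    A pair counts when the drug links the protein in ``role`` and the food
    contains >=1 phytochemical with an active call on it; a pair is counted
    once per protein however many phytochemicals mediate it.
    """
    foods_on_protein: dict[str, set[str]] = {}
    active: dict[str, set[str]] = {}
    for c in calls:
        if c.is_active:
            active.setdefault(c.protein_id, set()).add(c.compound_id)
    for fid, food in foods.items():
        for pid, cids in active.items():
            if food.compound_ids & cids:
                foods_on_protein.setdefault(pid, set()).add(fid)

    pairs: dict[str, set[tuple[str, str]]] = {}
    for did, drug in drugs.items():
        for pid, r in drug.protein_links:
            if r is not role:
                continue
            for fid in foods_on_protein.get(pid, ()):
                pairs.setdefault(pid, set()).add((did, fid))
    return pairs


def build_target_network(
    calls: list[ActivityCall],
    drugs: dict[str, DrugRecord],
    proteins: dict[str, ProteinRecord],
    foods: dict[str, FoodRecord],
    disease_class: str,
    config: PipelineConfig,
) -> nx.Graph:
    """Targets of one disease class, connected by >=3 shared drug-food pairs.

    Nodes are drug targets of the disease class that participate in >=1
    drug-food pair; the graph carries ``disease_class`` and the per-class
    target count as attributes.
    """
    pairs = shared_drug_food_pairs(calls, foods, drugs)
    in_class = {
        pid
        for pid, p in proteins.items()
        if p.category is ProteinCategory.DRUG_TARGET and disease_class in p.disease_classes
    }
    if not in_class:
        logger.warning("no drug targets annotated to disease class %r", disease_class)
    nodes = sorted(pid for pid in in_class if pairs.get(pid))
    g = nx.Graph(disease_class=disease_class, n_targets=len(nodes))
    for pid in nodes:
        g.add_node(pid, n_drug_food_pairs=len(pairs[pid]))
    for i, p1 in enumerate(nodes):
        for p2 in nodes[i + 1 :]:
            shared = len(pairs[p1] & pairs[p2])
            if shared >= config.shared_pair_min:
                g.add_edge(p1, p2, weight=shared)
    return g


def top_k_edges(g: nx.Graph, k: int) -> nx.Graph:
    """Display filter: keep each node's k heaviest edges (union over nodes).

    An edge survives when it is among the top k for either endpoint. Ties
    break by (weight descending, lexical edge key). Idempotent.
    """
    keep: set[tuple[str, str]] = set()
    for node in g.nodes:
        edges = sorted(
            g.edges(node, data=True),
            key=lambda e: (-e[2].get("weight", 1), tuple(sorted((str(e[0]), str(e[1]))))),
        )
        for u, v, _ in edges[:k]:
            keep.add(tuple(sorted((str(u), str(v)))))
    out = g.__class__()
    out.graph.update(g.graph)
    out.add_nodes_from(g.nodes(data=True))
    for u, v in sorted(keep):
        out.add_edge(u, v, **g.edges[u, v])
    return out


@dataclass(frozen=True)
class TripartiteAnnotation:
    protein_id: str
    best_phytochemical: str
    best_affinity: float  # nM
    endpoint: Endpoint | None
    foods: frozenset[str]
    drugs: frozenset[str]


def annotate_strongest_binder(
    protein_id: str,
    role_context: str,  # 'pd' (drug target) or 'pk' (enzyme/transporter/carrier)
    calls: list[ActivityCall],
    foods: dict[str, FoodRecord],
    drugs: dict[str, DrugRecord],
    proteins: dict[str, ProteinRecord],
    endpoint_of: dict[tuple[str, str], Endpoint] | None = None,
) -> TripartiteAnnotation | None:
    """Label a protein with its most potent active phytochemical.

    ``role_context`` selects the pharmacodynamics (drug-target) or
    pharmacokinetics (enzyme/transporter/carrier) reading of the protein:
    the protein's category must belong to the context and only drugs
    linking the protein in a matching role are listed. Returns None when no
    active phytochemical with an affinity exists (never zero-filled).
    """
    if role_context not in ("pd", "pk"):
        raise ValueError("role_context must be 'pd' or 'pk'")
    prot = proteins.get(protein_id)
    ctx_categories = (
        {ProteinCategory.DRUG_TARGET} if role_context == "pd" else set(PK_CATEGORIES)
    )
    if prot is None or prot.category not in ctx_categories:
        return None

    candidates = [
        c
        for c in calls
        if c.protein_id == protein_id and c.is_active and c.representative_affinity is not None
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (c.representative_affinity, c.compound_id))
    member_foods = frozenset(
        fid for fid, food in foods.items() if best.compound_id in food.compound_ids
    )
    linked_drugs = frozenset(
        did
        for did, d in drugs.items()
        if any(pid == protein_id and role in ctx_categories for pid, role in d.protein_links)
    )
    ep = endpoint_of.get((best.compound_id, protein_id)) if endpoint_of else None
    return TripartiteAnnotation(
        protein_id=protein_id,
        best_phytochemical=best.compound_id,
        best_affinity=best.representative_affinity,
        endpoint=ep,
        foods=member_foods,
        drugs=linked_drugs,
    )


@dataclass(frozen=True)
class EnrichmentInput:
    category: str
    tpc: int  # drug targets annotated to the category
    tdt: int  # total drug targets across categories
    tpa: int  # drug targets participating in food interactions


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    expected: float
    observed: int
    ratio: float
    t_significant: bool  # category ratio outlying under the stated t-test
    binomial_p: float


def category_enrichment(
    inputs: list[EnrichmentInput],
    observed: dict[str, int],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Biological-system overrepresentation of food-affected drug targets.

    Expected count per category: exp = (tpc / tdt) * tpa. Significance is
    reported two ways: a t-test over the per-category observed/expected
    ratios (each category's ratio compared, one-sided at level alpha, to
    the t bound of the remaining categories' ratios — leave-one-out so an
    outlying category does not inflate its own threshold), and an exact
    per-category binomial test of observed successes in tpa draws at
    probability tpc/tdt.
    """
    import statistics

    if not inputs:
        return []
    if any(i.tdt <= 0 for i in inputs):
        raise ValueError("tdt must be positive")
    prelim = []
    for inp in inputs:
        exp = (inp.tpc / inp.tdt) * inp.tpa
        obs = observed.get(inp.category, 0)
        ratio = obs / exp if exp > 0 else float("inf")
        prelim.append((inp, exp, obs, ratio))
    finite = [r for _, e, _, r in prelim if e > 0]

    def _t_flag(ratio: float) -> bool:
        others = [r for r in finite if r != ratio] or finite
        if len(others) < 2:
            return False
        mean_o = statistics.fmean(others)
        sd_o = statistics.stdev(others)
        if sd_o == 0:
            return ratio > mean_o
        t = (ratio - mean_o) / (sd_o * math.sqrt(1 + 1 / len(others)))
        return bool(stats.t.sf(t, df=len(others) - 1) < alpha)

    out = []
    for inp, exp, obs, ratio in prelim:
        p_cat = inp.tpc / inp.tdt
        binom_p = float(stats.binomtest(obs, inp.tpa, p_cat, alternative="greater").pvalue) if inp.tpa > 0 else 1.0
        out.append(
            EnrichmentResult(
                category=inp.category,
                expected=exp,
                observed=obs,
                ratio=ratio,
                t_significant=_t_flag(ratio) if exp > 0 else False,
                binomial_p=binom_p,
            )
        )
    return out


def export_network(g: nx.Graph, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Write a graph as nodes.tsv + edges.tsv + GraphML (all attributes)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    node_rows = [{"node": n, **{k: _plain(v) for k, v in d.items()}} for n, d in sorted(g.nodes(data=True))]
    paths["nodes"] = outdir / f"{stem}_nodes.tsv"
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False)
    edge_rows = [
        {"source": u, "target": v, **{k: _plain(val) for k, val in d.items()}}
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    paths["edges"] = outdir / f"{stem}_edges.tsv"
    pd.DataFrame(edge_rows, columns=["source", "target"] + sorted({k for _, _, d in g.edges(data=True) for k in d})).to_csv(
        paths["edges"], sep="\t", index=False
    )
    paths["graphml"] = outdir / f"{stem}.graphml"
    nx.write_graphml(g, paths["graphml"])
    return paths


def _plain(v):
    return v.value if hasattr(v, "value") else v
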