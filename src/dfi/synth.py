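"""Synthetic data generators with planted ground truth.

Two generators emulate every input table the pipeline consumes:

* :func:`gen_chemistry` — foods, compounds (with programmatically built
  SMILES), proteins, drugs, replicated bioassay measurements, PPI edges
  and ortholog rows, with planted in-range/out-of-range food compounds,
  structural "twin" pairs (chain homologs, so Tanimoto similarity is
  guaranteed by construction) and replicate flip noise exercising the
  positive-frequency rule.
* :func:`gen_expression` — normalized expression matrices with a planted
  DE gene set per food and reference rank profiles built so that planted
  correlated drugs rank the food's up-tags near the top (inverted for
  anticorrelated drugs).

The ground truth needed to score any downstream stage is serialized next
to the tables as ``ground_truth.json``.

Defaults are small but fully exercise every rule: drug affinities are
drawn log-uniformly from 1-300 nM (well inside the pchembl > 6 window),
out-of-range compounds sit 2-3x above the weakest drug while still passing
the measurement filter, and replicate flips emit values just on the wrong
side of each endpoint's cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GroundTruth:
    seed: int
    params: dict = field(default_factory=dict)
    active_pairs: list[list[str]] = field(default_factory=list)  # [compound, protein]
    inactive_pairs: list[list[str]] = field(default_factory=list)
    food_ranking: list[str] = field(default_factory=list)  # most-interacting first
    twin_pairs: list[list[str]] = field(default_factory=list)  # [query, reference]
    exact_pairs: list[list[str]] = field(default_factory=list)
    target_adjacency: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)  # food -> {up: [...], down: [...]}
    connectivity: dict = field(default_factory=dict)  # food -> {drug: class}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


_DISEASES = ["cancer", "neurological", "cardiovascular", "metabolic", "infectious"]
_SYSTEMS = ["signal_transduction", "immune_system", "metabolism", "developmental", "transport"]
_CATEGORIES = ["drug_target", "drug_target", "drug_target", "enzyme", "transporter", "carrier"]


def _chain_smiles(length: int, head: str = "c1ccccc1", tail: str = "O") -> str:
    """Alkyl chain capped by an aromatic head and polar tail; homologs of
    the same (head, tail) differ only in chain length, which leaves the
    radius-2 Morgan environments of the interior identical."""
    return tail + "C" * length + head


_HEADS = ["c1ccccc1", "c1ccc(O)cc1", "c1ccncc1", "c1ccc(N)cc1", "c1ccc(Cl)cc1", "c1ccco1"]
_TAILS = ["O", "N", "OC(=O)", "S", ""]


def _compound_params(i: int) -> tuple[str, str, int]:
    head = _HEADS[i % len(_HEADS)]
    tail = _TAILS[(i // len(_HEADS)) % len(_TAILS)]
    length = 8 + (i % 7) + 7 * (i // (len(_HEADS) * len(_TAILS)))
    return head, tail, length


def _compound_smiles(i: int) -> str:
    head, tail, length = _compound_params(i)
    return _chain_smiles(length, head, tail)


def gen_chemistry(
    seed: int,
    outdir: str | Path,
    n_foods: int = 8,
    n_compounds: int = 40,
    n_proteins: int = 15,
    n_drugs: int = 12,
    frac_in_range: float = 0.5,
    n_replicates: int = 3,
    flip_rate: float = 0.0,
    n_twins: int = 4,
    n_exact: int = 2,
    affinity_sigma: float = 0.1,
    n_ppi_edges: int = 30,
) -> GroundTruth:
    """Generate the chemistry-side table set with planted ground truth.

    Each planted (compound, protein) pair gets ``n_replicates``
    measurements; each replicate is independently flipped to a failing
    value with probability ``flip_rate``, so the fraction of pairs
    surviving the frequency rule follows the binomial closed form. Twin
    compounds are chain homologs of reference compounds (Tanimoto 1.0 by
    construction, MW delta 14 g/mol); exact pairs reuse the reference
    structure verbatim under a food compound id.
    """
    if n_twins + n_exact > n_compounds:
        raise ValueError("more twin/exact compounds requested than compounds")
    if n_compounds < 1 or n_proteins < 1 or n_drugs < 1 or n_foods < 1:
        raise ValueError("all entity counts must be positive")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    protein_rows = [
        {
            "protein_id": pid,
            "name": f"protein-{i}",
            "category": _CATEGORIES[i % len(_CATEGORIES)],
            "disease_classes": _DISEASES[i % len(_DISEASES)],
            "biological_system": _SYSTEMS[i % len(_SYSTEMS)],
            "species": "human",
        }
        for i, pid in enumerate(proteins)
    ]

    # drug compounds + drugs, each drug targeting 1-3 proteins
    drug_compounds = [f"DC{i:03d}" for i in range(n_drugs)]
    drugs = [f"DRUG{i:03d}" for i in range(n_drugs)]
    drug_rows, drug_measurements = [], []
    drug_affinity: dict[str, list[float]] = {p: [] for p in proteins}
    for i, (did, dcid) in enumerate(zip(drugs, drug_compounds)):
        n_links = 1 + int(rng.integers(0, 3))
        linked = rng.choice(n_proteins, size=min(n_links, n_proteins), replace=False)
        for j in linked:
            pid = proteins[j]
            role = protein_rows[j]["category"]
            drug_rows.append(
                {
                    "drug_id": did,
                    "compound_id": dcid,
                    "protein_id": pid,
                    "role": role,
                    "disease_classes": protein_rows[j]["disease_classes"],
                }
            )
            aff = float(10 ** rng.uniform(0, np.log10(300)))  # 1-300 nM
            drug_affinity[pid].append(aff)
            drug_measurements.append((dcid, pid, "IC50", aff))

    # food compounds: planted active (in drug range) or inactive (above it)
    food_compounds = [f"FC{i:03d}" for i in range(n_compounds)]
    gt = GroundTruth(
        seed=seed,
        params={
            "n_foods": n_foods,
            "n_compounds": n_compounds,
            "n_proteins": n_proteins,
            "n_drugs": n_drugs,
            "frac_in_range": frac_in_range,
            "n_replicates": n_replicates,
            "flip_rate": flip_rate,
            "affinity_sigma": affinity_sigma,
        },
    )
    targeted = [p for p in proteins if drug_affinity[p]]
    food_measurements = []
    for i, cid in enumerate(food_compounds):
        pid = targeted[int(rng.integers(0, len(targeted)))]
        hi = max(drug_affinity[pid])
        in_range = rng.random() < frac_in_range
        if in_range:
            # comfortably inside the drug range so replicate noise cannot
            # push the summary affinity across the range boundary
            aff = float(10 ** rng.uniform(min(0.0, np.log10(hi / 2)), max(0.0, np.log10(hi / 2))))
            gt.active_pairs.append([cid, pid])
        else:
            # above the weakest drug but still passing pchembl > 6 (value < 1000 nM)
            aff = float(min(hi * rng.uniform(2.0, 3.0), 990.0))
            gt.inactive_pairs.append([cid, pid])
        for _ in range(n_replicates):
            if rng.random() < flip_rate:
                bad = float(10 ** rng.uniform(np.log10(2000), np.log10(50000)))
                food_measurements.append((cid, pid, "IC50", bad))
            else:
                noisy = float(aff * 10 ** rng.normal(0, affinity_sigma))
                food_measurements.append((cid, pid, "IC50", noisy))

    # structures: twins are chain homologs of drug compounds, exacts reuse them
    smiles: dict[str, str] = {}
    for i, dcid in enumerate(drug_compounds):
        smiles[dcid] = _compound_smiles(i)
    for i, cid in enumerate(food_compounds):
        smiles[cid] = _compound_smiles(n_drugs + i)
    for k in range(n_twins):
        q, ref = food_compounds[k], drug_compounds[k % n_drugs]
        head, tail, length = _compound_params(k % n_drugs)
        smiles[q] = _chain_smiles(length + 1, head, tail)  # chain homolog of ref
        gt.twin_pairs.append([q, ref])
    for k in range(n_exact):
        q, ref = food_compounds[n_twins + k], drug_compounds[(n_twins + k) % n_drugs]
        smiles[q] = smiles[ref]
        gt.exact_pairs.append([q, ref])

    compound_rows = [
        {"compound_id": c, "smiles": smiles[c], "mw": "", "names": "", "origin": "drug"}
        for c in drug_compounds
    ] + [
        {"compound_id": c, "smiles": smiles[c], "mw": "", "names": "", "origin": "food"}
        for c in food_compounds
    ]

    # foods: food F000 deliberately gets the compounds covering the most
    # proteins (the planted top-ranking food); others get random subsets
    per_compound_protein = {cid: pid for cid, pid in gt.active_pairs}
    coverage_order = sorted(
        food_compounds,
        key=lambda c: (c not in per_compound_protein, c),
    )
    food_rows = []
    top_share = coverage_order[: max(3, n_compounds // 3)]
    for cid in top_share:
        food_rows.append({"food_id": "F000", "compound_id": cid})
    for cid in food_compounds:
        fid = f"F{1 + int(rng.integers(0, n_foods - 1)):03d}" if n_foods > 1 else "F000"
        food_rows.append({"food_id": fid, "compound_id": cid})
    food_rows = pd.DataFrame(food_rows).drop_duplicates().to_dict("records")

    measurement_rows = [
        {
            "compound_id": cid,
            "protein_id": pid,
            "endpoint": ep,
            "value": repr(val),
            "units": "nM",
            "pchembl": "",
        }
        for cid, pid, ep, val in drug_measurements + food_measurements
    ]

    # PPI edges among proteins, scores straddling the 400 cutoff
    ppi_rows = []
    for _ in range(n_ppi_edges):
        a, b = rng.choice(n_proteins, size=2, replace=False)
        ppi_rows.append(
            {
                "protein_a": proteins[a],
                "protein_b": proteins[b],
                "score": int(rng.integers(100, 1000)),
                "species": "human",
            }
        )

    ortho_rows = [
        {"source_id": f"R{i:04d}", "source_species": "rat", "human_id": proteins[i % n_proteins]}
        for i in range(5)
    ]

    pd.DataFrame(compound_rows).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame(food_rows).to_csv(outdir / "foods.tsv", sep="\t", index=False)
    pd.DataFrame(protein_rows).to_csv(outdir / "proteins.tsv", sep="\t", index=False)
    pd.DataFrame(measurement_rows).to_csv(outdir / "measurements.tsv", sep="\t", index=False)
    pd.DataFrame(drug_rows).to_csv(outdir / "drugs.tsv", sep="\t", index=False)
    pd.DataFrame(ppi_rows).to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    pd.DataFrame(ortho_rows).to_csv(outdir / "orthologs.tsv", sep="\t", index=False)

    # realized food ranking by planted coverage: distinct proteins first,
    # then distinct active compounds, then food id (the profile sort order)
    cover: dict[str, set[str]] = {}
    n_active: dict[str, set[str]] = {}
    for row in food_rows:
        cid = row["compound_id"]
        if cid in per_compound_protein:
            cover.setdefault(row["food_id"], set()).add(per_compound_protein[cid])
            n_active.setdefault(row["food_id"], set()).add(cid)
    gt.food_ranking = sorted(cover, key=lambda f: (-len(cover[f]), -len(n_active[f]), f))
    gt.to_json(outdir / "ground_truth.json")
    return gt


def gen_expression(
    seed: int,
    outdir: str | Path,
    n_genes: int = 1000,
    n_samples: int = 10,
    n_reference_instances: int = 3,
    de_fraction: float = 0.05,
    effect: float = 3.0,
    sigma: float = 1.0,
    foods: list[str] | None = None,
    drug_plan: dict[str, str] | None = None,
    rank_noise: float = 0.02,
) -> GroundTruth:
    """Generate expression matrices and reference rank profiles.

    Per food: a genes x samples matrix (half treatment, half control),
    baseline N(8, sigma), with ``de_fraction`` of genes shifted by
    ``effect * sigma`` (half up, half down) in the treatment group.
    ``drug_plan`` maps reference drug ids to 'correlated',
    'anticorrelated' or 'null' (the same plan applies to every food).
    Correlated instances rank the food's planted up genes at the top and
    down genes at the bottom, with a ``rank_noise`` fraction of random
    pairwise displacement; anticorrelated instances invert the profile;
    null instances are uniform random permutations.
    """
    if n_samples < 4:
        raise ValueError("need >= 4 samples (2 per group)")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    foods = foods or ["FOODX"]
    drug_plan = drug_plan or {"DRUGC": "correlated", "DRUGA": "anticorrelated", "DRUGN": "null"}

    genes = [f"g{i:05d}" for i in range(n_genes)]
    probes = [f"p{i:05d}" for i in range(n_genes)]
    id_map_rows = [{"gene_id": g, "probe_id": p} for g, p in zip(genes, probes)]
    gt = GroundTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_samples": n_samples,
            "de_fraction": de_fraction,
            "effect": effect,
            "sigma": sigma,
            "n_reference_instances": n_reference_instances,
            "rank_noise": rank_noise,
        },
    )

    n_de = int(round(de_fraction * n_genes))
    n_t = n_samples // 2
    n_c = n_samples - n_t
    ref_cols: dict[str, np.ndarray] = {}
    for food in foods:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        up_idx = de_idx[: n_de // 2]
        down_idx = de_idx[n_de // 2 :]
        X = rng.normal(8.0, sigma, size=(n_genes, n_samples))
        X[up_idx, :n_t] += effect * sigma
        X[down_idx, :n_t] -= effect * sigma
        samples = [f"{food}_T{j}" for j in range(n_t)] + [f"{food}_C{j}" for j in range(n_c)]
        mat = pd.DataFrame(X, index=genes, columns=samples)
        mat.insert(0, "gene_id", genes)
        mat.to_csv(outdir / f"expression_{food}.tsv", sep="\t", index=False, float_format="%.5f")
        groups = pd.DataFrame(
            {"sample": samples, "group": ["treatment"] * n_t + ["control"] * n_c}
        )
        groups.to_csv(outdir / f"groups_{food}.tsv", sep="\t", index=False)
        gt.de_genes[food] = {
            "up": sorted(genes[i] for i in up_idx),
            "down": sorted(genes[i] for i in down_idx),
        }
        gt.connectivity[food] = dict(drug_plan)

        up_set = set(up_idx.tolist())
        down_set = set(down_idx.tolist())
        rest = [i for i in range(n_genes) if i not in up_set and i not in down_set]
        for drug, cls in drug_plan.items():
            for inst in range(n_reference_instances):
                if cls == "null":
                    order = rng.permutation(n_genes)
                else:
                    top = list(rng.permutation(sorted(up_set)))
                    bottom = list(rng.permutation(sorted(down_set)))
                    middle = list(rng.permutation(rest))
                    order = np.array(top + middle + bottom)
                    if cls == "anticorrelated":
                        order = order[::-1]
                    n_swap = int(rank_noise * n_genes)
                    for _ in range(n_swap):
                        a, b = rng.integers(0, n_genes, size=2)
                        order[a], order[b] = order[b], order[a]
                ranks = np.empty(n_genes, dtype=int)
                ranks[order] = np.arange(1, n_genes + 1)
                ref_cols[f"{food}|{drug}|{inst}"] = ranks

    ref = pd.DataFrame(ref_cols, index=probes)
    ref.insert(0, "probe_id", probes)
    ref.to_csv(outdir / "reference_ranks.tsv", sep="\t", index=False)
    pd.DataFrame(id_map_rows).to_csv(outdir / "id_map.tsv", sep="\t", index=False)
    gt.to_json(outdir / "ground_truth.json")
    return gt
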