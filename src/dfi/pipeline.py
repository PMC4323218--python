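"""End-to-end orchestration: load -> filter -> classify -> networks (+ expression).

Single-process and deterministic: all randomness flows from the one seed
in :class:`PipelineConfig` (stage-local generators are spawned from it),
and a run manifest records the config, input digests and per-stage row
counts so a rerun with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioactivity, chemspace, networks
from .config import PipelineConfig
from .io import Registry, load_tables
from .records import Endpoint, ProteinCategory

logger = logging.getLogger("dfi")

__version__ = "0.1.0"

CHEMISTRY_TABLES = ("compounds", "foods", "proteins", "measurements", "drugs", "ppi", "orthologs")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def discover_inputs(indir: str | Path) -> dict[str, Path]:
    indir = Path(indir)
    return {name: indir / f"{name}.tsv" for name in CHEMISTRY_TABLES if (indir / f"{name}.tsv").exists()}


class ChemistryResult:
    """All chemistry-arm artifacts of one run, kept for downstream stages."""

    def __init__(self, registry: Registry, config: PipelineConfig):
        self.registry = registry
        self.config = config
        self.flagged = bioactivity.filter_measurements(registry.measurements, config)
        interactions = bioactivity.aggregate_interactions(self.flagged, config)
        drug_cids = registry.drug_compound_ids()
        self.drug_interactions = [i for i in interactions if i.compound_id in drug_cids]
        self.food_interactions = [i for i in interactions if i.compound_id not in drug_cids]
        self.drug_index = bioactivity.build_drug_affinity_index(
            self.drug_interactions, registry.drugs, registry.proteins, self.flagged
        )
        self.calls = bioactivity.classify_all(
            self.food_interactions, self.drug_index, registry.proteins, config
        )
        self.profiles = bioactivity.food_protein_profile(
            registry.foods, self.calls, registry.proteins
        )
        # endpoint provenance for tripartite annotation display
        self.endpoint_of: dict[tuple[str, str], Endpoint] = {}
        for f in self.flagged:
            m = f.measurement
            if f.positive:
                self.endpoint_of.setdefault((m.compound_id, m.protein_id), m.endpoint)


def run_all(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage the inputs support; returns the manifest dict."""
    config = config or PipelineConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = discover_inputs(input_dir)
    reg = load_tables(paths, config)
    chem = ChemistryResult(reg, config)

    rows = [
        {
            "compound_id": i.compound_id,
            "protein_id": i.protein_id,
            "positive_frequency": i.positive_frequency,
            "n_measurements": i.n_measurements,
            "representative_affinity_nM": i.representative_affinity,
            "endpoints": "|".join(sorted(e.value for e in i.endpoint_mix)),
        }
        for i in chem.food_interactions + chem.drug_interactions
    ]
    pd.DataFrame(rows).to_csv(output_dir / "interactions.tsv", sep="\t", index=False)

    rows = [
        {
            "compound_id": c.compound_id,
            "protein_id": c.protein_id,
            "is_active": c.is_active,
            "basis": c.basis.value,
            "drug_range_min_nM": c.drug_range[0] if c.drug_range else "",
            "drug_range_max_nM": c.drug_range[1] if c.drug_range else "",
            "category_mean_nM": c.category_mean if c.category_mean is not None else "",
            "representative_affinity_nM": c.representative_affinity
            if c.representative_affinity is not None
            else "",
        }
        for c in chem.calls
    ]
    pd.DataFrame(rows).to_csv(output_dir / "calls.tsv", sep="\t", index=False)

    fg = networks.build_food_network(chem.calls, reg.foods)
    networks.export_network(fg, output_dir, "food_network")

    disease_classes = sorted({d for p in reg.proteins.values() for d in p.disease_classes})
    n_target_edges = 0
    for dc in disease_classes:
        tg = networks.build_target_network(
            chem.calls, reg.drugs, reg.proteins, reg.foods, dc, config
        )
        if tg.number_of_nodes():
            networks.export_network(tg, output_dir, f"target_network_{dc}")
            n_target_edges += tg.number_of_edges()

    ann_rows = []
    for pid, prot in sorted(reg.proteins.items()):
        ctx = "pd" if prot.category is ProteinCategory.DRUG_TARGET else "pk"
        ann = networks.annotate_strongest_binder(
            pid, ctx, chem.calls, reg.foods, reg.drugs, reg.proteins, chem.endpoint_of
        )
        if ann is not None:
            ann_rows.append(
                {
                    "protein_id": pid,
                    "context": ctx,
                    "best_phytochemical": ann.best_phytochemical,
                    "best_affinity_nM": ann.best_affinity,
                    "endpoint": ann.endpoint.value if ann.endpoint else "",
                    "foods": "|".join(sorted(ann.foods)),
                    "drugs": "|".join(sorted(ann.drugs)),
                }
            )
    pd.DataFrame(ann_rows).to_csv(output_dir / "tripartite_annotations.tsv", sep="\t", index=False)

    manifest = {
        "tool_version": __version__,
        "config": asdict(config),
        "inputs": {k: _digest(v) for k, v in sorted(paths.items())},
        "seed": config.seed,
        "counts": {
            "compounds": len(reg.compounds),
            "foods": len(reg.foods),
            "proteins": len(reg.proteins),
            "measurements": len(reg.measurements),
            "drugs": len(reg.drugs),
            "confident_interactions": len(chem.food_interactions) + len(chem.drug_interactions),
            "active_calls": sum(c.is_active for c in chem.calls),
            "food_network_nodes": fg.number_of_nodes(),
            "food_network_edges": fg.number_of_edges(),
            "target_network_edges": n_target_edges,
            "tripartite_annotations": len(ann_rows),
        },
    }
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %s", manifest["counts"])
    return manifest
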