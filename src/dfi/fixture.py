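"""Curated case-study fixture.

A small table set transcribing the published case studies of drug-food
interference at the protein level: seven phytochemical-protein
interactions with their printed binding affinities, the foods containing
each phytochemical and the drugs sharing each protein. Aromatase appears
twice — once as a drug target (pharmacodynamics context) and once as a
metabolic enzyme (pharmacokinetics context) — under two protein records,
mirroring how target and enzyme roles are separate entries in drug
databases; the naringenin affinity differs between the two contexts
(2.9 nM vs 1000 nM).

Drug anchor affinities are synthetic: the sources print only the
phytochemical affinities, so each protein's drugs are given plausible
values whose range contains the phytochemical (the case studies describe
the phytochemicals as comparable to or stronger than the drugs).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

# (compound, smiles, protein, protein name, category, disease, endpoint, affinity nM)
CASE_STUDIES = [
    ("naringenin", "O=C1C[C@H](c2ccc(O)cc2)Oc2cc(O)cc(O)c21", "P11511", "aromatase",
     "drug_target", "cancer", "IC50", 2.9),
    ("kaempferol", "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "P00533",
     "epidermal growth factor receptor", "drug_target", "cancer", "IC50", 3.0),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12", "P08908", "5-hydroxytryptamine receptor",
     "drug_target", "neurological", "Ki", 1.1),
    ("aporphine", "CN1CCc2cccc3c2C1Cc1ccccc1-3", "P14416", "D(2) dopamine receptor",
     "drug_target", "neurological", "Ki", 527.0),
    ("p-hydroxybenzoic-acid", "O=C(O)c1ccc(O)cc1", "P00918", "carbonic anhydrase",
     "drug_target", "cardiovascular", "Ki", 920.0),
    ("resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1", "P16083",
     "ribosyl-dihydronicotinamide dehydrogenase", "enzyme", "metabolic", "IC50", 450.0),
    ("naringenin", "O=C1C[C@H](c2ccc(O)cc2)Oc2cc(O)cc(O)c21", "P11511-E",
     "aromatase", "enzyme", "cancer", "IC50", 1000.0),
]

FOOD_MEMBERSHIP = {
    "naringenin": ["licorice", "beansprout", "maize", "sugar-pea", "guava"],
    "kaempferol": ["lychee", "onion", "strawberry"],
    "serotonin": ["sunflower", "potato", "tomato"],
    "aporphine": ["poppy-seed"],
    "p-hydroxybenzoic-acid": ["coconut", "currant", "sprouted-lentil", "swede"],
    "resveratrol": ["grape"],
}

# drug, protein, role, disease, synthetic anchor affinity (nM)
DRUG_LINKS = [
    ("Anastrozole", "P11511", "drug_target", "cancer", 15.0),
    ("Testolactone", "P11511", "drug_target", "cancer", 40.0),
    ("Exemestane", "P11511", "drug_target", "cancer", 20.0),
    ("Letrozole", "P11511", "drug_target", "cancer", 11.0),
    ("Aminoglutethiumide", "P11511", "drug_target", "cancer", 60.0),
    ("Lapatinib", "P00533", "drug_target", "cancer", 10.0),
    ("Gefitinib", "P00533", "drug_target", "cancer", 33.0),
    ("Vandetanib", "P00533", "drug_target", "cancer", 40.0),
    ("Erlotinib", "P00533", "drug_target", "cancer", 20.0),
    ("Loxapine", "P08908", "drug_target", "neurological", 5.0),
    ("Buspirone", "P08908", "drug_target", "neurological", 20.0),
    ("Ofremoxipride", "P14416", "drug_target", "neurological", 300.0),
    ("Sulpiride", "P14416", "drug_target", "neurological", 600.0),
    ("Trichlormethiazide", "P00918", "drug_target", "cardiovascular", 950.0),
    ("Primaquine", "P16083", "enzyme", "infectious", 900.0),
    ("Anastrozole-E", "P11511-E", "enzyme", "cancer", 1200.0),
    ("Letrozole-E", "P11511-E", "enzyme", "cancer", 1100.0),
    ("Exemestane-E", "P11511-E", "enzyme", "cancer", 1300.0),
    ("Aminoglutethimide-E", "P11511-E", "enzyme", "cancer", 1050.0),
]

# Assay-level pchembl flags for rows at or past the 1000 nM boundary of the
# pchembl > 6 positivity rule: the enzyme-context aromatase interactions sit
# exactly at (or above) that boundary, as in source bioassay records where
# the standardized pchembl and the displayed affinity disagree by rounding.
EXPLICIT_PCHEMBL = {
    ("naringenin", "P11511-E"): 6.02,
    ("Anastrozole-E-ingredient", "P11511-E"): 6.1,
    ("Letrozole-E-ingredient", "P11511-E"): 6.1,
    ("Exemestane-E-ingredient", "P11511-E"): 6.1,
    ("Aminoglutethimide-E-ingredient", "P11511-E"): 6.1,
}

_DRUG_SMILES = "CCN(CC)C(=O)Cc1ccccc1"  # shared placeholder drug-ingredient structure


def in_paper_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the curated fixture tables to ``outdir``; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    compound_rows = {}
    for cid, smi, *_ in CASE_STUDIES:
        compound_rows[cid] = {
            "compound_id": cid, "smiles": smi, "mw": "", "names": cid, "origin": "food",
        }
    for drug, *_ in DRUG_LINKS:
        cid = f"{drug}-ingredient"
        compound_rows[cid] = {
            "compound_id": cid, "smiles": _DRUG_SMILES, "mw": "", "names": drug, "origin": "drug",
        }

    protein_rows = {}
    for _, _, pid, name, cat, disease, _, _ in CASE_STUDIES:
        protein_rows[pid] = {
            "protein_id": pid,
            "name": name,
            "category": cat,
            "disease_classes": disease,
            "biological_system": "signal_transduction" if cat == "drug_target" else "metabolism",
            "species": "human",
        }

    food_rows = [
        {"food_id": fid, "compound_id": cid}
        for cid, fids in FOOD_MEMBERSHIP.items()
        for fid in fids
    ]

    measurement_rows = [
        {
            "compound_id": cid, "protein_id": pid, "endpoint": ep,
            "value": val, "units": "nM",
            "pchembl": EXPLICIT_PCHEMBL.get((cid, pid), ""),
        }
        for cid, _, pid, _, _, _, ep, val in CASE_STUDIES
    ] + [
        {
            "compound_id": f"{drug}-ingredient", "protein_id": pid, "endpoint": "IC50",
            "value": aff, "units": "nM",
            "pchembl": EXPLICIT_PCHEMBL.get((f"{drug}-ingredient", pid), ""),
        }
        for drug, pid, _, _, aff in DRUG_LINKS
    ]

    drug_rows = [
        {
            "drug_id": drug, "compound_id": f"{drug}-ingredient", "protein_id": pid,
            "role": role, "disease_classes": disease,
        }
        for drug, pid, role, disease, _ in DRUG_LINKS
    ]

    paths = {}
    for name, rows in [
        ("compounds", list(compound_rows.values())),
        ("proteins", list(protein_rows.values())),
        ("foods", food_rows),
        ("measurements", measurement_rows),
        ("drugs", drug_rows),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        pd.DataFrame(rows).to_csv(paths[name], sep="\t", index=False)
    return paths
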