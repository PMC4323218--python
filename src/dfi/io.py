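"""Table I/O: loading, validation, unit normalization and round-trip writing.

The canonical dialect is TSV with a header row. One registry object holds
every loaded table; cross-references are validated at load time and the
load report records, for every rejected row, a machine-readable reason code.

Schemas
-------
compounds.tsv     compound_id  smiles  mw  names  origin
foods.tsv         food_id  compound_id                     (one row per pair)
proteins.tsv      protein_id  name  category  disease_classes  biological_system  species
measurements.tsv  compound_id  protein_id  endpoint  value  units  pchembl
drugs.tsv         drug_id  compound_id  protein_id  role  disease_classes
ppi.tsv           protein_a  protein_b  score  species
orthologs.tsv     source_id  source_species  human_id

Multi-valued cells (names, disease_classes) are '|'-separated; empty cells
are allowed where the field is optional.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .records import (
    AFFINITY_ENDPOINTS,
    CompoundRecord,
    DrugRecord,
    Endpoint,
    FoodRecord,
    MeasurementRecord,
    Origin,
    ProteinCategory,
    ProteinRecord,
    Species,
)

logger = logging.getLogger("dfi")

#: nM per unit, for affinity/potency unit normalization
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9, "pm": 1e-3}


@dataclass
class RejectedRow:
    table: str
    row: int  # 0-based data-row index
    reason: str  # machine-readable code
    detail: str = ""


@dataclass
class LoadReport:
    counts: dict[str, int] = field(default_factory=dict)
    rejects: list[RejectedRow] = field(default_factory=list)

    def log(self) -> None:
        for table, n in sorted(self.counts.items()):
            logger.info("loaded %s: %d records", table, n)
        for r in self.rejects:
            logger.warning("rejected %s row %d: %s (%s)", r.table, r.row, r.reason, r.detail)


@dataclass
class Registry:
    """In-memory view of every input table, cross-validated."""

    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    foods: dict[str, FoodRecord] = field(default_factory=dict)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    measurements: list[MeasurementRecord] = field(default_factory=list)
    drugs: dict[str, DrugRecord] = field(default_factory=dict)
    ppi: pd.DataFrame | None = None
    orthologs: pd.DataFrame | None = None
    report: LoadReport = field(default_factory=LoadReport)

    def food_compound_ids(self) -> set[str]:
        out: set[str] = set()
        for f in self.foods.values():
            out |= f.compound_ids
        return out

    def drug_compound_ids(self) -> set[str]:
        return {d.compound_id for d in self.drugs.values()}


class ReferentialIntegrityError(ValueError):
    """A foreign identifier does not resolve in its registry."""


def _split_multi(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return ()
    return tuple(s for s in str(cell).split("|") if s)


def _opt_float(cell) -> float | None:
    if cell is None or cell == "":
        return None
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def normalize_value(endpoint: Endpoint, value: float | None, units: str) -> float | None:
    """Normalize a measurement value to the pipeline scale (nM or percent)."""
    if value is None:
        return None
    u = units.strip().lower()
    if endpoint is Endpoint.INHIBITION:
        return value  # percent
    if u in ("", "nan"):
        # potency defaults to uM (its conventional input unit), affinities to nM
        return value * 1e3 if endpoint is Endpoint.POTENCY else value
    if u in ("%", "percent"):
        return value
    if u in _UNIT_TO_NM:
        return value * _UNIT_TO_NM[u]
    return None  # unknown unit -> caller rejects the row


def load_tables(paths: dict[str, str | Path], config: PipelineConfig | None = None) -> Registry:
    """Load all provided tables into a cross-validated :class:`Registry`.

    ``paths`` maps table names ('compounds', 'foods', 'proteins',
    'measurements', 'drugs', 'ppi', 'orthologs') to file paths; absent
    tables load as empty. Rows failing row-local validation are rejected
    with a reason code; unresolvable foreign identifiers are a hard error.
    """
    config = config or PipelineConfig()
    reg = Registry()
    rep = reg.report

    if "compounds" in paths:
        df = _read_tsv(Path(paths["compounds"]), ["compound_id"])
        for i, row in df.iterrows():
            cid = row["compound_id"]
            if not cid:
                rep.rejects.append(RejectedRow("compounds", i, "missing_id"))
                continue
            if cid in reg.compounds:
                rep.rejects.append(RejectedRow("compounds", i, "duplicate_id", cid))
                continue
            origin_s = row.get("origin", "") or "food"
            try:
                origin = Origin(origin_s)
            except ValueError:
                rep.rejects.append(RejectedRow("compounds", i, "unknown_origin", origin_s))
                continue
            reg.compounds[cid] = CompoundRecord(
                compound_id=cid,
                smiles=row.get("smiles") or None,
                mw=_opt_float(row.get("mw")),
                names=_split_multi(row.get("names")),
                origin=origin,
            )
    rep.counts["compounds"] = len(reg.compounds)

    if "proteins" in paths:
        df = _read_tsv(Path(paths["proteins"]), ["protein_id", "category"])
        for i, row in df.iterrows():
            pid = row["protein_id"]
            if pid in reg.proteins:
                rep.rejects.append(RejectedRow("proteins", i, "duplicate_id", pid))
                continue
            try:
                cat = ProteinCategory(row["category"])
            except ValueError:
                rep.rejects.append(RejectedRow("proteins", i, "unknown_category", row["category"]))
                continue
            sp_s = row.get("species", "") or "human"
            try:
                sp = Species(sp_s)
            except ValueError:
                rep.rejects.append(RejectedRow("proteins", i, "unknown_species", sp_s))
                continue
            reg.proteins[pid] = ProteinRecord(
                protein_id=pid,
                category=cat,
                disease_classes=frozenset(_split_multi(row.get("disease_classes"))),
                biological_system=row.get("biological_system", "") or "",
                species=sp,
                name=row.get("name", "") or "",
            )
    rep.counts["proteins"] = len(reg.proteins)

    offenders: list[str] = []

    if "foods" in paths:
        df = _read_tsv(Path(paths["foods"]), ["food_id", "compound_id"])
        members: dict[str, set[str]] = {}
        for i, row in df.iterrows():
            fid, cid = row["food_id"], row["compound_id"]
            if cid not in reg.compounds:
                offenders.append(f"foods row {i}: compound {cid!r}")
                continue
            members.setdefault(fid, set()).add(cid)
        reg.foods = {fid: FoodRecord(fid, frozenset(c)) for fid, c in members.items()}
    rep.counts["foods"] = len(reg.foods)

    if "measurements" in paths:
        df = _read_tsv(
            Path(paths["measurements"]), ["compound_id", "protein_id", "endpoint", "value"]
        )
        for i, row in df.iterrows():
            cid, pid = row["compound_id"], row["protein_id"]
            if cid not in reg.compounds:
                offenders.append(f"measurements row {i}: compound {cid!r}")
                continue
            if pid not in reg.proteins:
                offenders.append(f"measurements row {i}: protein {pid!r}")
                continue
            try:
                ep = Endpoint(row["endpoint"])
            except ValueError:
                rep.rejects.append(
                    RejectedRow("measurements", i, "unknown_endpoint", row["endpoint"])
                )
                continue
            raw = _opt_float(row.get("value"))
            value = normalize_value(ep, raw, row.get("units", ""))
            if raw is not None and value is None:
                rep.rejects.append(
                    RejectedRow("measurements", i, "unknown_units", row.get("units", ""))
                )
                continue
            if value is not None:
                if ep is Endpoint.INHIBITION and not (0 <= value <= 100):
                    rep.rejects.append(
                        RejectedRow("measurements", i, "inhibition_out_of_range", str(value))
                    )
                    continue
                if ep is not Endpoint.INHIBITION and value <= 0:
                    rep.rejects.append(
                        RejectedRow("measurements", i, "nonpositive_value", str(value))
                    )
                    continue
            m = MeasurementRecord(
                compound_id=cid,
                protein_id=pid,
                endpoint=ep,
                value=value,
                pchembl=_opt_float(row.get("pchembl")),
            )
            reg.measurements.append(m)
    rep.counts["measurements"] = len(reg.measurements)

    if "drugs" in paths:
        df = _read_tsv(Path(paths["drugs"]), ["drug_id", "compound_id", "protein_id", "role"])
        links: dict[str, dict] = {}
        for i, row in df.iterrows():
            did = row["drug_id"]
            cid, pid = row["compound_id"], row["protein_id"]
            if cid not in reg.compounds:
                offenders.append(f"drugs row {i}: compound {cid!r}")
                continue
            if pid not in reg.proteins:
                offenders.append(f"drugs row {i}: protein {pid!r}")
                continue
            try:
                role = ProteinCategory(row["role"])
            except ValueError:
                rep.rejects.append(RejectedRow("drugs", i, "unknown_role", row["role"]))
                continue
            if role is not reg.proteins[pid].category:
                rep.rejects.append(
                    RejectedRow(
                        "drugs", i, "role_category_mismatch", f"{pid}: {role.value}"
                    )
                )
                continue
            d = links.setdefault(
                did, {"compound_id": cid, "links": [], "diseases": set()}
            )
            d["links"].append((pid, role))
            d["diseases"] |= set(_split_multi(row.get("disease_classes")))
        reg.drugs = {
            did: DrugRecord(
                drug_id=did,
                compound_id=d["compound_id"],
                protein_links=tuple(sorted(set(d["links"]), key=lambda t: (t[0], t[1].value))),
                disease_classes=frozenset(d["diseases"]),
            )
            for did, d in links.items()
        }
    rep.counts["drugs"] = len(reg.drugs)

    if "ppi" in paths:
        df = _read_tsv(Path(paths["ppi"]), ["protein_a", "protein_b", "score"])
        df["score"] = df["score"].astype(float)
        if "species" not in df.columns:
            df["species"] = "human"
        reg.ppi = df
        rep.counts["ppi"] = len(df)

    if "orthologs" in paths:
        df = _read_tsv(Path(paths["orthologs"]), ["source_id", "source_species", "human_id"])
        reg.orthologs = df
        rep.counts["orthologs"] = len(df)

    if offenders:
        raise ReferentialIntegrityError(
            "unresolvable foreign identifiers:\n  " + "\n  ".join(offenders)
        )
    rep.log()
    return reg


def write_tables(reg: Registry, outdir: str | Path) -> dict[str, Path]:
    """Write a registry back to canonical TSVs; inverse of :func:`load_tables`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [
        {
            "compound_id": c.compound_id,
            "smiles": c.smiles or "",
            "mw": "" if c.mw is None else repr(c.mw),
            "names": "|".join(c.names),
            "origin": c.origin.value,
        }
        for c in sorted(reg.compounds.values(), key=lambda c: c.compound_id)
    ]
    paths["compounds"] = outdir / "compounds.tsv"
    pd.DataFrame(
        rows, columns=["compound_id", "smiles", "mw", "names", "origin"]
    ).to_csv(paths["compounds"], sep="\t", index=False)

    rows = [
        {"food_id": f.food_id, "compound_id": cid}
        for f in sorted(reg.foods.values(), key=lambda f: f.food_id)
        for cid in sorted(f.compound_ids)
    ]
    paths["foods"] = outdir / "foods.tsv"
    pd.DataFrame(rows, columns=["food_id", "compound_id"]).to_csv(
        paths["foods"], sep="\t", index=False
    )

    rows = [
        {
            "protein_id": p.protein_id,
            "name": p.name,
            "category": p.category.value,
            "disease_classes": "|".join(sorted(p.disease_classes)),
            "biological_system": p.biological_system,
            "species": p.species.value,
        }
        for p in sorted(reg.proteins.values(), key=lambda p: p.protein_id)
    ]
    paths["proteins"] = outdir / "proteins.tsv"
    pd.DataFrame(
        rows,
        columns=["protein_id", "name", "category", "disease_classes", "biological_system", "species"],
    ).to_csv(paths["proteins"], sep="\t", index=False)

    rows = [
        {
            "compound_id": m.compound_id,
            "protein_id": m.protein_id,
            "endpoint": m.endpoint.value,
            "value": "" if m.value is None else repr(m.value),
            "units": "%" if m.endpoint is Endpoint.INHIBITION else "nM",
            "pchembl": "" if m.pchembl is None else repr(m.pchembl),
        }
        for m in reg.measurements
    ]
    paths["measurements"] = outdir / "measurements.tsv"
    pd.DataFrame(
        rows, columns=["compound_id", "protein_id", "endpoint", "value", "units", "pchembl"]
    ).to_csv(paths["measurements"], sep="\t", index=False)

    rows = [
        {
            "drug_id": d.drug_id,
            "compound_id": d.compound_id,
            "protein_id": pid,
            "role": role.value,
            "disease_classes": "|".join(sorted(d.disease_classes)),
        }
        for d in sorted(reg.drugs.values(), key=lambda d: d.drug_id)
        for pid, role in d.protein_links
    ]
    paths["drugs"] = outdir / "drugs.tsv"
    pd.DataFrame(
        rows, columns=["drug_id", "compound_id", "protein_id", "role", "disease_classes"]
    ).to_csv(paths["drugs"], sep="\t", index=False)

    if reg.ppi is not None:
        paths["ppi"] = outdir / "ppi.tsv"
        reg.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    if reg.orthologs is not None:
        paths["orthologs"] = outdir / "orthologs.tsv"
        reg.orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
    return paths
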