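"""Chemical space: descriptors, similarity matching and target transfer.

Each compound is described by a 1024-bit Morgan circular fingerprint
(radius 2) concatenated with five physicochemical descriptors — TPSA,
SlogP, MW, Lipinski H-bond acceptor and donor counts — giving a fixed
1029-column descriptor matrix. Structural similarity is the Tanimoto
coefficient over fingerprint on-bits; two compounds are similar when
TC >= 0.85 and their molecular weights differ by less than 50 g/mol.
Phytochemicals inherit the confident protein interactions of reference
compounds they match (exactly or by similarity), and targets of exactly
matched compounds are further expanded through high-confidence PPI
neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem.rdMolDescriptors import CalcTPSA
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .records import (
    CompoundRecord,
    ConfidentInteraction,
    InferredLink,
    MatchKind,
    SimilarityMatch,
    Species,
)

logger = logging.getLogger("dfi")

N_FP_BITS = 1024
PHYSCHEM_COLUMNS = ["tpsa", "slogp", "mw", "hba", "hbd"]
#: total descriptor-matrix width: 1024 fingerprint bits + 5 physicochemical
N_DESCRIPTOR_COLUMNS = N_FP_BITS + len(PHYSCHEM_COLUMNS)

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_FP_BITS)


def _mol_from_smiles(smiles: str | None):
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def fingerprint_bits(mol) -> frozenset[int]:
    """On-bit positions of the radius-2 Morgan fingerprint."""
    return frozenset(_fp_generator.GetFingerprint(mol).GetOnBits())


def tanimoto(bits_a: frozenset[int], bits_b: frozenset[int]) -> float:
    """TC = |A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    union = len(bits_a | bits_b)
    if union == 0:
        return 0.0
    return len(bits_a & bits_b) / union


def canonical_structure_key(smiles: str) -> str | None:
    """Canonical-SMILES key used for exact structure matching."""
    mol = _mol_from_smiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass
class DescriptorSet:
    """Descriptor matrix plus fingerprints and structure keys by compound."""

    matrix: pd.DataFrame  # index compound_id; 1029 columns
    bits: dict[str, frozenset[int]]
    structure_key: dict[str, str]
    rejects: list[str]  # compound ids whose structure failed to parse


def compute_descriptors(compounds: list[CompoundRecord]) -> DescriptorSet:
    """Fingerprint + physicochemical descriptors for every parseable compound.

    Unparseable structures are reported in ``rejects``, never silently
    dropped. The matrix has exactly ``N_DESCRIPTOR_COLUMNS`` columns.
    """
    rows, index = [], []
    bits: dict[str, frozenset[int]] = {}
    keys: dict[str, str] = {}
    rejects: list[str] = []
    for c in compounds:
        mol = _mol_from_smiles(c.smiles)
        if mol is None:
            rejects.append(c.compound_id)
            continue
        # recanonicalize so identical structures yield bit-identical
        # descriptor rows regardless of input atom order
        key = Chem.MolToSmiles(mol)
        mol = Chem.MolFromSmiles(key)
        b = fingerprint_bits(mol)
        bits[c.compound_id] = b
        keys[c.compound_id] = key
        fp_row = np.zeros(N_FP_BITS, dtype=float)
        fp_row[list(b)] = 1.0
        phys = [
            CalcTPSA(mol),
            Crippen.MolLogP(mol),
            Descriptors.MolWt(mol),
            # Lipinski rule-of-five definitions: N+O and NH+OH counts
            float(Lipinski.NOCount(mol)),
            float(Lipinski.NHOHCount(mol)),
        ]
        rows.append(np.concatenate([fp_row, phys]))
        index.append(c.compound_id)
    columns = [f"fp_{i}" for i in range(N_FP_BITS)] + PHYSCHEM_COLUMNS
    matrix = pd.DataFrame(rows, index=index, columns=columns)
    assert matrix.shape[1] == N_DESCRIPTOR_COLUMNS
    if rejects:
        logger.warning("%d compounds had unparseable structures: %s", len(rejects), rejects[:10])
    return DescriptorSet(matrix, bits, keys, rejects)


def pca_projection(matrix: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-standardized PCA of the descriptor matrix.

    Constant columns are dropped (with a warning) before standardization;
    returns (scores, explained-variance fractions).
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 compounds")
    std = matrix.std(axis=0, ddof=1)
    keep = std > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d constant descriptor columns before PCA", n_dropped)
    X = matrix.loc[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    k = min(k, Z.shape[1], len(Z) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), pca.explained_variance_ratio_


def match_compounds(
    queries: DescriptorSet,
    references: DescriptorSet,
    config: PipelineConfig,
) -> list[SimilarityMatch]:
    """Match query compounds to references, exact structure first.

    A query with an exact structure match (canonical-structure key
    equality) yields exact matches only; otherwise every reference with
    TC >= tc_min and |dMW| < mw_window is returned, sorted by TC descending
    with lexical reference-id tie-break.
    """
    ref_by_key: dict[str, list[str]] = {}
    for rid, key in references.structure_key.items():
        ref_by_key.setdefault(key, []).append(rid)

    out: list[SimilarityMatch] = []
    for qid in queries.matrix.index:
        qkey = queries.structure_key[qid]
        exact = sorted(ref_by_key.get(qkey, ()))
        if exact:
            for rid in exact:
                out.append(SimilarityMatch(qid, rid, 1.0, 0.0, MatchKind.EXACT_STRUCTURE))
            continue
        qbits = queries.bits[qid]
        qmw = queries.matrix.at[qid, "mw"]
        hits = []
        for rid in references.matrix.index:
            tc = tanimoto(qbits, references.bits[rid])
            if tc < config.tc_min:
                continue
            dmw = abs(qmw - references.matrix.at[rid, "mw"])
            if dmw >= config.mw_window:
                continue
            hits.append(SimilarityMatch(qid, rid, tc, float(dmw), MatchKind.SIMILAR))
        hits.sort(key=lambda h: (-h.tanimoto, h.reference_compound_id))
        out.extend(hits)
    return out


def transfer_targets(
    matches: list[SimilarityMatch],
    reference_interactions: list[ConfidentInteraction],
) -> list[InferredLink]:
    """Transfer confident reference-compound targets to matched queries.

    Each inferred link records the reference compound and match kind it
    came from, so provenance is lossless.
    """
    by_ref: dict[str, list[ConfidentInteraction]] = {}
    for it in reference_interactions:
        by_ref.setdefault(it.compound_id, []).append(it)
    out: list[InferredLink] = []
    for m in matches:
        for it in by_ref.get(m.reference_compound_id, ()):
            out.append(
                InferredLink(
                    compound_id=m.query_compound_id,
                    protein_id=it.protein_id,
                    via_reference=m.reference_compound_id,
                    match_kind=m.match_kind,
                )
            )
    return out


def expand_via_ppi(
    links: list[InferredLink],
    ppi: pd.DataFrame,
    config: PipelineConfig,
) -> list[InferredLink]:
    """Add first-degree PPI partners of exactly matched compounds' targets.

    Only seeds that came from exact structure matches are expanded;
    partners require edge score strictly above ``ppi_score_min`` and a
    human/rat/mouse edge. Added links are flagged indirect and keep the
    seed protein in their provenance.
    """
    allowed = {s.value for s in Species}
    neighbors: dict[str, set[str]] = {}
    for _, row in ppi.iterrows():
        if float(row["score"]) <= config.ppi_score_min:
            continue
        if str(row.get("species", "human")) not in allowed:
            continue
        a, b = str(row["protein_a"]), str(row["protein_b"])
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    out = list(links)
    seen = {(l.compound_id, l.protein_id) for l in links}
    for link in links:
        if link.match_kind is not MatchKind.EXACT_STRUCTURE or link.indirect:
            continue
        for partner in sorted(neighbors.get(link.protein_id, ())):
            key = (link.compound_id, partner)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                InferredLink(
                    compound_id=link.compound_id,
                    protein_id=partner,
                    via_reference=link.via_reference,
                    match_kind=link.match_kind,
                    indirect=True,
                    via_seed_protein=link.protein_id,
                )
            )
    return out


def map_orthologs(
    protein_ids: set[str],
    orthologs: pd.DataFrame | None,
    species_of: dict[str, Species] | None = None,
) -> tuple[set[str], int]:
    """Map rat/mouse protein (or gene) ids to human ids.

    Human ids pass through unchanged; rat/mouse ids are replaced by every
    human ortholog listed for them (one-to-many rows all retained);
    ids with no mapping are dropped. Returns (human id set, n_unmapped).
    When ``species_of`` is provided, only ids marked rat/mouse are mapped;
    otherwise any id present in the table's source column is treated as
    non-human.
    """
    mapping: dict[str, set[str]] = {}
    if orthologs is not None:
        for _, row in orthologs.iterrows():
            mapping.setdefault(str(row["source_id"]), set()).add(str(row["human_id"]))

    out: set[str] = set()
    unmapped = 0
    for pid in protein_ids:
        if species_of is not None:
            if species_of.get(pid, Species.HUMAN) is Species.HUMAN:
                out.add(pid)
                continue
            if pid in mapping:
                out |= mapping[pid]
            else:
                unmapped += 1
        else:
            if pid in mapping:
                out |= mapping[pid]
            else:
                out.add(pid)
    if unmapped:
        logger.info("%d rodent ids had no human ortholog and were dropped", unmapped)
    return out, unmapped
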