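"""Domain records shared by every pipeline stage.

Identifiers (compound, protein, food, drug, gene, probe) are opaque,
case-sensitive strings. Affinity-like measurement values are normalized to
nM on load; inhibition stays in percent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Origin(str, enum.Enum):
    FOOD = "food"
    DRUG = "drug"
    REFERENCE_BIOACTIVE = "reference_bioactive"


class ProteinCategory(str, enum.Enum):
    DRUG_TARGET = "drug_target"
    ENZYME = "enzyme"
    TRANSPORTER = "transporter"
    CARRIER = "carrier"


#: ADME-side (pharmacokinetics) categories; the complement is the
#: pharmacodynamics side.
PK_CATEGORIES = frozenset(
    {ProteinCategory.ENZYME, ProteinCategory.TRANSPORTER, ProteinCategory.CARRIER}
)


class Species(str, enum.Enum):
    HUMAN = "human"
    RAT = "rat"
    MOUSE = "mouse"


class Endpoint(str, enum.Enum):
    KI = "Ki"
    KD = "Kd"
    IC50 = "IC50"
    EC50 = "EC50"
    INHIBITION = "inhibition"
    POTENCY = "potency"


#: Endpoints whose value is a binding/functional concentration (nM after
#: normalization) and which are filtered on the pchembl scale.
AFFINITY_ENDPOINTS = frozenset({Endpoint.KI, Endpoint.KD, Endpoint.IC50, Endpoint.EC50})


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str | None = None
    mw: float | None = None
    names: tuple[str, ...] = ()
    origin: Origin = Origin.FOOD


@dataclass(frozen=True)
class FoodRecord:
    food_id: str
    compound_ids: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    category: ProteinCategory
    disease_classes: frozenset[str] = field(default_factory=frozenset)
    biological_system: str = ""
    species: Species = Species.HUMAN
    name: str = ""


@dataclass(frozen=True)
class MeasurementRecord:
    """One bioassay observation, value already normalized.

    ``value`` is in nM for Ki/Kd/IC50/EC50 and potency endpoints, percent
    for inhibition. ``pchembl`` is -log10 of the molar value when known; for
    affinity endpoints with a value but no reported pchembl it is derived
    on load (pchembl = 9 - log10(value_nM)).
    """

    compound_id: str
    protein_id: str
    endpoint: Endpoint
    value: float | None = None
    pchembl: float | None = None

    def derived_pchembl(self) -> float | None:
        if self.pchembl is not None:
            return self.pchembl
        if self.endpoint in AFFINITY_ENDPOINTS and self.value is not None and self.value > 0:
            return 9.0 - math.log10(self.value)
        return None


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    compound_id: str
    #: (protein_id, role) pairs; role matches the linked protein's category
    protein_links: tuple[tuple[str, ProteinCategory], ...] = ()
    disease_classes: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ConfidentInteraction:
    """Aggregated compound-protein link surviving the frequency rule."""

    compound_id: str
    protein_id: str
    positive_frequency: float
    n_measurements: int
    representative_affinity: float | None  # nM; geometric mean over positives
    endpoint_mix: frozenset[Endpoint]


class ActivityBasis(str, enum.Enum):
    DRUG_RANGE = "drug_range"
    CATEGORY_MEAN_FALLBACK = "category_mean_fallback"


@dataclass(frozen=True)
class ActivityCall:
    compound_id: str
    protein_id: str
    is_active: bool
    basis: ActivityBasis
    drug_range: tuple[float, float] | None = None  # (min nM, max nM)
    category_mean: float | None = None  # nM
    representative_affinity: float | None = None  # carried through for networks


class MatchKind(str, enum.Enum):
    EXACT_STRUCTURE = "exact_structure"
    SIMILAR = "similar"


@dataclass(frozen=True)
class SimilarityMatch:
    query_compound_id: str
    reference_compound_id: str
    tanimoto: float
    mw_delta: float
    match_kind: MatchKind


@dataclass(frozen=True)
class InferredLink:
    """A compound-protein link transferred from a matched reference compound."""

    compound_id: str
    protein_id: str
    via_reference: str
    match_kind: MatchKind
    indirect: bool = False  # True when added by PPI expansion
    via_seed_protein: str | None = None
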