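"""Pipeline configuration.

Every numeric cutoff used anywhere in the pipeline lives here, with the
published default. Affinity-like thresholds are stored on the nM scale so
that all endpoint comparisons happen on one axis (the 50 uM potency cutoff
becomes 50,000 nM internally).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


@dataclass
class PipelineConfig:
    """All tunable thresholds of the drug-food interaction pipeline.

    Attributes
    ----------
    pchembl_min:
        Minimum pchembl (-log10 molar) for a Ki/Kd/IC50/EC50 measurement to
        count as a positive observation (strict ``>``). 6 corresponds to 1 uM.
    inhibition_min_pct:
        Minimum percent inhibition for an inhibition endpoint (strict ``>``).
    potency_max_nM:
        Maximum potency, in nM, for a potency endpoint (strict ``<``);
        default is 50 uM expressed in nM.
    frequency_min:
        Minimum fraction of positive measurements for a compound-protein
        pair to be kept as a confident interaction (strict ``>``).
    tc_min:
        Tanimoto coefficient threshold for structural similarity (``>=``).
    mw_window:
        Maximum absolute molecular-weight difference, g/mol, for a
        similarity match (strict ``<``).
    ppi_score_min:
        Minimum PPI confidence score for first-neighbor expansion
        (strict ``>``).
    shared_pair_min:
        Minimum number of shared drug-food pairs for a target-target edge
        (``>=``).
    fdr_alpha:
        Benjamini-Hochberg q-value cutoff for differential expression.
    es_min:
        Minimum absolute connectivity enrichment score (strict ``>``).
    perm_p_max:
        Maximum permutation p-value for a non-null connectivity call
        (strict ``<``).
    nonnull_min_pct:
        Minimum non-null percentage for a non-null connectivity call
        (strict ``>``).
    top_edges_shown:
        Display-layer edge truncation per node; never affects statistics.
    strict_two_sided_range:
        If True, the drug-range activity rule also requires the food
        compound to be no more potent than the strongest drug. Default
        False: a phytochemical more potent than every drug is still active.
    pool_endpoints:
        If True (default), Ki/Kd/IC50/EC50 are pooled on the nM scale when
        computing drug ranges; if False, ranges are computed per endpoint.
    n_permutations:
        Resampled tag-list permutations behind the connectivity p-value.
    max_tag_list_size:
        Optional cap on tag-list length (None = no cap).
    seed:
        Root random seed; all pipeline randomness derives from it.
    """

    pchembl_min: float = 6.0
    inhibition_min_pct: float = 30.0
    potency_max_nM: float = 50_000.0
    frequency_min: float = 0.5
    tc_min: float = 0.85
    mw_window: float = 50.0
    ppi_score_min: float = 400.0
    shared_pair_min: int = 3
    fdr_alpha: float = 0.05
    es_min: float = 0.75
    perm_p_max: float = 0.01
    nonnull_min_pct: float = 80.0
    top_edges_shown: int = 5
    strict_two_sided_range: bool = False
    pool_endpoints: bool = True
    n_permutations: int = 10_000
    max_tag_list_size: int | None = None
    seed: int = 0

    _INT_FIELDS = frozenset({"shared_pair_min", "top_edges_shown", "n_permutations", "seed", "max_tag_list_size"})
    _BOOL_FIELDS = frozenset({"strict_two_sided_range", "pool_endpoints"})

    def to_file(self, path: Union[str, Path]) -> None:
        """Serialize to a ``key = value`` plain-text file."""
        lines = []
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Parse a ``key = value`` config file; unknown keys are an error."""
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = cls._parse_value(key, val)
        return cls(**kwargs)

    @classmethod
    def _parse_value(cls, key: str, val: str):
        if key in cls._BOOL_FIELDS:
            if val.lower() in ("true", "1", "yes"):
                return True
            if val.lower() in ("false", "0", "no"):
                return False
            raise ValueError(f"config key {key!r}: expected a boolean, got {val!r}")
        if key in cls._INT_FIELDS:
            return None if val == "None" else int(val)
        return float(val)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
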