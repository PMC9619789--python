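"""Pipeline configuration with the method's default thresholds.

All tunables live in one YAML-loadable dataclass: the completeness
threshold (share of concept-0 records a table may carry before the check
fails, default 0.20), the manual-review prioritization fraction (terms
covering 80% of events), the drug-era merge gap (30 days, the OHDSI
convention), the strict 1:many filter flag, and the observation-period
policy. Provenance (type) concept ids are one fixed constant per source
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "TYPE_CONCEPTS"]

#: provenance type_concept_id per source stream (configurable constants)
TYPE_CONCEPTS = {
    "baseline": 32862,        # patient self-report
    "gp_clinical": 32817,     # EHR
    "gp_scripts": 32838,      # EHR prescription
    "hospital": 32818,        # EHR administrative record
    "hospital_primary": 32902,    # primary diagnosis
    "hospital_secondary": 32908,  # secondary diagnosis
    "death": 32815,           # death certificate
    "covid_test": 32856,      # lab
}


@dataclass
class PipelineConfig:
    seed: int = 0
    completeness_threshold: float = 0.20
    prioritization_fraction: float = 0.80
    drug_era_gap_days: int = 30
    strict_filter: bool = False
    allow_out_of_period: bool = True
    emit_negative_booleans: bool = False
    type_concepts: dict = field(default_factory=lambda: dict(TYPE_CONCEPTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
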