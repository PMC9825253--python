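"""Run configuration: every pipeline threshold in one validated mapping.

Defaults are the analysis constants used throughout the package (QC
cut-offs, classifier length bounds, matching thresholds, simulation
rates). Configs round-trip through YAML; unknown keys are rejected so
typos fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Dict, Union

import yaml

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    # qPCR QC
    qpcr_max_ct: float = 21.0
    qpcr_sentinel: float = 999.0
    qpcr_max_rep_diff: float = 0.5
    qpcr_max_pct_dev: float = 3.0
    qpcr_gdna_threshold: float = 10.0
    genorm_m_cutoff: float = 1.5
    # functionality classifier
    duf247_min_aa: int = 508
    duf247_max_aa: int = 559
    female_min_aa: int = 82
    female_max_aa: int = 122
    length_tolerance: float = 0.0
    strict_classifier: bool = True
    # diversity / synteny
    identity_mode: str = "aligned_columns"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    synteny_identity_threshold: float = 70.0
    synteny_female_identity_threshold: float = 35.0
    # fine-mapping
    endpoint_convention: str = "mid"
    # simulation
    selfing_rate: float = 0.005
    call_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    verbosity: int = 1

    def merged(self, overrides: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return replace(self, **overrides)

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    """YAML config on top of the defaults; unknown keys rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return RunConfig().merged(data)


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
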