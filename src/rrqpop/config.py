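"""Pipeline configuration: every tunable in one validated object.

The resolved configuration is written alongside every run's outputs so an
analysis is reproducible from its artifact directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their pinned defaults.

    Thresholds: DE |log2FC| > 0.5 at BH-adjusted p < 0.1, refinement
    log2 ratio > 1, Bliss classification at +/-10, directional Cox filter
    at p < 0.05, radiosensitization reference dose 4 Gy.
    """

    seed: int = 0
    out_dir: str = "rrqpop_run"
    stages: list = field(default_factory=lambda: [
        "design", "dose_response", "qpop", "synergy", "radio", "select",
        "prognostic"])
    # screen
    n_drugs: int = 12
    screen_replicates: int = 2
    screen_noise_sd: float = 0.05
    # synergy
    bliss_synergy_threshold: float = 10.0
    bliss_antagonism_threshold: float = -10.0
    ci_form: str = "mutually_exclusive"
    # radiobiology
    sensitization_dose_Gy: float = 4.0
    sensitization_metric: str = "sf_ratio"  # or "mean_inactivation_dose"
    # gene selection
    de_lfc_min: float = 0.5
    de_alpha: float = 0.1
    refine_min_log2_ratio: float = 1.0
    refine_signed: bool = True
    n_genes: int = 20000
    n_per_group: int = 3
    # prognostic
    direction_alpha: float = 0.05
    cohort_n: int = 261
    validation_n: int = 158
    cohort_hr: float = 1.8
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self):
        return asdict(self)

    def dump(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))
        return Path(path)
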