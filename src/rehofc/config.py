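"""Pipeline configuration: one dataclass, YAML in, resolved YAML out."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All knobs of the analysis chain, with field-standard defaults.

    The extent thresholds for cluster correction can either be estimated
    per run by the Monte-Carlo module on the analysis mask
    (``extent_source="alphasim"``, the default) or fixed to
    ``group_min_extent_voxels`` / ``behavior_min_extent_voxels``
    (``extent_source="fixed"``).
    """

    # cohort simulation
    simulate: bool = True
    data_dir: str | None = None  # read a previously written cohort instead
    n_patient: int = 79
    n_control: int = 119
    n_volumes: int = 200
    tr_s: float = 2.0
    # preprocessing
    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    #: global-signal regression; the WM/CSF/motion regressors always apply.
    #: Off by default here: on the small synthetic brain the planted
    #: networks are a large fraction of the global mean, and removing it
    #: leaks a sign-inverted copy of the network signal everywhere.
    global_signal: bool = False
    drms_threshold_mm: float = 0.5
    exclusion_max_mm: float = 2.0
    exclusion_max_deg: float = 2.0
    # ReHo
    neighborhood: int = 27
    fwhm_mm: float = 8.0
    seed_source: str = "reho"  # "reho" (discovered) or "atlas" (planted regions)
    # statistics
    one_sample_correction: str = "cluster"  # or "bonferroni"
    one_sample_voxel_p: float = 0.01
    one_sample_alpha_fwe: float = 0.01
    group_voxel_p: float = 0.005
    group_min_extent_voxels: int = 74     # 1,998 mm^3 at 3 mm
    group_cluster_alpha: float = 0.01
    behavior_voxel_p: float = 0.05
    behavior_min_extent_voxels: int = 389  # 10,503 mm^3 at 3 mm
    behavior_cluster_alpha: float = 0.05
    extent_source: str = "alphasim"
    connectivity: int = 26
    # Monte-Carlo cluster simulation
    clustersim_iterations: int = 1000
    # mediation
    mediation_alpha: float = 0.05
    mediation_covariates: bool = False
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolved_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
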