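"""Run configuration: every tunable of the pipeline with its default.

Defaults mirror the analysis settings this pipeline implements: a 50%
missingness filter, a signed network at soft power 10 built from biweight
midcorrelations (maxPOutliers 0.05), dynamic tree cutting at deepSplit 4 with
minimum module size 10 and module merging at Eigenprotein dissimilarity 0.2,
PET positivity cut-offs 1.55 (Aβ) and 1.24 (tau), CSF Aβ42/40 cut-off 0.061,
kME > 0.6 for cross-cohort projection, a minimum of 20 observations per
protein for differential models, and elastic-net mixing α = 0.7.

The resolved configuration is serialized into every run directory for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # data paths (None -> simulate a cohort instead of loading)
    matrix_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "proteostage_run"

    # synthetic-cohort defaults (the study conditions emulated)
    n_per_stage: tuple[int, ...] = (20, 20, 20, 20, 20, 20, 20)
    module_sizes: dict[str, int] = field(default_factory=lambda: {
        "core_markers": 60,
        "endolysosomal": 30,
        "immune_response": 20,
        "metabolic": 40,
        "synapse_membrane": 50,
    })
    n_background: int = 300
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    tmt_set_size: int = 15
    validation_overlap_frac: float = 0.7

    # preprocessing
    max_missing_frac: float = 0.5
    qc_sd_mult: float = 4.0
    exclude_reference_from_medians: bool = True

    # network construction
    soft_power: int = 10
    auto_power: bool = False
    scale_free_r2_target: float = 0.9
    max_mean_connectivity: float = 100.0
    max_p_outliers: float = 0.05
    min_pairs: int = 10
    deep_split: int = 4
    min_module_size: int = 10
    merge_cut_height: float = 0.2
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    reassign_threshold: float = 0.05
    apply_reassignment: bool = False

    # staging cut-offs
    abeta_suvr_cut: float = 1.55
    tau_suvr_cut: float = 1.24
    abeta_ratio_cut: float = 0.061
    pool_min_n: int = 3

    # association / projection
    kme_cut: float = 0.6
    min_obs: int = 20
    adjust_method: str = "BH"

    # trajectories
    loess_span: float = 0.75
    loess_degree: int = 2
    exclude_discordant: bool = True

    # staging panels
    elasticnet_alpha: float = 0.7
    cv_folds: int = 10
    lambda_rule: str = "min_deviance"

    # randomness
    seed: int = 1

    def __post_init__(self) -> None:
        self.n_per_stage = tuple(int(n) for n in self.n_per_stage)
        if len(self.n_per_stage) != 7:
            raise ValueError("n_per_stage must have 7 entries (CTRL, I..VI)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_stage"] = list(self.n_per_stage)
        return d

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a JSON or YAML file; unknown keys raise."""
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path.name} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
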