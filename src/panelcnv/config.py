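"""Pipeline configuration: every tunable constant in one dataclass.

Defaults reproduce the production assay's published parameterization
(per-bp CNV exit rate 1/6200, CNV prior 1e-3, ~650x mean depth QC gates);
constants the assay did not publish (emission floor for copy 0, dispersion
caps, confidence thresholds, Alu matching stringency) carry the package's
own documented defaults and can be overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- emission model -------------------------------------------------
    #: copy-number state space; must contain the diploid state 2
    states: tuple[int, ...] = (0, 1, 2, 3)
    #: residual depth fraction modelled for homozygous deletions (copy 0);
    #: accounts for mismapping background, must lie in (0, 0.5)
    epsilon0: float = 0.01
    #: dispersion cap: negative binomial with r this large is numerically
    #: Poisson
    r_max: float = 1e8
    #: dispersion used when a batch is too small (< 2 samples) to estimate it
    default_r: float = 1e4

    # --- HMM transitions ------------------------------------------------
    #: per-bp probability of leaving a CNV state (1 / mean CNV length in bp)
    p_cnv_to_wt_per_bp: float = 1.0 / 6200.0
    #: prior odds of CNV vs wild-type occupancy per bp
    p_cnv_prior: float = 0.001
    #: inter-target gaps are clamped here; beyond it the chain has
    #: effectively mixed to stationarity anyway
    max_gap_bp: int = 1_000_000

    # --- calling policy -------------------------------------------------
    #: mean posterior confidence at or above which a call is confident
    t_conf: float = 0.99
    #: calls with confidence in [t_retest, t_conf) are flagged for retest
    t_retest: float = 0.5

    # --- sample QC gates (printed assay thresholds) ---------------------
    max_contamination: float = 0.05  # fail at >= 5%
    min_per_base_depth: float = 20.0  # inclusive
    min_mean_depth: float = 250.0  # strict: mean must exceed 250x
    min_roi_coverage: float = 1.0  # 100% of ROI covered

    # --- Alu insertion detection ----------------------------------------
    #: soft clips shorter than this carry too little junction sequence
    min_clip_len: int = 10
    #: clip boundary may sit this many bp from the catalogued insertion site
    clip_boundary_tolerance: int = 5
    #: minimum clip/junction overlap compared (bp)
    min_overlap: int = 10
    #: minimum identity over the compared overlap
    min_identity: float = 0.9
    #: unique matching reads required to call a site positive
    min_unique_reads: int = 3

    def __post_init__(self) -> None:
        if 2 not in self.states:
            raise ValueError("state space must include the diploid state 2")
        if not (0.0 < self.epsilon0 < 0.5):
            raise ValueError("epsilon0 must lie in (0, 0.5)")
        if not (0.0 < self.p_cnv_to_wt_per_bp < 1.0):
            raise ValueError("p_cnv_to_wt_per_bp must lie in (0, 1)")
        if self.p_cnv_prior <= 0:
            raise ValueError("p_cnv_prior must be positive")
        if not (0.0 <= self.t_retest <= self.t_conf <= 1.0):
            raise ValueError("need 0 <= t_retest <= t_conf <= 1")

    @property
    def p_wt_to_cnv_per_bp(self) -> float:
        """Per-bp entry rate, fixed by the prior: p_WT->CNV = p_CNV * p_CNV->WT."""
        return self.p_cnv_prior * self.p_cnv_to_wt_per_bp

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "states" in raw:
            raw["states"] = tuple(raw["states"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["states"] = list(data["states"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
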