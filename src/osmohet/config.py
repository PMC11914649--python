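"""Pipeline configuration: every numeric threshold used anywhere downstream.

All cutoffs quoted by the analysis (QC gene-count window, marker count
floor, rank cap of the signature score, subpopulation quantiles, screen
rules, trace-calling windows) live in one dataclass so a run can be
reproduced from a single YAML file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("osmohet")


@dataclass
class PipelineConfig:
    """Numeric thresholds and switches for the whole pipeline.

    Attributes
    ----------
    qc_min_genes, qc_max_genes:
        Inclusive window of detected genes per cell; cells with fewer than
        ``qc_min_genes`` or more than ``qc_max_genes`` are excluded.
    marker_min_count:
        Minimum UMI count for a positive selection-marker call
        (">1 counts" read as >= 2).
    norm_scale:
        Library-size target of the log-normalization
        ``ln(1 + count * norm_scale / n_molecules)``.
    rank_cap:
        Rank ceiling of the rank-based signature score; genes ranked worse
        than this contribute the capped rank.
    basal_quantile:
        Wild-type score quantile defining the basal-stressed threshold
        (last decile, 0.9).
    screen_min_cells:
        Minimum cells per genotype and condition for screen flags.
    screen_flag_fraction:
        Fraction of cells above threshold that flags a genotype (>25%).
    wt_sd_multiplier:
        Multiplier of the variability rule (see ``variability_rule``).
    variability_rule:
        ``"pooled_fold"`` (default): flag genotypes whose stress-condition
        score SD exceeds ``wt_sd_multiplier`` times the pooled wild-type SD.
        ``"replicate_sd"``: flag when SD exceeds mean(WT-strain SDs) +
        ``wt_sd_multiplier`` * SD(WT-strain SDs), the WT strains acting as
        replicates.
    trace_consecutive:
        Consecutive detections required to call a trace actively
        transcribing.
    trace_basal_points:
        Number of pre-stimulus points averaged into the basal level.
    highpix_n:
        Number of brightest pixels forming the HighPix object.
    connected_min:
        Minimum connected HighPix pixels for a transcription-site call.
    dilation_px:
        Nucleus dilation (pixels) defining the expanded nucleus.
    connectivity:
        Pixel connectivity (1 = 4-neighbour, 2 = 8-neighbour) used for the
        ConnectedHighPix component check.
    repressor_drop:
        Normalized drop separating high from low repressors (>50%).
    high_basal_sd:
        SD multiplier of the high-basal split (mean + 1 SD).
    post_window:
        Number of trailing points averaged into the post-induction level.
    de_min_fc:
        Linear fold-change floor of the differential-expression up set
        (1.5, i.e. log2 >= 0.58).
    de_alpha:
        Significance level for differential expression and screen tests.
    seed:
        Seed recorded with every run.
    """

    qc_min_genes: int = 500
    qc_max_genes: int = 3000
    marker_min_count: int = 2
    norm_scale: float = 10_000.0
    rank_cap: int = 1500
    basal_quantile: float = 0.9
    screen_min_cells: int = 6
    screen_flag_fraction: float = 0.25
    wt_sd_multiplier: float = 2.0
    variability_rule: str = "pooled_fold"
    trace_consecutive: int = 3
    trace_basal_points: int = 10
    highpix_n: int = 10
    connected_min: int = 5
    dilation_px: int = 5
    connectivity: int = 2
    repressor_drop: float = 0.5
    high_basal_sd: float = 1.0
    post_window: int = 10
    de_min_fc: float = 1.5
    de_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qc_min_genes >= self.qc_max_genes:
            raise ValueError("qc_min_genes must be < qc_max_genes")
        if not 0.0 < self.basal_quantile < 1.0:
            raise ValueError("basal_quantile must lie strictly in (0, 1)")
        for name in (
            "marker_min_count", "norm_scale", "rank_cap", "screen_min_cells",
            "screen_flag_fraction", "wt_sd_multiplier", "trace_consecutive",
            "trace_basal_points", "highpix_n", "connected_min", "dilation_px",
            "repressor_drop", "high_basal_sd", "post_window", "de_min_fc",
            "de_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.variability_rule not in ("pooled_fold", "replicate_sd"):
            raise ValueError(
                "variability_rule must be 'pooled_fold' or 'replicate_sd'")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def log_resolved(self) -> None:
        """Log every resolved field (each run records its config and seed)."""
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))
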