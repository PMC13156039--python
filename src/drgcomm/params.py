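"""Pipeline-wide thresholds and tuning parameters.

Every printed cutoff of the analysis lives here so that the stages share a
single, validated source of truth: QC fractions, detected-gene cutoffs, the
label-transfer prediction-score floor, the neuron marker thresholds, the
differential-expression selection criteria, the stratified-background layout
(20 intervals x 100 genes), the replicate count for activity scoring, module
filtering, and the permutation count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml


@dataclass
class PipelineParams:
    """Thresholds and settings shared across all pipeline stages.

    Defaults reproduce the published analysis: cells with more than 20% of
    counts from mitochondrial genes are discarded; the primary dataset keeps
    cells with more than 2,000 detected genes (secondary: at least 1,000);
    label transfers with a prediction score below 0.55 are discarded; neuron
    purification removes cells with normalized Rbfox3 below 0.5 or normalized
    Apoe above 2; pseudobulk DE uses an adjusted-P cutoff of 1e-20; ligand
    candidates require fold change > 3, detection in > 10% of cells and
    P < 0.05; activity scores use 20 expression intervals x 100 background
    genes, clipped at zero and averaged over 5 replicates; modules need at
    least 10 genes; permutation tests use 1,000 label shuffles.
    """

    mito_max_fraction: float = 0.20
    min_genes_primary: int = 2000
    min_genes_secondary: int = 1000
    prediction_score_min: float = 0.55
    rbfox3_min_norm: float = 0.5
    apoe_max_norm: float = 2.0
    pseudobulk_adj_p_max: float = 1e-20
    lr_fold_min: float = 3.0
    lr_pct_min: float = 0.10
    lr_p_max: float = 0.05
    n_background_intervals: int = 20
    genes_per_interval: int = 100
    n_score_replicates: int = 5
    module_min_genes: int = 10
    n_permutations: int = 1000
    normalization_scale: float = 1e4
    fc_pseudocount: float = 1e-9
    seed: int = 0
    # method switches (defaults follow the published choices where stated,
    # documented design decisions where not)
    p_adjust_method: Literal["bh", "bonferroni"] = "bh"
    neuron_filter_mode: Literal["any", "all"] = "any"
    candidate_pool_scope: Literal["global", "per_type"] = "global"
    background_rank_scope: Literal["receiver_timepoint", "global"] = "receiver_timepoint"
    degenerate_scaled_value: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mito_max_fraction", "lr_pct_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("prediction_score_min", "lr_p_max", "pseudobulk_adj_p_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in (
            "min_genes_primary",
            "min_genes_secondary",
            "n_background_intervals",
            "genes_per_interval",
            "n_score_replicates",
            "module_min_genes",
            "n_permutations",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.lr_fold_min <= 0:
            raise ValueError("lr_fold_min must be > 0")
        if self.normalization_scale <= 0:
            raise ValueError("normalization_scale must be > 0")
        if self.fc_pseudocount <= 0:
            raise ValueError("fc_pseudocount must be > 0")
        if self.p_adjust_method not in ("bh", "bonferroni"):
            raise ValueError("p_adjust_method must be 'bh' or 'bonferroni'")
        if self.neuron_filter_mode not in ("any", "all"):
            raise ValueError("neuron_filter_mode must be 'any' or 'all'")
        if not 0.0 <= self.degenerate_scaled_value <= 1.0:
            raise ValueError("degenerate_scaled_value must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def load_params(path: str | Path) -> PipelineParams:
    """Load :class:`PipelineParams` from a YAML mapping (1:1 keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return PipelineParams.from_dict(data)
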