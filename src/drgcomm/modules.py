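"""Gene-module scoring, module filtering, and the label-permutation test.

Module scores use the same binned-control contrast as the interactome
activity score (one background replicate), then are min-max scaled to
[0, 1] per module across all scored cells. Modules are filtered to
differentially expressed genes and a minimum of ten surviving genes.
Group comparisons of per-cell activity vectors use a permutation test on
the absolute difference of group means with 1,000 random label
assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .interactome import _cell_mask, stratified_background
from .io import get_lognorm
from .params import PipelineParams


@dataclass(frozen=True)
class GeneModule:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"module {self.name!r} has no genes")


def read_modules(path: str | Path) -> list[GeneModule]:
    """Read module definitions from TSV (name, genes ;-separated) or JSON
    ({name: [genes...]})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return [GeneModule(name, tuple(genes)) for name, genes in data.items()]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "genes"):
        if col not in df.columns:
            raise ValueError(f"module table missing column {col!r}")
    return [
        GeneModule(row["name"], tuple(g for g in str(row["genes"]).split(";") if g))
        for _, row in df.iterrows()
    ]


def filter_modules(
    modules: list[GeneModule],
    de_genes: set[str],
    params: PipelineParams | None = None,
) -> list[GeneModule]:
    """Intersect each module with the DE gene set; drop modules that retain
    fewer than ten genes."""
    params = params or PipelineParams()
    out = []
    for mod in modules:
        kept = tuple(g for g in mod.genes if g in de_genes)
        if len(kept) >= params.module_min_genes:
            out.append(GeneModule(mod.name, kept))
    return out


def module_score(
    adata: ad.AnnData,
    module: GeneModule,
    params: PipelineParams | None = None,
    rng: np.random.Generator | None = None,
    cell_type: str | None = None,
    timepoint: float | None = None,
) -> pd.DataFrame:
    """Per-cell module score, min-max scaled to [0, 1] across scored cells.

    Raw score per cell = mean normalized expression of the module genes
    minus the mean of one stratified binned-control background draw. If all
    raw scores are equal the scaled scores collapse to
    ``params.degenerate_scaled_value`` (default 0, "nonactivity").
    """
    params = params or PipelineParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes_present = [g for g in module.genes if g in adata.var_names]
    if not genes_present:
        raise ValueError(f"module {module.name!r} has no genes in the dataset")
    mask = _cell_mask(adata, cell_type, timepoint)
    if not mask.any():
        raise ValueError("no cells to score")
    bg = stratified_background(
        set(module.genes), adata, cell_type, rng, params=params, timepoint=timepoint
    )
    L = get_lognorm(adata, params.normalization_scale)
    sub = L[mask]
    a_idx = adata.var_names.get_indexer(genes_present)
    b_idx = adata.var_names.get_indexer(bg.ravel())
    raw = np.asarray(sub[:, a_idx].mean(axis=1)).ravel() - np.asarray(
        sub[:, b_idx].mean(axis=1)
    ).ravel()
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        scaled = (raw - lo) / (hi - lo)
    else:
        scaled = np.full_like(raw, params.degenerate_scaled_value)
    return pd.DataFrame(
        {"cell_id": adata.obs_names[mask], "raw_score": raw, "scaled_score": scaled}
    ).reset_index(drop=True)


def permutation_test(
    values,
    labels,
    n_permutations: int | None = None,
    rng: np.random.Generator | None = None,
    params: PipelineParams | None = None,
) -> float:
    """Two-group label-permutation p-value on |difference of group means|.

    ``labels`` is a two-level assignment (any dtype with exactly two unique
    values, both non-empty). p = (1 + #{permuted >= observed}) /
    (n_permutations + 1) — the add-one estimator, which is valid and never
    zero.
    """
    params = params or PipelineParams()
    n_permutations = n_permutations if n_permutations is not None else params.n_permutations
    if n_permutations <= 0:
        raise ValueError("n_permutations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.size}")
    g1 = labels == uniq[0]
    n1, n = int(g1.sum()), values.size
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    observed = abs(values[g1].mean() - values[~g1].mean())
    # |mean1 - mean2| is a monotone function of sum over group 1, so only
    # the permuted group-1 sums are needed
    total = values.sum()
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n1]
    sums1 = values[perm_idx].sum(axis=1)
    perm_stats = np.abs(sums1 / n1 - (total - sums1) / (n - n1))
    exceed = int(np.count_nonzero(perm_stats >= observed - 1e-12))
    return (1 + exceed) / (n_permutations + 1)
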