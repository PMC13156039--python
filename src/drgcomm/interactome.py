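"""Sender->receiver ligand-receptor activity with a stratified background.

The bespoke statistic of the pipeline. For a candidate pair, the activity in
the receiver cell type at a timepoint is the mean (over receiver cells) of
the average normalized expression of the pair's associated target genes
minus the average over a random background gene matrix. Background genes are
all genes outside the candidate pool (the union of upregulated genes),
ranked by their expression, split into 20 equal-rank intervals, with 100
genes drawn from each interval. Negative scores are clipped to zero
("nonactivity") and the score is averaged over 5 independent background
replicates.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .de import de_table, select_lr_candidates
from .io import get_lognorm
from .params import PipelineParams

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionActivity:
    """Scored activity of one ligand-receptor pair between two cell types."""

    sender_type: str
    receiver_type: str
    timepoint: float
    ligand: str
    receptor: str
    activity_score: float
    replicate_scores: tuple[float, ...]
    n_background_genes_used: int


def read_lr_reference(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor reference TSV.

    Columns ``ligand``, ``receptor``, ``targets`` (semicolon-separated
    associated target genes). Duplicate (ligand, receptor) entries and empty
    target sets are rejected.
    """
    ref = pd.read_csv(path, sep="\t", dtype=str)
    return validate_lr_reference(ref)


def validate_lr_reference(ref: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand", "receptor", "targets"):
        if col not in ref.columns:
            raise ValueError(f"ligand-receptor reference missing column {col!r}")
    dup = ref.duplicated(subset=["ligand", "receptor"])
    if dup.any():
        row = ref[dup].iloc[0]
        raise ValueError(f"duplicate ligand-receptor entry: ({row['ligand']}, {row['receptor']})")
    ref = ref.copy()
    ref["targets"] = ref["targets"].map(
        lambda s: tuple(t for t in str(s).split(";") if t) if pd.notna(s) else ()
    )
    if (ref["targets"].map(len) == 0).any():
        row = ref[ref["targets"].map(len) == 0].iloc[0]
        raise ValueError(f"empty target set for pair ({row['ligand']}, {row['receptor']})")
    return ref.reset_index(drop=True)


def _cell_mask(adata: ad.AnnData, cell_type: str | None, timepoint: float | None) -> np.ndarray:
    mask = np.ones(adata.n_obs, dtype=bool)
    if cell_type is not None:
        mask &= adata.obs["cell_type"].to_numpy() == cell_type
    if timepoint is not None:
        mask &= adata.obs["timepoint"].to_numpy(dtype=float) == float(timepoint)
    return mask


def build_candidate_pairs(
    up_by_type: dict[str, set[str]],
    adata: ad.AnnData,
    reference: pd.DataFrame,
    params: PipelineParams | None = None,
    timepoint: float | None = None,
) -> pd.DataFrame:
    """Candidate (sender, receiver, ligand, receptor) pairs.

    A pair exists when the ligand is upregulated in the sender type and the
    receptor is detected in more than ``lr_pct_min`` of receiver cells (at
    the given timepoint, if any). Self-pairs are allowed. Reference entries
    whose ligand or receptor is absent from the dataset are skipped (count
    logged).
    """
    params = params or PipelineParams()
    var_index = adata.var_names
    X = sp.csr_matrix(adata.X)
    cell_types = sorted(set(adata.obs["cell_type"]))
    detected: dict[str, np.ndarray] = {}
    for ct in cell_types:
        mask = _cell_mask(adata, ct, timepoint)
        detected[ct] = (
            np.asarray((X[mask] > 0).mean(axis=0)).ravel()
            if mask.any()
            else np.zeros(adata.n_vars)
        )
    skipped = 0
    rows = []
    for _, entry in reference.iterrows():
        lig, rec = entry["ligand"], entry["receptor"]
        if lig not in var_index or rec not in var_index:
            skipped += 1
            continue
        rec_j = var_index.get_loc(rec)
        senders = [ct for ct in cell_types if lig in up_by_type.get(ct, set())]
        receivers = [ct for ct in cell_types if detected[ct][rec_j] > params.lr_pct_min]
        for s in senders:
            for r in receivers:
                rows.append((s, r, lig, rec))
    if skipped:
        log.info("skipped %d reference entries with genes absent from the dataset", skipped)
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor"])


def stratified_background(
    candidate_pool: set[str],
    adata: ad.AnnData,
    receiver_type: str | None,
    rng: np.random.Generator,
    params: PipelineParams | None = None,
    timepoint: float | None = None,
) -> np.ndarray:
    """Draw the random background gene matrix.

    All genes outside the candidate pool are ranked by mean normalized
    expression in the receiver cells (at the timepoint, if given), split
    into ``n_background_intervals`` equal-rank intervals, and
    ``genes_per_interval`` genes are drawn uniformly without replacement
    from each. Returns an (intervals x draws) array of gene names. When the
    smallest interval holds fewer genes than requested the draw size is
    clamped (with a warning), never below 1.
    """
    params = params or PipelineParams()
    genes = np.asarray(adata.var_names)
    bg_mask = ~np.isin(genes, list(candidate_pool))
    bg_genes = genes[bg_mask]
    if bg_genes.size < params.n_background_intervals:
        raise ValueError(
            f"only {bg_genes.size} background genes for "
            f"{params.n_background_intervals} intervals"
        )
    if params.background_rank_scope == "global":
        mask = np.ones(adata.n_obs, dtype=bool)
    else:
        mask = _cell_mask(adata, receiver_type, timepoint)
    if not mask.any():
        raise ValueError(f"no cells for receiver {receiver_type!r} at t={timepoint}")
    L = get_lognorm(adata, params.normalization_scale)
    means = np.asarray(L[mask][:, bg_mask].mean(axis=0)).ravel()
    ranked = bg_genes[np.argsort(means, kind="stable")]
    intervals = np.array_split(ranked, params.n_background_intervals)
    min_size = min(len(iv) for iv in intervals)
    k = min(params.genes_per_interval, min_size)
    if k < params.genes_per_interval:
        warnings.warn(
            f"background intervals hold as few as {min_size} genes; "
            f"drawing {k} per interval instead of {params.genes_per_interval}",
            stacklevel=2,
        )
    k = max(k, 1)
    return np.vstack([rng.choice(iv, size=k, replace=False) for iv in intervals])


def enrichment_score(
    adata: ad.AnnData,
    receiver_type: str | None,
    timepoint: float | None,
    associated_genes,
    background_matrix: np.ndarray,
    params: PipelineParams | None = None,
) -> float:
    """Raw (unclipped) activity: mean over receiver cells of the associated
    genes' average normalized expression minus the background average.

    By linearity this equals the difference of the two gene-set means of the
    per-gene average expression over receiver cells, which is how it is
    computed.
    """
    params = params or PipelineParams()
    mask = _cell_mask(adata, receiver_type, timepoint)
    if not mask.any():
        raise ValueError(f"no receiver cells of type {receiver_type!r} at t={timepoint}")
    assoc = [g for g in associated_genes if g in adata.var_names]
    if not assoc:
        raise ValueError("no associated genes present in the dataset")
    L = get_lognorm(adata, params.normalization_scale)
    mu = np.asarray(L[mask].mean(axis=0)).ravel()
    a_idx = adata.var_names.get_indexer(assoc)
    b_idx = adata.var_names.get_indexer(background_matrix.ravel())
    return float(mu[a_idx].mean() - mu[b_idx].mean())


def score_interaction(
    adata: ad.AnnData,
    pair,
    timepoint: float,
    associated_genes,
    candidate_pool: set[str],
    params: PipelineParams | None = None,
    rng: np.random.Generator | None = None,
) -> InteractionActivity:
    """Replicated, clipped activity score for one candidate pair.

    ``pair`` is anything with ``sender``, ``receiver``, ``ligand`` and
    ``receptor`` attributes or keys. Draws ``n_score_replicates``
    independent background matrices; each replicate's raw score is clipped
    at zero and the activity is the mean of the clipped replicates.
    """
    params = params or PipelineParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    get = (lambda k: pair[k]) if isinstance(pair, (dict, pd.Series)) else (lambda k: getattr(pair, k))
    receiver = get("receiver")
    reps = []
    n_bg = 0
    for _ in range(params.n_score_replicates):
        bg = stratified_background(
            candidate_pool, adata, receiver, rng, params=params, timepoint=timepoint
        )
        n_bg = bg.size
        reps.append(
            enrichment_score(adata, receiver, timepoint, associated_genes, bg, params=params)
        )
    clipped = np.maximum(reps, 0.0)
    return InteractionActivity(
        sender_type=get("sender"),
        receiver_type=receiver,
        timepoint=float(timepoint),
        ligand=get("ligand"),
        receptor=get("receptor"),
        activity_score=float(clipped.mean()),
        replicate_scores=tuple(float(r) for r in reps),
        n_background_genes_used=n_bg,
    )


def score_timepoint(
    adata: ad.AnnData,
    timepoint: float,
    reference: pd.DataFrame,
    params: PipelineParams | None = None,
    rng: np.random.Generator | None = None,
    reference_timepoint: float = 0.0,
    de_tables: dict[str, pd.DataFrame] | None = None,
) -> list[InteractionActivity]:
    """End-to-end interactome for one timepoint.

    Runs per-cell-type DE versus control (unless precomputed tables are
    supplied), selects upregulated ligand candidates, builds candidate
    pairs, and scores each pair against its associated target program.
    """
    params = params or PipelineParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    cell_types = sorted(set(adata.obs["cell_type"]))
    up_by_type: dict[str, set[str]] = {}
    for ct in cell_types:
        tab = (
            de_tables[ct]
            if de_tables is not None and ct in de_tables
            else de_table(adata, ct, timepoint, reference_timepoint, params)
        )
        up_by_type[ct] = select_lr_candidates(tab, params)
    pairs = build_candidate_pairs(up_by_type, adata, reference, params, timepoint=timepoint)
    targets_of = {
        (e["ligand"], e["receptor"]): tuple(e["targets"]) for _, e in reference.iterrows()
    }
    activities = []
    for _, pair in pairs.iterrows():
        if params.candidate_pool_scope == "per_type":
            pool = set(up_by_type.get(pair["receiver"], set()))
        else:
            pool = set().union(*up_by_type.values()) if up_by_type else set()
        assoc = targets_of[(pair["ligand"], pair["receptor"])]
        activities.append(
            score_interaction(adata, pair, timepoint, assoc, pool, params, rng)
        )
    return activities


def interactome_table(activities: list[InteractionActivity]) -> pd.DataFrame:
    """All activities, sorted by descending score; ties broken by
    (sender, receiver, ligand, receptor) lexicographic order."""
    if not activities:
        return pd.DataFrame(
            columns=[
                "sender_type", "receiver_type", "timepoint", "ligand", "receptor",
                "activity_score", "replicate_scores", "n_background_genes_used",
            ]
        )
    df = pd.DataFrame([dataclasses.asdict(a) for a in activities])
    df["replicate_scores"] = df["replicate_scores"].map(
        lambda r: ";".join(f"{v:.9g}" for v in r)
    )
    df = df.sort_values(
        ["activity_score", "sender_type", "receiver_type", "ligand", "receptor"],
        ascending=[False, True, True, True, True],
        kind="stable",
    )
    return df.reset_index(drop=True)


def sankey_export(activities: list[InteractionActivity]) -> dict:
    """Sankey JSON: cell-type nodes and one sender->receiver link per pair
    with positive activity (weight = activity score)."""
    links = [
        {
            "source": a.sender_type,
            "target": a.receiver_type,
            "ligand": a.ligand,
            "receptor": a.receptor,
            "value": a.activity_score,
        }
        for a in sorted(
            activities,
            key=lambda a: (-a.activity_score, a.sender_type, a.receiver_type, a.ligand, a.receptor),
        )
        if a.activity_score > 0
    ]
    nodes = sorted({l["source"] for l in links} | {l["target"] for l in links})
    return {"nodes": [{"name": n} for n in nodes], "links": links}
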