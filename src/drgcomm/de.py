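"""Per-cell-type differential expression between a timepoint and control.

The test is a two-sided Wilcoxon rank-sum on the log-normalized layer with
midranks for ties, a tie-corrected normal approximation with continuity
correction, and exact enumeration of the rank-sum distribution for small
samples (n + m <= 12). Two selection regimes follow the published analysis:
pseudobulk DE at an adjusted-P cutoff of 1e-20, and ligand-candidate
selection at fold change > 3, detection in > 10% of cells and P < 0.05.
"""

from __future__ import annotations

import logging
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .io import get_lognorm
from .params import PipelineParams

log = logging.getLogger(__name__)

EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Midranks for ties. For n + m <= 12 the null distribution of the rank sum
    is enumerated exactly over all C(n+m, n) group assignments of the pooled
    midranks and p = min(1, 2 * min(P(W <= w), P(W >= w))); otherwise a
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    if n + m <= EXACT_MAX_N:
        return w, _exact_p(ranks, n, w)
    return w, _approx_p(ranks, n, m, w)


def _exact_p(ranks: np.ndarray, n: int, w: float) -> float:
    N = ranks.size
    sums = np.fromiter(
        (ranks[list(idx)].sum() for idx in combinations(range(N), n)),
        dtype=float,
    )
    eps = 1e-9
    c_le = np.count_nonzero(sums <= w + eps)
    c_ge = np.count_nonzero(sums >= w - eps)
    return min(1.0, 2.0 * min(c_le, c_ge) / sums.size)


def _approx_p(ranks: np.ndarray, n: int, m: int, w: float) -> float:
    N = n + m
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _wilcoxon_columns(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Wilcoxon p-values (X1, X2: cells x genes)."""
    n, m = X1.shape[0], X2.shape[0]
    if n + m <= EXACT_MAX_N:
        return np.array(
            [wilcoxon_rank_sum(X1[:, j], X2[:, j])[1] for j in range(X1.shape[1])]
        )
    pooled = np.vstack([X1, X2])
    ranks = rankdata(pooled, axis=0)
    W = ranks[:n].sum(axis=0)
    N = n + m
    mu = n * (N + 1) / 2.0
    tie_term = np.empty(pooled.shape[1])
    for j in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        tie_term[j] = ((counts**3) - counts).sum()
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    diff = W - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2.0 * norm.sf(np.abs(z))
    p[var <= 0] = 1.0
    return np.minimum(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * k / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def p_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``bh`` (default) or ``bonferroni``."""
    if method == "bh":
        return bh_adjust(p_values)
    if method == "bonferroni":
        p = np.asarray(p_values, dtype=float)
        if p.size and (np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p))):
            raise ValueError("p-values must lie in (0, 1]")
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def de_table(
    adata: ad.AnnData,
    cell_type: str,
    timepoint: float,
    reference_timepoint: float = 0.0,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Differential expression of one cell type at one timepoint vs control.

    One record per gene detected in either group. Fold change is the ratio
    of group means on the expm1-of-normalized scale with a tiny pseudocount;
    p-values are two-sided Wilcoxon rank-sum on the normalized layer,
    adjusted within the tested gene set.
    """
    params = params or PipelineParams()
    obs = adata.obs
    in_type = obs["cell_type"].to_numpy() == cell_type
    g_mask = in_type & (obs["timepoint"].to_numpy(dtype=float) == float(timepoint))
    r_mask = in_type & (obs["timepoint"].to_numpy(dtype=float) == float(reference_timepoint))
    n_g, n_r = int(g_mask.sum()), int(r_mask.sum())
    columns = [
        "gene", "cell_type", "timepoint", "fold_change", "log2_fc",
        "pct_expr_group", "pct_expr_ref", "p_value", "adj_p",
    ]
    if n_g < 3 or n_r < 3:
        log.warning(
            "skipping DE for %s at t=%s: %d vs %d cells (< 3 per group)",
            cell_type, timepoint, n_g, n_r,
        )
        return pd.DataFrame(columns=columns)
    X = sp.csr_matrix(adata.X)
    L = get_lognorm(adata, params.normalization_scale)
    pct_g = np.asarray((X[g_mask] > 0).mean(axis=0)).ravel()
    pct_r = np.asarray((X[r_mask] > 0).mean(axis=0)).ravel()
    tested = (pct_g > 0) | (pct_r > 0)
    Lg = np.asarray(L[g_mask][:, tested].todense())
    Lr = np.asarray(L[r_mask][:, tested].todense())
    mean_g = np.expm1(Lg).mean(axis=0)
    mean_r = np.expm1(Lr).mean(axis=0)
    pseudo = params.fc_pseudocount
    fc = (mean_g + pseudo) / (mean_r + pseudo)
    p = _wilcoxon_columns(Lg, Lr)
    adj = p_adjust(p, params.p_adjust_method)
    return pd.DataFrame(
        {
            "gene": np.asarray(adata.var_names)[tested],
            "cell_type": cell_type,
            "timepoint": float(timepoint),
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "pct_expr_group": pct_g[tested],
            "pct_expr_ref": pct_r[tested],
            "p_value": p,
            "adj_p": adj,
        }
    )


def select_pseudobulk_de(records: pd.DataFrame, params: PipelineParams | None = None) -> set[str]:
    """Genes passing the pseudobulk cutoff: adjusted P strictly below 1e-20."""
    params = params or PipelineParams()
    if len(records) == 0:
        return set()
    return set(records.loc[records["adj_p"] < params.pseudobulk_adj_p_max, "gene"])


def select_lr_candidates(records: pd.DataFrame, params: PipelineParams | None = None) -> set[str]:
    """Upregulated ligand-candidate genes: fold change strictly greater than
    3, detected in strictly more than 10% of cells, raw P below 0.05."""
    params = params or PipelineParams()
    if len(records) == 0:
        return set()
    keep = (
        (records["fold_change"] > params.lr_fold_min)
        & (records["pct_expr_group"] > params.lr_pct_min)
        & (records["p_value"] < params.lr_p_max)
    )
    return set(records.loc[keep, "gene"])
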