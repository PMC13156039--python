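"""Shared test utilities: toy dataset builders and independent oracles.

The oracles here are deliberately written from first principles (sorting,
enumeration over combinations) so they stay independent of the package's
implementation paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from drgcomm.io import make_dataset


def toy_adata(
    counts,
    cell_types=None,
    timepoints=None,
    compartments=None,
    is_mito=None,
    gene_symbols=None,
):
    """Build a small validated dataset from a dense cells x genes array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_symbols = gene_symbols or [f"g{j}" for j in range(n_genes)]
    is_mito = list(is_mito) if is_mito is not None else [False] * n_genes
    genes = pd.DataFrame(
        {
            "gene_id": [f"id{j}" for j in range(n_genes)],
            "gene_symbol": gene_symbols,
            "is_mito": is_mito,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "cell_type": cell_types or ["TypeA"] * n_cells,
            "compartment": compartments or ["non_neuronal"] * n_cells,
            "timepoint": timepoints if timepoints is not None else [0.0] * n_cells,
            "condition": ["control"] * n_cells,
        }
    )
    return make_dataset(sp.csr_matrix(counts), genes, cells)


def midranks(values) -> np.ndarray:
    """Midranks computed by explicit sorting (independent of scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def exact_wilcoxon_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    ranks = midranks(np.concatenate([x, y]))
    w = ranks[:n].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(ranks)), n)]
    eps = 1e-9
    c_le = sum(s <= w + eps for s in sums)
    c_ge = sum(s >= w - eps for s in sums)
    return min(1.0, 2.0 * min(c_le, c_ge) / len(sums))


def exact_permutation_p(values, labels) -> float:
    """|mean difference| permutation p by enumerating all label splits."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    assert uniq.size == 2
    n1 = int((labels == uniq[0]).sum())
    observed = abs(values[labels == uniq[0]].mean() - values[labels == uniq[1]].mean())
    count = 0
    total = 0
    idx = range(len(values))
    for group in combinations(idx, n1):
        g = np.zeros(len(values), bool)
        g[list(group)] = True
        stat = abs(values[g].mean() - values[~g].mean())
        count += stat >= observed - 1e-12
        total += 1
    return count / total


def qc_fixture():
    """10-cell fixture with known detected-gene counts and mito fractions.

    Includes the boundary cases: exactly 20% mitochondrial counts (not
    discarded) and exactly 2,000 detected genes (fails the strictly-greater
    primary cutoff, passes the secondary one). Returns (adata, expected)
    where expected is a DataFrame of the pass flags.
    """
    n_genes = 2700  # gene 0 is mitochondrial
    rows = [
        # (n_detected_nonmito, each-count, mito_count) -> flags computed below
        (2001, 1, 0),    # pass both
        (2000, 1, 0),    # exactly 2000 detected: fail primary, pass secondary
        (999, 1, 0),     # fail both
        (1000, 1, 0),    # fail primary, pass secondary
        (2096, 1, 524),  # exactly 20% mito (524/2620), 2097 detected: pass both
        (2600, 1, 691),  # 21.0% mito (691/3291): fail both
        (2500, 2, 0),    # pass both
        (2500, 1, 2500), # 50% mito: fail both
        (1500, 1, 352),  # 19.0% mito (352/1852), 1501 detected: fail primary only
        (500, 3, 0),     # fail both
    ]
    counts = np.zeros((len(rows), n_genes), dtype=int)
    expected = []
    for i, (n_det, per, mito) in enumerate(rows):
        counts[i, 1 : n_det + 1] = per
        counts[i, 0] = mito
        detected = n_det + (1 if mito > 0 else 0)
        mito_frac = mito / (n_det * per + mito)
        expected.append(
            {
                "n_genes_detected": detected,
                "mito_ok": mito_frac <= 0.20,
                "pass_primary": mito_frac <= 0.20 and detected > 2000,
                "pass_secondary": mito_frac <= 0.20 and detected >= 1000,
            }
        )
    adata = toy_adata(counts, is_mito=[True] + [False] * (n_genes - 1))
    return adata, pd.DataFrame(expected)
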