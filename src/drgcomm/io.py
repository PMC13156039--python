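"""Dataset container, normalization, and on-disk fixture layout.

The in-memory container is an :class:`anndata.AnnData` with

* ``X`` — sparse CSR genes-are-columns integer count matrix (cells x genes),
* ``layers["lognorm"]`` — the log-normalized layer (lazily computed),
* ``var`` — gene records: index = unique gene symbol, columns ``gene_id``,
  ``gene_symbol`` (original, possibly duplicated) and ``is_mito``,
* ``obs`` — cell records: index = unique cell id, columns ``cell_type``,
  ``compartment`` (neuronal / non_neuronal / immune), ``timepoint`` (days,
  float) and ``condition``.

On disk a dataset is three text files: ``matrix.mtx`` (Matrix Market,
genes x cells, integer), ``genes.tsv`` and ``cells.tsv``; the simulator adds
``truth.json``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
CELLS_FILE = "cells.tsv"
TRUTH_FILE = "truth.json"

COMPARTMENTS = ("neuronal", "non_neuronal", "immune")

LOGNORM_LAYER = "lognorm"


def validate_dataset(adata: ad.AnnData) -> None:
    """Check the container invariants; raise ``ValueError`` on violation.

    Counts must be integral and non-negative, cell ids unique, gene symbols
    unique (after disambiguation), and the metadata columns present.
    """
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and (data < 0).any():
        raise ValueError("count matrix contains negative entries")
    if data.size and np.any(data != np.floor(data)):
        raise ValueError("count matrix contains non-integer entries")
    if adata.obs_names.has_duplicates:
        dup = adata.obs_names[adata.obs_names.duplicated()][0]
        raise ValueError(f"duplicated cell_id: {dup!r}")
    if adata.var_names.has_duplicates:
        dup = adata.var_names[adata.var_names.duplicated()][0]
        raise ValueError(f"duplicated gene symbol after disambiguation: {dup!r}")
    for col in ("cell_type", "compartment", "timepoint", "condition"):
        if col not in adata.obs.columns:
            raise ValueError(f"cells metadata missing column {col!r}")
    if "is_mito" not in adata.var.columns:
        raise ValueError("gene metadata missing column 'is_mito'")
    bad = set(adata.obs["compartment"].unique()) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment value(s): {sorted(bad)}")


def _deduplicate_symbols(symbols: pd.Series) -> pd.Index:
    """Suffix repeated gene symbols with ``.1``, ``.2``, ... in order."""
    counts: dict[str, int] = {}
    out = []
    for s in symbols.astype(str):
        k = counts.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        counts[s] = k + 1
    return pd.Index(out, name="gene")


def make_dataset(
    counts: sp.spmatrix | np.ndarray,
    genes: pd.DataFrame,
    cells: pd.DataFrame,
) -> ad.AnnData:
    """Assemble and validate an AnnData from a cells x genes count matrix."""
    X = sp.csr_matrix(counts)
    var = genes.copy()
    var.index = _deduplicate_symbols(var["gene_symbol"])
    obs = cells.copy()
    obs.index = pd.Index(obs["cell_id"].astype(str), name="cell")
    adata = ad.AnnData(X=X, obs=obs.drop(columns=["cell_id"]), var=var)
    validate_dataset(adata)
    return adata


def write_dataset(adata: ad.AnnData, directory: str | Path, force: bool = False) -> list[Path]:
    """Write ``matrix.mtx`` (genes x cells), ``genes.tsv`` and ``cells.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / f for f in (MATRIX_FILE, GENES_FILE, CELLS_FILE)]
    existing = [p for p in paths if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {', '.join(p.name for p in existing)}; pass force=True"
        )
    # disk convention is genes x cells (10x-style export)
    scipy.io.mmwrite(str(paths[0]), sp.csr_matrix(adata.X).T.astype(np.int64), field="integer")
    genes = adata.var.reset_index(drop=True)[["gene_id", "gene_symbol", "is_mito"]]
    genes.to_csv(paths[1], sep="\t", index=False)
    cells = adata.obs.reset_index().rename(columns={"cell": "cell_id"})
    cells = cells[["cell_id", "cell_type", "compartment", "timepoint", "condition"]]
    cells.to_csv(paths[2], sep="\t", index=False)
    return paths


def read_dataset(directory: str | Path) -> ad.AnnData:
    """Read a dataset from the three-file fixture layout.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    dimension mismatches, negative or non-integer counts, duplicated cell
    ids, or malformed metadata rows (reported with their line number).
    """
    directory = Path(directory)
    for fname in (MATRIX_FILE, GENES_FILE, CELLS_FILE):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {directory}")
    mat = scipy.io.mmread(str(directory / MATRIX_FILE))  # genes x cells
    genes = pd.read_csv(directory / GENES_FILE, sep="\t", dtype={"gene_symbol": str})
    cells = pd.read_csv(directory / CELLS_FILE, sep="\t")
    for col in ("gene_id", "gene_symbol", "is_mito"):
        if col not in genes.columns:
            raise ValueError(f"{GENES_FILE}: missing column {col!r}")
        bad = genes.index[genes[col].isna()]
        if len(bad):
            raise ValueError(f"{GENES_FILE}: malformed row at line {bad[0] + 2}")
    for col in ("cell_id", "cell_type", "compartment", "timepoint", "condition"):
        if col not in cells.columns:
            raise ValueError(f"{CELLS_FILE}: missing column {col!r}")
        bad = cells.index[cells[col].isna()]
        if len(bad):
            raise ValueError(f"{CELLS_FILE}: malformed row at line {bad[0] + 2}")
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape[0]} genes x {mat.shape[1]} cells "
            f"but genes.tsv has {len(genes)} rows and cells.tsv has {len(cells)} rows"
        )
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated cell_id: {dup.iloc[0]!r}")
    genes["is_mito"] = genes["is_mito"].astype(bool)
    cells["timepoint"] = cells["timepoint"].astype(float)
    return make_dataset(sp.csr_matrix(mat).T, genes, cells)


def log_normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Attach the log-normalized layer: ``ln(1 + count * scale / cell_total)``.

    Per-cell library-size scaling to ``scale`` total counts followed by
    natural log1p. Cells with zero total counts get an all-zero row and a
    warning. Returns the same AnnData (modified in place) for chaining.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total counts; "
            "their normalized values are all zero",
            stacklevel=2,
        )
    factors = np.divide(scale, totals, out=np.zeros_like(totals), where=~zero)
    norm = sp.diags(factors) @ X
    norm.data = np.log1p(norm.data)
    adata.layers[LOGNORM_LAYER] = sp.csr_matrix(norm)
    return adata


def get_lognorm(adata: ad.AnnData, scale: float = 1e4) -> sp.csr_matrix:
    """Return the log-normalized layer, computing it if absent."""
    if LOGNORM_LAYER not in adata.layers:
        log_normalize(adata, scale=scale)
    return adata.layers[LOGNORM_LAYER]
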