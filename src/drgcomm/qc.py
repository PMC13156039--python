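"""Cell-level quality control, neuron purification, and label transfer.

QC follows the published rules: cells with more than 20% of counts from
mitochondrial genes are discarded; the primary dataset keeps cells with more
than 2,000 detected genes, the secondary dataset cells with at least 1,000.
Neuron candidates are purified on the normalized layer (Rbfox3 / Apoe
thresholds). Cell-type labels are transferred with a nearest-centroid
prototype classifier whose softmax prediction score is thresholded at 0.55;
cells below threshold are left unassigned.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import get_lognorm
from .params import PipelineParams

UNASSIGNED = "unassigned"


def compute_qc(adata: ad.AnnData, params: PipelineParams | None = None) -> pd.DataFrame:
    """Per-cell QC: detected genes, mitochondrial fraction, pass flags.

    ``pass_primary`` requires mito fraction not above 20% (cells with *more*
    than 20% are discarded) and *more* than 2,000 detected genes;
    ``pass_secondary`` relaxes the gene cutoff to *at least* 1,000. A gene is
    detected when its count is > 0.
    """
    params = params or PipelineParams()
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var["is_mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    mito_ok = mito_fraction <= params.mito_max_fraction
    return pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "n_genes_detected": n_detected.astype(int),
            "mito_fraction": mito_fraction,
            "pass_primary": mito_ok & (n_detected > params.min_genes_primary),
            "pass_secondary": mito_ok & (n_detected >= params.min_genes_secondary),
        }
    ).reset_index(drop=True)


def filter_neuron_candidates(
    adata: ad.AnnData,
    neuron_cells: pd.Index | list[str] | None = None,
    params: PipelineParams | None = None,
    rbfox3: str = "Rbfox3",
    apoe: str = "Apoe",
) -> pd.Index:
    """Purify putative neurons on the normalized layer.

    A cell is removed when its normalized ``Rbfox3`` is below 0.5 or its
    normalized ``Apoe`` is above 2 (the default ``any`` mode; ``all`` mode
    requires both criteria to remove). Returns the retained cell ids.
    """
    params = params or PipelineParams()
    for marker in (rbfox3, apoe):
        if marker not in adata.var_names:
            raise KeyError(f"marker gene {marker!r} not present in the dataset")
    cells = pd.Index(neuron_cells) if neuron_cells is not None else adata.obs_names
    L = get_lognorm(adata, params.normalization_scale)
    idx = adata.obs_names.get_indexer(cells)
    r = np.asarray(L[idx, adata.var_names.get_loc(rbfox3)].todense()).ravel()
    a = np.asarray(L[idx, adata.var_names.get_loc(apoe)].todense()).ravel()
    low_rbfox3 = r < params.rbfox3_min_norm
    high_apoe = a > params.apoe_max_norm
    remove = (low_rbfox3 | high_apoe) if params.neuron_filter_mode == "any" else (low_rbfox3 & high_apoe)
    return cells[~remove]


class PrototypeClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid label transfer with a softmax prediction score.

    Stands in for a mixture-discriminant label-transfer model with the same
    contract: a label, a calibrated score in [0, 1], and a score threshold.
    Fitting selects the ``n_top_genes`` most variable features, stores one
    centroid per label in normalized space, and scoring applies a softmax
    over negative Euclidean centroid distances — a query on a centroid of a
    well-separated reference scores near 1, a query equidistant between two
    centroids scores 0.5.

    The softmax is the Gaussian posterior under an isotropic within-class
    model: logits are -d_k^2 / (2 sigma^2), with sigma^2 the pooled
    within-class per-feature variance of the reference. Well-separated
    references therefore score near 1 on their own cells, while exact ties
    (e.g. duplicated cells across labels) score symmetrically regardless of
    scale. A degenerate zero variance falls back to 1.

    Parameters
    ----------
    n_top_genes : number of most-variable features kept (all if fewer).
    min_cells_per_label : labels with fewer reference cells are an error.
    """

    def __init__(self, n_top_genes: int = 500, min_cells_per_label: int = 3):
        self.n_top_genes = n_top_genes
        self.min_cells_per_label = min_cells_per_label

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 labels to fit")
        if counts.min() < self.min_cells_per_label:
            bad = classes[counts.argmin()]
            raise ValueError(
                f"label {bad!r} has {counts.min()} cells (< {self.min_cells_per_label})"
            )
        variances = X.var(axis=0)
        k = min(self.n_top_genes, X.shape[1])
        order = np.argsort(-variances, kind="stable")
        self.feature_idx_ = np.sort(order[:k])
        self.classes_ = classes
        self.centroids_ = np.vstack(
            [X[np.asarray(y) == c][:, self.feature_idx_].mean(axis=0) for c in classes]
        )
        self.n_features_in_ = X.shape[1]
        within_var = np.concatenate(
            [X[np.asarray(y) == c][:, self.feature_idx_].var(axis=0) for c in classes]
        )
        v = float(within_var.mean())
        self.within_variance_ = v if v > 0 else 1.0
        return self

    def _distances(self, X, validate: bool = True):
        check_is_fitted(self, "centroids_")
        if validate:
            X = check_array(X, dtype=np.float64)
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"gene-universe mismatch: query has {X.shape[1]} features, "
                    f"classifier was fitted on {self.n_features_in_}"
                )
        Xs = X[:, self.feature_idx_]
        d2 = ((Xs[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2)

    def predict_proba(self, X):
        d2 = self._distances(X) ** 2
        z = -(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * self.within_variance_)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


def fit_prototype_classifier(
    reference: ad.AnnData,
    label_column: str = "cell_type",
    params: PipelineParams | None = None,
    n_top_genes: int = 500,
) -> PrototypeClassifier:
    """Fit the prototype classifier on a labeled reference dataset."""
    params = params or PipelineParams()
    L = get_lognorm(reference, params.normalization_scale)
    clf = PrototypeClassifier(n_top_genes=n_top_genes)
    clf.fit(np.asarray(L.todense()), reference.obs[label_column].to_numpy())
    clf.gene_universe_ = np.asarray(reference.var_names)
    return clf


def assign_labels(
    clf: PrototypeClassifier,
    query: ad.AnnData,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Transfer labels to a query dataset; score < 0.55 becomes unassigned."""
    params = params or PipelineParams()
    if query.n_obs == 0:
        return pd.DataFrame(columns=["cell_id", "label", "prediction_score"])
    universe = getattr(clf, "gene_universe_", None)
    if universe is not None and not np.array_equal(universe, np.asarray(query.var_names)):
        raise ValueError("gene-universe mismatch between classifier reference and query")
    L = get_lognorm(query, params.normalization_scale)
    proba = clf.predict_proba(np.asarray(L.todense()))
    scores = proba.max(axis=1)
    labels = clf.classes_[proba.argmax(axis=1)].astype(object)
    labels[scores < params.prediction_score_min] = UNASSIGNED
    return pd.DataFrame(
        {"cell_id": query.obs_names, "label": labels, "prediction_score": scores}
    ).reset_index(drop=True)
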