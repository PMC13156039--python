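"""Cell-type composition per timepoint and fold change versus control.

Fractions are computed within a compartment (immune, non_neuronal,
neuronal, or "all"), matching how immune percentages are reported: the
monocyte influx takes monocytes from ~3.5% of immune cells at baseline to
~65% at 6-12 h (~20-fold). Fold-change intervals use the normal
approximation on the log ratio of two independent binomial proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FoldChange:
    cell_type: str
    timepoint: float
    reference_timepoint: float
    fraction: float
    reference_fraction: float
    ratio: float
    ci_low: float
    ci_high: float


def composition_table(annotation: pd.DataFrame, compartment: str = "immune") -> pd.DataFrame:
    """Cell counts and within-compartment fractions per timepoint.

    ``annotation`` needs columns ``cell_type``, ``compartment`` and
    ``timepoint``. ``compartment="all"`` uses every cell. A timepoint with
    no cells in the compartment is an error naming the timepoint.
    """
    df = annotation if compartment == "all" else annotation[annotation["compartment"] == compartment]
    timepoints = sorted(annotation["timepoint"].astype(float).unique())
    empty = [tp for tp in timepoints if not (df["timepoint"].astype(float) == tp).any()]
    if empty:
        raise ValueError(f"no cells in compartment {compartment!r} at timepoint {empty[0]}")
    counts = (
        df.groupby(["timepoint", "cell_type"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    counts["timepoint"] = counts["timepoint"].astype(float)
    totals = counts.groupby("timepoint")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts.sort_values(["timepoint", "cell_type"], kind="stable").reset_index(drop=True)


def composition_fold_change(
    table: pd.DataFrame,
    cell_type: str,
    timepoint: float,
    reference_timepoint: float = 0.0,
    confidence: float = 0.95,
) -> FoldChange:
    """Ratio of within-compartment fractions with a binomial CI on the log
    ratio. The reference fraction must be positive."""
    from scipy.stats import norm

    def fraction_at(tp: float) -> tuple[float, int]:
        rows = table[table["timepoint"].astype(float) == float(tp)]
        if len(rows) == 0:
            raise ValueError(f"timepoint {tp} not in composition table")
        n_total = int(rows["n_cells"].sum())
        hit = rows[rows["cell_type"] == cell_type]
        n = int(hit["n_cells"].sum()) if len(hit) else 0
        return n / n_total, n_total

    p1, n1 = fraction_at(timepoint)
    p0, n0 = fraction_at(reference_timepoint)
    if p0 == 0:
        raise ValueError(
            f"reference fraction of {cell_type!r} at t={reference_timepoint} is zero; "
            "fold change undefined"
        )
    if p1 == 0:
        raise ValueError(f"fraction of {cell_type!r} at t={timepoint} is zero")
    ratio = p1 / p0
    se_log = np.sqrt((1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0))
    z = norm.ppf(0.5 + confidence / 2)
    return FoldChange(
        cell_type=cell_type,
        timepoint=float(timepoint),
        reference_timepoint=float(reference_timepoint),
        fraction=p1,
        reference_fraction=p0,
        ratio=ratio,
        ci_low=float(ratio * np.exp(-z * se_log)),
        ci_high=float(ratio * np.exp(z * se_log)),
    )
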