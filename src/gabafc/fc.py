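"""Fractional-contribution (FC) statistics over the subunit panel.

The FC of a subunit gene is its share, in percent, of the expression of
the whole 19-gene panel.  Three estimators are provided, differing in
what is pooled:

* **FC1** — per cell: each cell's panel counts are converted to
  percentages (summing to 100); the dataset statistic is the mean +/- SD
  over cells, restricted to *defined* cells (cells with any panel
  expression).  FC1 is invariant to per-cell depth.
* **FC2** — per dataset: panel counts are pooled over all cells first,
  then converted to percentages.  FC2 weighs cells by depth and is *not*
  depth-invariant.
* **FC3** — detection: the percentage of cells (out of *all* cells in the
  gated input, including panel-silent ones) in which each panel gene is
  detected.  Note the denominator differs from FC1's, which excludes
  panel-silent cells.

Cross-dataset aggregation averages datasets as units (unweighted mean,
SE over datasets); a cell-weighted alternative is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, IntegrityError, PreconditionError
from .matrix import ExpressionMatrix
from .panel import SubunitPanel, default_panel

FC_STATISTICS = ("fc1_mean", "fc2", "fc3")


@dataclass(frozen=True)
class CellFCProfile:
    """Per-cell fractional contributions (percent, summing to 100).

    ``defined`` is False for cells with zero total panel expression, in
    which case ``fc`` is empty.
    """

    cell_id: str
    fc: dict[str, float]
    defined: bool


@dataclass
class DatasetFCSummary:
    """Per-dataset FC table: one row per panel gene.

    ``table`` columns: fc1_mean, fc1_sd, fc1_se, fc2, fc3 (percent);
    columns not computed by the producing call are NaN.
    """

    dataset_id: str
    table: pd.DataFrame
    n_cells_total: int
    n_cells_defined: int

    def __post_init__(self) -> None:
        if self.n_cells_defined > self.n_cells_total:
            raise IntegrityError("n_cells_defined exceeds n_cells_total")


@dataclass
class CrossDatasetFCTable:
    """Datasets (rows) by panel genes (columns) for one FC statistic."""

    statistic: str
    table: pd.DataFrame          # rows: dataset labels, cols: panel genes
    grand_mean: pd.Series        # per-gene mean across datasets
    grand_se: pd.Series          # per-gene SE across datasets (NaN at n=1)
    n_datasets: int
    weighted_by_cells: bool = False
    row_meta: pd.DataFrame | None = field(default=None)


def _panel_values(m: ExpressionMatrix, panel: SubunitPanel) -> np.ndarray:
    return m.values[:, m.gene_indices(panel.genes)]


def fc1_cell(
    values, panel: SubunitPanel | None = None, cell_id: str = ""
) -> CellFCProfile:
    """FC of one cell: 100 * x_g / sum(x) over the panel."""
    panel = panel or default_panel()
    x = np.asarray(values, dtype=float)
    if x.shape != (len(panel),):
        raise PreconditionError(
            f"expected {len(panel)} panel values, got shape {x.shape}"
        )
    if (x < 0).any():
        raise PreconditionError("negative panel values")
    total = x.sum()
    if total <= 0:
        return CellFCProfile(cell_id=cell_id, fc={}, defined=False)
    fc = dict(zip(panel.genes, (100.0 * x / total).tolist()))
    return CellFCProfile(cell_id=cell_id, fc=fc, defined=True)


def fc1_profiles(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> pd.DataFrame:
    """Per-cell FC1 table over defined cells only (rows sum to 100)."""
    panel = panel or default_panel()
    P = _panel_values(m, panel)
    totals = P.sum(axis=1)
    defined = totals > 0
    F = 100.0 * P[defined] / totals[defined, None]
    return pd.DataFrame(
        F,
        index=[c for c, d in zip(m.cell_ids, defined) if d],
        columns=panel.genes,
    )


def _empty_summary_table(panel: SubunitPanel) -> pd.DataFrame:
    return pd.DataFrame(
        np.nan,
        index=pd.Index(panel.genes, name="gene"),
        columns=["fc1_mean", "fc1_sd", "fc1_se", "fc2", "fc3"],
    )


def fc1_dataset(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> DatasetFCSummary:
    """Mean/SD/SE of per-cell FC over the dataset's defined cells.

    Sample (n-1) SD; at a single defined cell SD and SE are NaN, never 0.
    """
    panel = panel or default_panel()
    P = _panel_values(m, panel)
    totals = P.sum(axis=1)
    defined = totals > 0
    n_def = int(defined.sum())
    if n_def == 0:
        raise EstimationError(
            f"{m.dataset_id}: no cell expresses any panel gene; FC1 undefined"
        )
    F = 100.0 * P[defined] / totals[defined, None]
    table = _empty_summary_table(panel)
    table["fc1_mean"] = F.mean(axis=0)
    if n_def > 1:
        table["fc1_sd"] = F.std(axis=0, ddof=1)
        table["fc1_se"] = table["fc1_sd"] / np.sqrt(n_def)
    return DatasetFCSummary(
        dataset_id=m.dataset_id,
        table=table,
        n_cells_total=m.n_cells,
        n_cells_defined=n_def,
    )


def fc2_dataset(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> DatasetFCSummary:
    """Pooled FC: 100 * pooled count of gene g / pooled panel total."""
    panel = panel or default_panel()
    P = _panel_values(m, panel)
    pooled = P.sum(axis=0)
    total = pooled.sum()
    table = _empty_summary_table(panel)
    table["fc2"] = 100.0 * pooled / total if total > 0 else np.nan
    totals = P.sum(axis=1)
    return DatasetFCSummary(
        dataset_id=m.dataset_id,
        table=table,
        n_cells_total=m.n_cells,
        n_cells_defined=int((totals > 0).sum()),
    )


def fc3_dataset(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> DatasetFCSummary:
    """Detection FC: percent of all cells with count > 0 per panel gene."""
    panel = panel or default_panel()
    if m.n_cells == 0:
        raise PreconditionError(f"{m.dataset_id}: empty matrix")
    P = _panel_values(m, panel)
    table = _empty_summary_table(panel)
    table["fc3"] = 100.0 * (P > 0).mean(axis=0)
    return DatasetFCSummary(
        dataset_id=m.dataset_id,
        table=table,
        n_cells_total=m.n_cells,
        n_cells_defined=int((P.sum(axis=1) > 0).sum()),
    )


def summarize_dataset(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> DatasetFCSummary:
    """All three FC statistics for one dataset in a single table."""
    panel = panel or default_panel()
    s1 = fc1_dataset(m, panel)
    s2 = fc2_dataset(m, panel)
    s3 = fc3_dataset(m, panel)
    table = s1.table.copy()
    table["fc2"] = s2.table["fc2"]
    table["fc3"] = s3.table["fc3"]
    return DatasetFCSummary(
        dataset_id=m.dataset_id,
        table=table,
        n_cells_total=m.n_cells,
        n_cells_defined=s1.n_cells_defined,
    )


def aggregate_fc(
    summaries: list[DatasetFCSummary],
    statistic: str = "fc1_mean",
    weight_by_cells: bool = False,
    row_labels: list[str] | None = None,
) -> CrossDatasetFCTable:
    """Stack per-dataset FC vectors and average across datasets.

    Datasets are averaged as units (unweighted) by default; with
    ``weight_by_cells`` the grand mean weighs each dataset by its defined
    cell count.  SE is the across-dataset SD / sqrt(n_datasets), NaN at
    a single dataset.
    """
    if statistic not in FC_STATISTICS:
        raise PreconditionError(
            f"statistic must be one of {FC_STATISTICS}, got {statistic!r}"
        )
    if not summaries:
        raise PreconditionError("at least one dataset summary required")
    genes0 = list(summaries[0].table.index)
    for s in summaries[1:]:
        if list(s.table.index) != genes0:
            raise IntegrityError(
                f"dataset {s.dataset_id}: panel differs from {summaries[0].dataset_id}"
            )
    labels = row_labels or [s.dataset_id for s in summaries]
    if len(set(labels)) != len(labels):
        raise IntegrityError("duplicate row labels in cross-dataset table")
    table = pd.DataFrame(
        [s.table[statistic].to_numpy() for s in summaries],
        index=pd.Index(labels, name="dataset"),
        columns=genes0,
    )
    n = len(summaries)
    if weight_by_cells:
        w = np.array([s.n_cells_defined for s in summaries], dtype=float)
        grand_mean = pd.Series(
            np.average(table.to_numpy(), axis=0, weights=w), index=genes0
        )
    else:
        grand_mean = table.mean(axis=0)
    grand_se = (
        table.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else pd.Series(np.nan, index=genes0)
    )
    meta = pd.DataFrame(
        {
            "n_cells_total": [s.n_cells_total for s in summaries],
            "n_cells_defined": [s.n_cells_defined for s in summaries],
        },
        index=table.index,
    )
    return CrossDatasetFCTable(
        statistic=statistic,
        table=table,
        grand_mean=grand_mean,
        grand_se=grand_se,
        n_datasets=n,
        weighted_by_cells=weight_by_cells,
        row_meta=meta,
    )
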