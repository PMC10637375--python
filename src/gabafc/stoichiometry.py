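"""Correlation-based stoichiometry inference and segregation clustering.

Subunits that co-assemble into the same receptor pentamers should covary
across datasets, so candidate co-assembly is read off a pairwise Pearson
correlation matrix of subunit FC values (correlation is evidence, not
proof, of physical co-assembly).  The correlation structure is summarised
by average-linkage (UPGMA) clustering under the correlation distance
``d = 1 - r``.

Segregation analysis asks whether cell types carry distinct panel
signatures: rows (dataset x cell-type FC vectors) are robustly
standardised per gene (median / scaled MAD) and clustered two-way with
Euclidean distance and average linkage; cutting the row tree at k
clusters is scored against the annotated cell types with the adjusted
Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .errors import EstimationError, PreconditionError
from .fc import CrossDatasetFCTable

#: normal-consistency constant: MAD * 1.4826 estimates sigma for Gaussians
MAD_CONSISTENCY = 1.4826

CORRELATION_MODES = ("dataset_means", "per_cell")


@dataclass
class CorrelationResult:
    """Pairwise Pearson structure over the subunit panel.

    ``r`` and ``p`` are symmetric gene-by-gene frames; zero-variance
    genes give NaN rows/columns.  ``p`` is the two-sided p-value from the
    t transform with ``n_obs - 2`` degrees of freedom.  No
    multiple-testing correction is applied to the subunit pairs.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_obs: int
    mode: str


@dataclass
class ClusterResult:
    """Agglomerative merge tree in scipy linkage form.

    ``linkage`` rows are (index_a, index_b, height, size); ``leaf_order``
    is the dendrogram leaf permutation used for heatmaps.  ``excluded``
    lists items dropped before clustering (e.g. all-NaN correlation
    columns).
    """

    items: list[str]
    linkage: np.ndarray
    leaf_order: np.ndarray
    distance_name: str
    linkage_name: str = "average"
    excluded: list[str] = field(default_factory=list)

    def labels_at_k(self, k: int) -> pd.Series:
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.items, name=f"cluster_k{k}")


@dataclass
class SegregationResult:
    """Two-way clustering of FC rows plus agreement with annotations."""

    standardized: pd.DataFrame
    row_cluster: ClusterResult
    col_cluster: ClusterResult
    row_labels_k: pd.Series
    ari: float
    flagged_constant_genes: list[str] = field(default_factory=list)


def _pearson_with_p(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-pairwise Pearson r and two-sided p (t with n-2 df).

    Zero-variance columns yield NaN.  r is clipped to [-1, 1] against
    floating-point overshoot; |r| = 1 gives p = 0.
    """
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    ss = (Xc**2).sum(axis=0)
    sd = np.sqrt(ss)
    valid = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / np.outer(sd, sd)
    r[~valid, :] = np.nan
    r[:, ~valid] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, np.nan)
    return r, p


def subunit_correlation(
    table: CrossDatasetFCTable | pd.DataFrame, mode: str = "dataset_means"
) -> CorrelationResult:
    """Pearson correlation of subunit FC columns over observations (rows).

    ``dataset_means`` treats datasets (or dataset x cell-type rows) as
    observations; ``per_cell`` treats defined cells as observations (pass
    a per-cell FC frame from :func:`gabafc.fc.fc1_profiles`).  Fewer than
    3 observations refuse with an estimation error — with 2 rows every
    correlation is +/-1 by construction and would be pure artifact.
    """
    if mode not in CORRELATION_MODES:
        raise PreconditionError(f"mode must be one of {CORRELATION_MODES}")
    df = table.table if isinstance(table, CrossDatasetFCTable) else table
    n = len(df)
    if n < 3:
        raise EstimationError(
            f"{mode} correlation requires >= 3 observations, got {n}"
        )
    X = df.to_numpy(dtype=float)
    r, p = _pearson_with_p(X)
    genes = list(df.columns)
    return CorrelationResult(
        r=pd.DataFrame(r, index=genes, columns=genes),
        p=pd.DataFrame(p, index=genes, columns=genes),
        n_obs=n,
        mode=mode,
    )


def cluster_correlation(c: CorrelationResult) -> ClusterResult:
    """UPGMA clustering of subunits under correlation distance 1 - r.

    Genes whose correlations are all NaN (zero variance across
    observations) are excluded and listed in the result.
    """
    r = c.r.to_numpy(dtype=float)
    genes = list(c.r.columns)
    off_diag_ok = ~np.all(np.isnan(r) | np.eye(len(genes), dtype=bool), axis=0)
    usable = [g for g, ok in zip(genes, off_diag_ok) if ok]
    excluded = [g for g, ok in zip(genes, off_diag_ok) if not ok]
    if len(usable) < 2:
        raise EstimationError(
            f"need >= 2 subunits with defined correlations, got {len(usable)}"
        )
    sub = c.r.loc[usable, usable].to_numpy(dtype=float)
    d = 1.0 - sub
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize against rounding
    Z = sch.linkage(ssd.squareform(d, checks=False), method="average")
    return ClusterResult(
        items=usable,
        linkage=Z,
        leaf_order=np.asarray(sch.leaves_list(Z)),
        distance_name="correlation",
        excluded=excluded,
    )


def robust_standardize(
    table: CrossDatasetFCTable | pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-column robust z-score: (x - median) / (1.4826 * MAD).

    MAD is the median absolute deviation from the column median.
    Columns with MAD = 0 (at least half the values tied at the median)
    are set to all zeros and returned in the flag list.
    """
    df = table.table if isinstance(table, CrossDatasetFCTable) else table
    if len(df) < 2:
        raise PreconditionError("robust standardization requires >= 2 rows")
    med = df.median(axis=0)
    mad = (df - med).abs().median(axis=0)
    flagged = list(df.columns[mad == 0])
    scale = MAD_CONSISTENCY * mad
    out = (df - med) / scale.replace(0, np.nan)
    out[flagged] = 0.0
    return out, flagged


def _euclidean_upgma(X: np.ndarray, items: list[str]) -> ClusterResult:
    Z = sch.linkage(X, method="average", metric="euclidean")
    return ClusterResult(
        items=items,
        linkage=Z,
        leaf_order=np.asarray(sch.leaves_list(Z)),
        distance_name="euclidean",
    )


def segregation_cluster(
    table: pd.DataFrame,
    cell_types: pd.Series | None = None,
    k: int = 2,
) -> SegregationResult:
    """Two-way clustering of robust-standardised FC rows.

    ``table`` rows are dataset x cell-type FC vectors; ``cell_types``
    (aligned to rows) gives the annotated type per row.  Rows and columns
    are clustered with Euclidean distance and average linkage after
    robust standardisation; the row tree cut at ``k`` is compared to the
    annotations with the adjusted Rand index.  A single annotated type
    yields ARI = NaN while the clustering itself is still returned.
    """
    from sklearn.metrics import adjusted_rand_score

    if len(table) < 2:
        raise PreconditionError("segregation requires >= 2 rows")
    std, flagged = robust_standardize(table)
    X = std.to_numpy(dtype=float)
    row_cluster = _euclidean_upgma(X, list(table.index))
    col_cluster = _euclidean_upgma(X.T, list(table.columns))
    labels = row_cluster.labels_at_k(k)
    if cell_types is None or pd.Series(cell_types).nunique() < 2:
        ari = float("nan")
    else:
        truth = pd.Series(cell_types).reindex(table.index)
        ari = float(adjusted_rand_score(truth.to_numpy(), labels.to_numpy()))
    return SegregationResult(
        standardized=std,
        row_cluster=row_cluster,
        col_cluster=col_cluster,
        row_labels_k=labels,
        ari=ari,
        flagged_constant_genes=flagged,
    )


def plot_correlation_heatmap(c: CorrelationResult, cluster: ClusterResult, path):
    """Render the clustered correlation matrix to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [cluster.items[i] for i in cluster.leaf_order]
    mat = c.r.loc[order, order]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
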