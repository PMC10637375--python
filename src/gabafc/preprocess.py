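"""Quality control and normalisation of count matrices.

The QC step mirrors the standard droplet single-cell recipe: drop cells
with too few or too many detected genes or a high mitochondrial count
fraction, then drop genes detected in too few of the remaining cells.
The filter order is fixed — cells first, then genes — and the step is
idempotent.

``log_normalize`` applies the standard per-cell depth normalisation
``ln(1 + scale_factor * x / total)`` (natural log, default scale factor
10,000), after which the matrix is tagged ``LOGNORM`` and count-based QC
refuses to run on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError, ValidationError
from .matrix import COUNT_UNITS, ExpressionMatrix, Unit, mito_fractions
from .panel import SubunitPanel

logger = logging.getLogger("gabafc.preprocess")


@dataclass(frozen=True)
class QCParams:
    """Cell- and gene-level quality-control thresholds.

    ``min_features <= detected genes < max_features`` keeps a cell;
    ``mito_fraction * 100 < max_mito_pct`` keeps a cell;
    genes must be detected in at least ``min_cells_per_gene`` retained cells.
    ``scale_factor`` parameterises :func:`log_normalize`.
    """

    min_cells_per_gene: int = 3
    min_features: int = 200
    max_features: int = 3000
    max_mito_pct: float = 5.0
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.min_features < self.max_features:
            raise ValidationError(
                f"min_features ({self.min_features}) must be < max_features "
                f"({self.max_features})"
            )
        if not 0 <= self.max_mito_pct <= 100:
            raise ValidationError("max_mito_pct must be in [0, 100]")
        if not self.scale_factor > 0:
            raise ValidationError("scale_factor must be positive")


def harmonize_symbols(
    m: ExpressionMatrix,
    aliases: dict[str, str] | None = None,
    panel: SubunitPanel | None = None,
) -> ExpressionMatrix:
    """Rename gene symbols to canonical form and zero-pad missing panel genes.

    Columns whose symbols map (via ``aliases``) to the same canonical
    symbol are summed — total counts per cell are conserved.  When a
    ``panel`` is given, any panel gene absent from the dataset is appended
    as an all-zero column (logged), so every panel statistic downstream is
    well defined.
    """
    aliases = aliases or {}
    canonical = [aliases.get(g, g) for g in m.gene_symbols]

    out_symbols: list[str] = []
    positions: dict[str, list[int]] = {}
    for j, sym in enumerate(canonical):
        if sym not in positions:
            positions[sym] = []
            out_symbols.append(sym)
        positions[sym].append(j)

    values = np.zeros((m.n_cells, len(out_symbols)), dtype=float)
    for k, sym in enumerate(out_symbols):
        cols = positions[sym]
        values[:, k] = m.values[:, cols].sum(axis=1) if len(cols) > 1 else m.values[:, cols[0]]
        if len(cols) > 1:
            logger.info(
                "%s: merged %d columns into %s", m.dataset_id, len(cols), sym
            )

    if panel is not None:
        present = set(out_symbols)
        missing = [g for g in panel.genes if g not in present]
        if missing:
            logger.info(
                "%s: panel genes absent, zero-padded: %s", m.dataset_id, missing
            )
            values = np.hstack([values, np.zeros((m.n_cells, len(missing)))])
            out_symbols = out_symbols + missing

    return ExpressionMatrix(
        dataset_id=m.dataset_id,
        cell_ids=list(m.cell_ids),
        gene_symbols=out_symbols,
        values=values,
        unit=m.unit,
        cell_meta=m.cell_meta,
    )


def qc_filter(m: ExpressionMatrix, params: QCParams | None = None) -> ExpressionMatrix:
    """Apply cell-level then gene-level QC filters to a count matrix.

    Cells are retained when ``min_features <= n detected genes <
    max_features`` and the mitochondrial percentage is below
    ``max_mito_pct``; genes are then retained when detected (count > 0)
    in at least ``min_cells_per_gene`` remaining cells.  "Detected" means
    count strictly greater than zero throughout.
    """
    params = params or QCParams()
    if m.unit not in COUNT_UNITS:
        raise PreconditionError(
            f"qc_filter operates on count units, got {m.unit.value}"
        )
    n_features = (m.values > 0).sum(axis=1)
    mito_pct = mito_fractions(m) * 100.0
    keep_cells = (
        (n_features >= params.min_features)
        & (n_features < params.max_features)
        & (mito_pct < params.max_mito_pct)
    )
    sub = m.subset_cells(keep_cells)
    cells_per_gene = (sub.values > 0).sum(axis=0)
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    out = sub.subset_genes([g for g, k in zip(sub.gene_symbols, keep_genes) if k])
    logger.info(
        "%s: QC kept %d/%d cells, %d/%d genes",
        m.dataset_id, out.n_cells, m.n_cells, out.n_genes, m.n_genes,
    )
    return out


def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalise and log-transform: ``x -> ln(1 + sf * x / total)``.

    Every cell must have a positive total count; a zero-total cell is a
    contract violation and the error names the offending cell.
    """
    if m.unit not in COUNT_UNITS:
        raise PreconditionError(
            f"log_normalize operates on count units, got {m.unit.value}"
        )
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise PreconditionError(
            f"cell(s) with zero total count: {[m.cell_ids[i] for i in zero[:5]]}"
        )
    values = np.log1p(scale_factor * m.values / totals[:, None])
    return ExpressionMatrix(
        dataset_id=m.dataset_id,
        cell_ids=list(m.cell_ids),
        gene_symbols=list(m.gene_symbols),
        values=values,
        unit=Unit.LOGNORM,
        cell_meta=m.cell_meta,
    )
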