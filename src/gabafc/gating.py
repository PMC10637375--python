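"""Marker- and label-based cell selection.

Oligodendrocyte progenitor cells (OPCs) are gated as PDGFRA-positive
cells; other populations (e.g. neurons) can be selected by the cell-type
labels carried in ``cell_meta``.  Gating is a pure row filter — expression
values are never modified.
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeneLookupError, PreconditionError
from .matrix import ExpressionMatrix
from .panel import SubunitPanel, default_panel

logger = logging.getLogger("gabafc.gating")

OPC_MARKER = "PDGFRA"


@dataclass(frozen=True)
class GateResult:
    """Outcome of a marker gate on one dataset."""

    parent_dataset_id: str
    marker: str
    selected_cell_ids: tuple[str, ...]
    n_total: int

    @property
    def n_selected(self) -> int:
        return len(self.selected_cell_ids)

    @property
    def fraction_selected(self) -> float:
        return self.n_selected / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class PanelExpressionSummary:
    """How many gated cells express any / each panel gene."""

    n_cells: int
    n_expressing_any: int
    per_gene_expressing: dict[str, int]

    @property
    def fraction_expressing(self) -> float:
        return self.n_expressing_any / self.n_cells if self.n_cells else float("nan")


def select_marker_positive(
    m: ExpressionMatrix,
    marker: str = OPC_MARKER,
    min_value: float | None = None,
) -> tuple[GateResult, ExpressionMatrix]:
    """Select cells expressing ``marker``.

    Default positivity is any expression (value > 0, i.e. one UMI
    suffices).  ``min_value`` raises the threshold to ``value >=
    min_value`` for sensitivity analyses.  An absent marker raises
    :class:`GeneLookupError` listing near-miss symbols.
    """
    if marker not in m.gene_symbols:
        near = difflib.get_close_matches(marker, m.gene_symbols, n=5, cutoff=0.6)
        raise GeneLookupError(marker, near)
    col = m.column(marker)
    mask = col > 0 if min_value is None else col >= min_value
    subset = m.subset_cells(mask)
    result = GateResult(
        parent_dataset_id=m.dataset_id,
        marker=marker,
        selected_cell_ids=tuple(subset.cell_ids),
        n_total=m.n_cells,
    )
    logger.info(
        "%s: %s gate selected %d/%d cells",
        m.dataset_id, marker, result.n_selected, result.n_total,
    )
    return result, subset


def select_by_label(m: ExpressionMatrix, label: str) -> ExpressionMatrix:
    """Select cells whose ``cell_type_label`` equals ``label``.

    An absent label yields an empty subset with a warning, not an error.
    """
    if "cell_type_label" not in m.cell_meta.columns:
        raise PreconditionError(
            f"{m.dataset_id}: cell_meta carries no cell_type_label column"
        )
    mask = (m.cell_meta["cell_type_label"] == label).to_numpy(dtype=bool)
    if not mask.any():
        warnings.warn(
            f"{m.dataset_id}: no cell carries label {label!r}", stacklevel=2
        )
        logger.warning("%s: no cell carries label %r", m.dataset_id, label)
    return m.subset_cells(mask)


def panel_expression_summary(
    m: ExpressionMatrix, panel: SubunitPanel | None = None
) -> PanelExpressionSummary:
    """Count cells expressing at least one, and each, panel gene."""
    panel = panel or default_panel()
    idx = m.gene_indices(panel.genes)
    detected = m.values[:, idx] > 0
    return PanelExpressionSummary(
        n_cells=m.n_cells,
        n_expressing_any=int(detected.any(axis=1).sum()),
        per_gene_expressing={
            g: int(detected[:, j].sum()) for j, g in enumerate(panel.genes)
        },
    )
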