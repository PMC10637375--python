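"""Genome-wide co-expression response screening.

Every gene is ranked by the Pearson correlation of its expression with a
per-cell *response* — here the summed expression of the 19 subunit-panel
genes.  The parametric p-value comes from the t transform of r with
``n - 2`` degrees of freedom; with tens of thousands of cells it
underflows double precision for strong correlates and is stored as 0.
Ranking is therefore by (p ascending, |r| descending, symbol ascending),
which keeps the top-K list deterministic through the underflow regime.

Panel genes trivially correlate with their own sum and are excluded from
the ranking by default.  No multiple-testing correction is applied (the
selection uses a raw p cutoff); the export manifest records the number of
tests performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .errors import EstimationError, PreconditionError
from .matrix import ExpressionMatrix
from .panel import SubunitPanel, default_panel

logger = logging.getLogger("gabafc.screen")

#: the smallest positive double is ~4.9e-324; this cutoff sits just above
DEFAULT_P_MAX = 4.2e-322


@dataclass
class ScreenTable:
    """Ranked correlation screen.

    ``table`` columns: gene, r, t_stat, p, rank (ranks 1..m, no gaps).
    ``excluded`` maps gene symbol to the exclusion reason ("constant"
    for zero-variance genes, "panel" for panel genes when excluded).
    """

    table: pd.DataFrame
    n_cells: int
    excluded: dict[str, str] = field(default_factory=dict)


def panel_sum(m: ExpressionMatrix, panel: SubunitPanel | None = None) -> np.ndarray:
    """Per-cell summed panel expression — the screening response."""
    panel = panel or default_panel()
    return m.values[:, m.gene_indices(panel.genes)].sum(axis=1)


def response_screen(
    m: ExpressionMatrix,
    response: np.ndarray | None = None,
    panel: SubunitPanel | None = None,
    exclude_panel: bool = True,
) -> ScreenTable:
    """Correlate every gene with the response and rank by significance.

    ``response`` defaults to :func:`panel_sum` of ``m``.  Requires at
    least 3 cells; a response or gene with zero variance cannot be
    correlated (constant genes are excluded with reason "constant").
    """
    panel = panel or default_panel()
    if m.n_cells < 3:
        raise PreconditionError(f"response screen requires >= 3 cells, got {m.n_cells}")
    y = panel_sum(m, panel) if response is None else np.asarray(response, dtype=float)
    if y.shape != (m.n_cells,):
        raise PreconditionError(
            f"response length {y.shape} does not match {m.n_cells} cells"
        )
    n = m.n_cells
    X = m.values
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise EstimationError("response is constant; screen undefined")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))

    excluded: dict[str, str] = {}
    panel_set = set(panel.genes)
    keep = np.ones(m.n_genes, dtype=bool)
    for j, g in enumerate(m.gene_symbols):
        if sx[j] == 0:
            excluded[g] = "constant"
            keep[j] = False
        elif exclude_panel and g in panel_set:
            excluded[g] = "panel"
            keep[j] = False
    if not keep.any():
        raise EstimationError("no gene with variance to screen")

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc[:, keep].T @ yc) / (sx[keep] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    df = pd.DataFrame(
        {
            "gene": [g for g, k in zip(m.gene_symbols, keep) if k],
            "r": r,
            "t_stat": t,
            "p": p,
        }
    )
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(
        ["p", "abs_r", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="abs_r")
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.reset_index(drop=True)
    return ScreenTable(table=df, n_cells=n, excluded=excluded)


def select_top(
    s: ScreenTable, k: int = 1000, p_max: float = DEFAULT_P_MAX
) -> list[str]:
    """The first min(k, qualifying) genes in rank order with p < p_max.

    Underflowed p-values (stored 0) qualify under any positive cutoff.
    """
    if s.table.empty:
        raise PreconditionError("screen table is empty")
    qualifying = s.table[s.table["p"] < p_max]
    selected = qualifying["gene"].head(k).tolist()
    if len(selected) < k:
        logger.info(
            "select_top: only %d/%d genes pass p < %.3g", len(selected), k, p_max
        )
    return selected


def export_gene_list(
    genes: list[str],
    path: str | Path,
    k: int | None = None,
    p_max: float | None = None,
    n_cells: int | None = None,
    n_tests: int | None = None,
) -> Path:
    """Write one symbol per line (paste-ready for enrichment services).

    A JSON manifest (``<path>.manifest.json``) records the selection
    parameters and the number of univariate tests performed.
    """
    if not genes:
        raise PreconditionError("gene list is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes))
    manifest = {
        "n_genes": len(genes),
        "k": k,
        "p_max": p_max,
        "n_cells": n_cells,
        "n_tests": n_tests,
        "multiple_testing_correction": "none (raw p cutoff)",
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
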