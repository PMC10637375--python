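"""The cells-by-genes expression matrix carried between pipeline stages.

:class:`ExpressionMatrix` is a thin, validated container: a dense
non-negative ``cells x genes`` array plus cell identifiers, gene symbols,
a unit tag and optional per-cell metadata.  It deliberately stays small —
conversion to and from :class:`anndata.AnnData` is provided for users who
want the scanpy ecosystem.

Units
-----
``UMI`` and ``READS`` are integer count units; ``FPKM`` is a continuous
length-normalised unit; ``LOGNORM`` marks data that has been through
:func:`gabafc.preprocess.log_normalize` and is no longer on the count scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import IntegrityError

AGE_GROUPS = ("fetal", "pediatric", "adolescent", "adult")

#: cell_meta columns with reserved meaning
META_COLUMNS = ("age_group", "cell_type_label", "mito_fraction")


class Unit(str, enum.Enum):
    UMI = "UMI"
    FPKM = "FPKM"
    READS = "READS"
    LOGNORM = "LOGNORM"


#: units on which count-based QC is defined
COUNT_UNITS = frozenset({Unit.UMI, Unit.READS})


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense(), dtype=float)
    return np.asarray(values, dtype=float)


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with metadata.

    Parameters
    ----------
    dataset_id
        Identifier of the source dataset (accession or synthetic id).
    cell_ids
        Unique cell barcodes / identifiers, one per row.
    gene_symbols
        Unique gene symbols, one per column.
    values
        Non-negative ``(n_cells, n_genes)`` array.  Accepted as dense or
        scipy-sparse; stored dense.
    unit
        One of :class:`Unit`.  Count units (UMI, READS) must be integral.
    cell_meta
        Optional per-cell metadata frame indexed by ``cell_ids``.
        Recognised columns: ``age_group``, ``cell_type_label``,
        ``mito_fraction``.
    """

    dataset_id: str
    cell_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    unit: Unit = Unit.UMI
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        self.values = _as_dense(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")
        self.validate()

    # -- structural invariants ------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise IntegrityError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_symbols) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("duplicate cell ids")
        if len(set(self.gene_symbols)) != n_genes:
            raise IntegrityError("duplicate gene symbols")
        if self.values.size and self.values.min() < 0:
            raise IntegrityError("negative expression values")
        if self.unit in COUNT_UNITS and self.values.size:
            if not np.allclose(self.values, np.rint(self.values)):
                raise IntegrityError(f"unit {self.unit.value} requires integer values")

    # -- basic accessors ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError as exc:
            raise KeyError(symbol) from exc

    def gene_indices(self, symbols: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"gene symbols not present: {missing}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def column(self, symbol: str) -> np.ndarray:
        return self.values[:, self.gene_index(symbol)]

    # -- subsetting (pure filters: values are copied, never modified) ---------
    def subset_cells(self, mask_or_ids: np.ndarray | Iterable[str]) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = set(mask_or_ids)  # type: ignore[arg-type]
            idx = np.array(
                [i for i, c in enumerate(self.cell_ids) if c in wanted], dtype=int
            )
        return ExpressionMatrix(
            dataset_id=self.dataset_id,
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_symbols=list(self.gene_symbols),
            values=self.values[idx].copy(),
            unit=self.unit,
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(symbols)
        return ExpressionMatrix(
            dataset_id=self.dataset_id,
            cell_ids=list(self.cell_ids),
            gene_symbols=list(symbols),
            values=self.values[:, idx].copy(),
            unit=self.unit,
            cell_meta=self.cell_meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.cell_ids), columns=list(self.gene_symbols)
        )

    # -- interchange with the scanpy ecosystem --------------------------------
    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (cells as obs, genes as var)."""
        import anndata

        ad = anndata.AnnData(
            X=self.values.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_symbols, name="gene_symbol")),
        )
        ad.uns["unit"] = self.unit.value
        ad.uns["dataset_id"] = self.dataset_id
        return ad

    @classmethod
    def from_anndata(cls, ad, dataset_id: str | None = None,
                     unit: Unit | str | None = None) -> "ExpressionMatrix":
        unit = Unit(unit or ad.uns.get("unit", "UMI"))
        return cls(
            dataset_id=dataset_id or ad.uns.get("dataset_id", "anndata"),
            cell_ids=list(ad.obs_names),
            gene_symbols=list(ad.var_names),
            values=ad.X,
            unit=unit,
            cell_meta=ad.obs,
        )


def mito_fractions(m: ExpressionMatrix, prefix: str = "MT-") -> np.ndarray:
    """Per-cell mitochondrial count fraction.

    Uses the ``mito_fraction`` metadata column when present (and fully
    populated); otherwise computes the fraction of counts on genes whose
    symbol starts with ``prefix`` (case-insensitive).  Cells with zero
    total count get fraction 0.
    """
    if "mito_fraction" in m.cell_meta.columns:
        col = pd.to_numeric(m.cell_meta["mito_fraction"], errors="coerce")
        if not col.isna().any():
            return col.to_numpy(dtype=float)
    is_mt = np.array(
        [g.upper().startswith(prefix.upper()) for g in m.gene_symbols], dtype=bool
    )
    totals = m.values.sum(axis=1)
    mito = m.values[:, is_mt].sum(axis=1) if is_mt.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    return frac
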