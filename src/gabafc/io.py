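"""Readers and writers for processed expression matrices.

Two on-disk layouts are supported, covering how public repositories
deposit processed single-cell data:

* **MTX triplet** — MatrixMarket coordinate ``matrix.mtx`` plus
  one-barcode-per-line and one-feature-per-line text files (the 10x
  convention, genes in rows), optionally gzipped.
* **Dense table** — TSV/CSV with a header row and row labels, in either
  orientation.

Both loaders return an :class:`~gabafc.matrix.ExpressionMatrix` in
cells-by-genes orientation regardless of the on-disk orientation.
A dataset *registry* (YAML) describes where each dataset lives and how to
interpret it.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import FormatError, IntegrityError, ValidationError
from .matrix import AGE_GROUPS, ExpressionMatrix, Unit

logger = logging.getLogger("gabafc.io")

FORMATS = ("mtx_triplet", "dense_table")
ORIENTATIONS = ("cells_by_genes", "genes_by_cells")


@dataclass
class DatasetRegistryEntry:
    """One dataset in the registry: where it lives and how to read it."""

    accession: str
    format: str
    orientation: str
    unit: Unit
    paths: dict[str, str]
    age_group: str | None = None
    apply_qc: bool = False

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValidationError(f"unknown format {self.format!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        self.unit = Unit(self.unit)
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"age_group {self.age_group!r} not in {AGE_GROUPS}"
            )
        needed = (
            {"matrix", "barcodes", "features"}
            if self.format == "mtx_triplet"
            else {"table"}
        )
        missing = needed - set(self.paths)
        if missing:
            raise ValidationError(
                f"registry entry {self.accession}: missing paths {sorted(missing)}"
            )


def load_registry(path: str | Path) -> list[DatasetRegistryEntry]:
    """Load a YAML registry: a list of dataset entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("registry YAML must be a list of entries")
    base = Path(path).parent
    entries = []
    for item in raw:
        item = dict(item)
        item["paths"] = {
            k: str((base / v)) if not Path(v).is_absolute() else v
            for k, v in item.get("paths", {}).items()
        }
        entries.append(DatasetRegistryEntry(**item))
    return entries


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _feature_symbols(lines: list[str]) -> list[str]:
    """Pull gene symbols from a features file.

    10x features files carry (ensembl_id, symbol, type) tab-separated;
    plain one-symbol-per-line files are also accepted.
    """
    symbols = []
    for line in lines:
        parts = line.split("\t")
        symbols.append(parts[1] if len(parts) >= 2 else parts[0])
    return symbols


def load_mtx_triplet(entry: DatasetRegistryEntry) -> ExpressionMatrix:
    """Read a MatrixMarket triplet into cells-by-genes orientation.

    Raises
    ------
    FormatError
        Invalid MatrixMarket header or barcode/feature counts that do not
        match the matrix dimensions.
    IntegrityError
        Duplicate barcodes/features or negative entries.
    """
    for key in ("matrix", "barcodes", "features"):
        if not Path(entry.paths[key]).exists():
            raise FormatError(f"{entry.accession}: missing file {entry.paths[key]}")
    try:
        with _open_text(entry.paths["matrix"]) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"{entry.accession}: invalid MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)

    barcodes = _read_lines(entry.paths["barcodes"])
    features = _feature_symbols(_read_lines(entry.paths["features"]))

    if entry.orientation == "genes_by_cells":
        n_genes, n_cells = mat.shape
        mat = mat.T
    else:
        n_cells, n_genes = mat.shape
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{entry.accession}: {len(barcodes)} barcodes but matrix has "
            f"{n_cells} cells"
        )
    if len(features) != n_genes:
        raise FormatError(
            f"{entry.accession}: {len(features)} features but matrix has "
            f"{n_genes} genes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise IntegrityError(f"{entry.accession}: duplicate barcodes")
    if mat.nnz and mat.data.min() < 0:
        raise IntegrityError(f"{entry.accession}: negative matrix entries")

    meta = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    if entry.age_group is not None:
        meta["age_group"] = entry.age_group
    return ExpressionMatrix(
        dataset_id=entry.accession,
        cell_ids=barcodes,
        gene_symbols=features,
        values=mat.tocsr(),
        unit=entry.unit,
        cell_meta=meta,
    )


def load_dense_table(entry: DatasetRegistryEntry) -> ExpressionMatrix:
    """Read a dense TSV/CSV expression table (either orientation)."""
    path = Path(entry.paths["table"])
    if not path.exists():
        raise FormatError(f"{entry.accession}: missing file {path}")
    sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{entry.accession}: ragged or malformed table: {exc}") from exc
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{entry.accession}: non-numeric value in table: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{entry.accession}: missing (NA) value in table")
    if entry.orientation == "genes_by_cells":
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"{entry.accession}: duplicate gene symbols {dups}")
        df = df.T
    else:
        if df.columns.duplicated().any():
            raise IntegrityError(f"{entry.accession}: duplicate gene symbols")
    meta = pd.DataFrame(index=pd.Index([str(c) for c in df.index], name="cell_id"))
    if entry.age_group is not None:
        meta["age_group"] = entry.age_group
    return ExpressionMatrix(
        dataset_id=entry.accession,
        cell_ids=[str(c) for c in df.index],
        gene_symbols=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
        unit=entry.unit,
        cell_meta=meta,
    )


def load_dataset_entry(entry: DatasetRegistryEntry) -> ExpressionMatrix:
    """Dispatch on the registry entry's declared format."""
    if entry.format == "mtx_triplet":
        return load_mtx_triplet(entry)
    return load_dense_table(entry)


# ---------------------------------------------------------------------------
# writing: MTX triplet (10x convention, genes in rows) + metadata sidecars
# ---------------------------------------------------------------------------

def write_mtx_triplet(m: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write a matrix as an MTX triplet directory.

    Files written: ``matrix.mtx`` (genes x cells, integer field for count
    units), ``barcodes.tsv``, ``features.tsv``, ``cell_meta.tsv`` (when
    metadata exists) and ``meta.json`` (dataset id and unit).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes_by_cells = sp.csr_matrix(m.values.T)
    if m.unit in (Unit.UMI, Unit.READS):
        genes_by_cells = genes_by_cells.astype(np.int64)
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "meta": out / "meta.json",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(genes_by_cells))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in m.cell_ids))
    paths["features"].write_text("".join(f"{g}\n" for g in m.gene_symbols))
    if len(m.cell_meta.columns):
        m.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t")
        paths["cell_meta"] = out / "cell_meta.tsv"
    paths["meta"].write_text(
        json.dumps({"dataset_id": m.dataset_id, "unit": m.unit.value}, indent=2)
    )
    return paths


def read_mtx_dir(path: str | Path) -> ExpressionMatrix:
    """Read back a directory written by :func:`write_mtx_triplet`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text()) if (path / "meta.json").exists() else {}
    entry = DatasetRegistryEntry(
        accession=meta.get("dataset_id", path.name),
        format="mtx_triplet",
        orientation="genes_by_cells",
        unit=meta.get("unit", "UMI"),
        paths={
            "matrix": str(path / "matrix.mtx"),
            "barcodes": str(path / "barcodes.tsv"),
            "features": str(path / "features.tsv"),
        },
    )
    m = load_mtx_triplet(entry)
    meta_path = path / "cell_meta.tsv"
    if meta_path.exists():
        cm = pd.read_csv(meta_path, sep="\t", index_col=0)
        m.cell_meta = cm.reindex(m.cell_ids)
        m.cell_meta.index = pd.Index(m.cell_ids, name="cell_id")
    return m
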