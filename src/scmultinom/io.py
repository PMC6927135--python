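"""Readers and writers for count matrices and derived tables.

Two on-disk dialects are supported: a MatrixMarket triplet directory in the
10x style (matrix.mtx + barcodes.tsv + features.tsv, stored genes × cells)
and a dense TSV (header row = gene ids, first column = cell ids, stored
cells × genes). The in-memory canonical orientation is always cells × genes;
the reader transposes according to the orientation flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .count_model import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["DatasetBundle", "read_counts", "write_counts", "write_matrix"]

ORIENTATIONS = ("cells_by_genes", "genes_by_cells")


@dataclass
class DatasetBundle:
    counts: CountMatrix
    cell_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self):
        for meta, ids, what in ((self.cell_meta, self.counts.cell_ids, "cell"),
                                (self.gene_meta, self.counts.gene_ids, "gene")):
            if meta is not None:
                extra = set(meta.index) - set(ids)
                if extra:
                    raise ValueError(f"{what} metadata keys not in matrix: "
                                     f"{sorted(extra)[:5]}...")


def _read_mtx_dir(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path / "matrix.mtx")
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.array_equal(mat, np.rint(mat)):
        raise ValueError(f"{path / 'matrix.mtx'}: non-integer entries")
    barcodes = [l.split("\t")[0] for l in
                (path / "barcodes.tsv").read_text().splitlines() if l]
    feat_path = path / "features.tsv"
    if not feat_path.exists():
        feat_path = path / "genes.tsv"
    features = [l.split("\t")[0] for l in
                feat_path.read_text().splitlines() if l]
    return mat.astype(np.int64), barcodes, features


def read_counts(path, format: str = "mtx_dir",
                orientation: str = "genes_by_cells") -> DatasetBundle:
    """Read a count matrix; validates integers and id/dimension agreement.

    The 10x MatrixMarket convention stores genes × cells, hence the default
    orientation for ``mtx_dir``; dense TSVs written by this package are
    cells × genes.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    if format == "mtx_dir":
        mat, barcodes, features = _read_mtx_dir(path)
        if orientation == "genes_by_cells":
            mat = mat.T  # rows become cells
        cell_ids, gene_ids = barcodes, features
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(cell_ids)} barcodes x {len(gene_ids)} features")
        return DatasetBundle(CountMatrix(mat, cell_ids, gene_ids))
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.array_equal(vals, np.rint(vals)):
            raise ValueError(f"{path}: non-integer entries")
        if orientation == "genes_by_cells":
            df = df.T
        return DatasetBundle(CountMatrix(df.to_numpy().astype(np.int64),
                                         list(df.index), list(df.columns)))
    raise ValueError(f"unknown format {format!r}")


def write_counts(counts: CountMatrix, path, format: str = "mtx_dir") -> None:
    """Write a count matrix mirroring :func:`read_counts`."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx",
                         sp.coo_matrix(counts.counts.T), field="integer")
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in counts.cell_ids))
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\n" for g in counts.gene_ids))
        return
    if format == "tsv":
        pd.DataFrame(counts.counts, index=counts.cell_ids,
                     columns=counts.gene_ids).to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown format {format!r}")


def write_matrix(values: np.ndarray, path, row_ids=None, col_ids=None,
                 digits: int = 6) -> None:
    """Write a real-valued matrix as TSV with ids, 6 significant digits."""
    values = np.asarray(values)
    if values.size and not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    if row_ids is None:
        row_ids = [f"row{i}" for i in range(values.shape[0])]
    if col_ids is None:
        col_ids = [f"col{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t", float_format=f"%.{digits}g")
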