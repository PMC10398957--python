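"""Core in-memory containers and plain-text I/O for the pipeline.

Counts travel as a sparse nuclei x genes integer matrix with string
identifiers on both axes; expression is the dense normalized/log matrix
derived from it. On disk a dataset is a MatrixMarket ``matrix.mtx``
(1-based indices) plus ``genes.tsv`` / ``barcodes.tsv`` and a per-nucleus
``metadata.tsv``, mirroring the layout 10x-style tools exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_mtx_dir",
    "write_mtx_dir",
    "META_COLUMNS",
]

#: required columns of a per-nucleus metadata table
META_COLUMNS = ["nucleus_id", "sample", "amyloid", "tau", "apoe", "trem2", "age"]


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, nuclei (rows) x genes (columns)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    nucleus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=object)
        n, g = self.values.shape
        if len(self.nucleus_ids) != n:
            raise ValueError(
                f"nucleus_ids length {len(self.nucleus_ids)} != matrix rows {n}"
            )
        if len(self.gene_ids) != g:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != matrix columns {g}")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.nucleus_ids)) != n:
            raise ValueError("duplicate nucleus identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_nuclei(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.values[mask], self.gene_ids, self.nucleus_ids[mask])

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.values[:, mask], self.gene_ids[mask], self.nucleus_ids)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])


@dataclass
class ExpressionMatrix:
    """Dense expression values on natural-log scale, nuclei x genes.

    Provenance flags record what has been applied; zero counts stay
    exactly zero through normalize + log1p.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    nucleus_ids: np.ndarray
    normalized: bool = False
    logged: bool = False
    smoothed: bool = False
    smooth_k: int | None = None
    target_sum: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_nuclei(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return replace(self, values=self.values[mask], nucleus_ids=self.nucleus_ids[mask])

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return replace(self, values=self.values[:, mask], gene_ids=self.gene_ids[mask])

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]


def write_mtx_dir(counts: CountMatrix, outdir: str | Path, meta: pd.DataFrame | None = None) -> Path:
    """Write counts (and optionally metadata) to a directory of text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # MatrixMarket convention stores genes x nuclei for 10x-style exports;
    # we keep our row-major nuclei x genes orientation and record it in the
    # comment so round-trips are unambiguous.
    scipy.io.mmwrite(
        outdir / "matrix.mtx",
        sp.coo_matrix(counts.values),
        comment="nuclei x genes counts",
        field="integer",
    )
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.nucleus_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if meta is not None:
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return outdir


def read_mtx_dir(path: str | Path) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Read a dataset directory written by :func:`write_mtx_dir`."""
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    counts = CountMatrix(mat, genes, barcodes)
    meta_path = path / "metadata.tsv"
    meta = pd.read_csv(meta_path, sep="\t") if meta_path.exists() else None
    return counts, meta


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-nucleus covariate table has the expected columns."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["nucleus_id"].duplicated().any():
        raise ValueError("duplicate nucleus_id in metadata")
    for col in ("amyloid", "tau"):
        vals = set(pd.unique(meta[col]))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be coded 0/1, got {sorted(vals)}")
    return meta
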