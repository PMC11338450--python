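"""Count-matrix I/O and preprocessing.

Reads gene-by-cell count matrices from Matrix-Market directories (10x-style
triplet of matrix + gene list + barcode list) or dense CSV/TSV, and applies
the three preprocessing steps used throughout the pipeline: low-abundance
gene filtering, median-library log normalization, and highly-variable-gene
selection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_ids(ids: Sequence[str], axis: str, n: int) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValidationError(f"{axis} identifier count {len(ids)} != axis length {n}")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {axis} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Raw non-negative gene x cell counts with identifiers.

    ``values`` has shape ``(n_genes, n_cells)``; rows are genes.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("count matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("count matrix contains negative entries")
        self.gene_ids = _check_ids(self.gene_ids, "gene", self.values.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell", self.values.shape[1])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ProcessedMatrix:
    """Filtered, log-normalized (and optionally HVG-restricted) matrix.

    Entries are ``ln(m * x_gc / t_c + 1)`` with ``t_c`` the library size of
    cell ``c`` and ``m`` the median library size, so all entries are >= 0 and
    zeros stay zero.  ``provenance`` records how the matrix was derived.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("processed matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("processed matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("processed matrix contains negative entries")
        self.gene_ids = _check_ids(self.gene_ids, "gene", self.values.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell", self.values.shape[1])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MTX_NAMES = ("matrix.mtx",)
_GENE_NAMES = ("genes.tsv", "features.tsv", "genes.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")


def _find_file(directory: Path, names: Sequence[str], kind: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {kind} file found in {directory} (tried {', '.join(names)})")


def _read_id_column(path: Path) -> list[str]:
    # 10x gene files may carry 2+ tab-separated columns; the first is the id.
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts(path: str | Path, format: str = "csv") -> CountMatrix:
    """Read a raw count matrix.

    Parameters
    ----------
    path
        File path for ``csv``/``tsv``, or a directory for ``mtx_dir``
        containing ``matrix.mtx`` plus gene and barcode lists.
    format
        One of ``mtx_dir``, ``csv``, ``tsv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"mtx_dir input must be a directory: {path}")
        mtx = _find_file(path, _MTX_NAMES, "matrix")
        genes = _read_id_column(_find_file(path, _GENE_NAMES, "gene list"))
        barcodes = _read_id_column(_find_file(path, _BARCODE_NAMES, "barcode list"))
        mat = spio.mmread(mtx)
        if sparse.issparse(mat):
            mat = mat.toarray()
        return CountMatrix(np.asarray(mat, dtype=float), genes, barcodes)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        return CountMatrix(values, list(df.index), list(df.columns))
    raise ValueError(f"unknown format: {format!r}")


def write_counts(x: CountMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a count matrix in ``csv``, ``tsv`` or ``mtx_dir`` form."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(x.values))
        (path / "genes.tsv").write_text("\n".join(x.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(x.cell_ids) + "\n")
        return
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids)
        # keep integer counts integral on disk for bit-exact round-trips
        if np.all(x.values == np.round(x.values)):
            df = df.astype(np.int64)
        df.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format: {format!r}")


def write_processed(x: ProcessedMatrix, path: str | Path) -> None:
    """Write a processed matrix as CSV with a ``<path>.provenance`` sidecar."""
    path = Path(path)
    pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids).to_csv(path)
    lines = [f"{k}={v}" for k, v in sorted(x.provenance.items())]
    Path(str(path) + ".provenance").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def filter_genes(x: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes with a non-zero count in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_expressing = (x.values > 0).sum(axis=1)
    keep = n_expressing >= min_cells
    if not np.any(keep):
        raise ValidationError(
            f"no gene is expressed in >= {min_cells} cells; nothing left after filtering"
        )
    return CountMatrix(
        x.values[keep, :],
        [g for g, k in zip(x.gene_ids, keep) if k],
        list(x.cell_ids),
    )


def log_normalize(x: CountMatrix) -> ProcessedMatrix:
    """Median-library log normalization.

    Entry ``(g, c)`` becomes ``ln(m * x_gc / t_c + 1)`` where ``t_c`` is the
    total count of cell ``c`` and ``m`` the median of all cell totals.  Cells
    with zero total count are dropped first and recorded in provenance.
    """
    totals = x.values.sum(axis=0)
    keep = totals > 0
    dropped = [c for c, k in zip(x.cell_ids, keep) if not k]
    values = x.values[:, keep]
    cell_ids = [c for c, k in zip(x.cell_ids, keep) if k]
    totals = totals[keep]
    if values.shape[1] == 0:
        raise ValidationError("all cells have zero total counts")
    m = float(np.median(totals))
    normed = np.log1p(m * values / totals[np.newaxis, :])
    provenance = {
        "normalization": "median-library-log1p",
        "median_library_size": m,
        "n_cells_dropped_zero_total": len(dropped),
    }
    return ProcessedMatrix(normed, list(x.gene_ids), cell_ids, provenance)


def select_hvgs(
    x: ProcessedMatrix, n_top: int = 2000, method: str = "variance"
) -> ProcessedMatrix:
    """Keep the ``n_top`` most variable genes, preserving input order.

    ``method='variance'`` ranks by per-gene variance of the log-normalized
    values; ``method='dispersion'`` ranks by variance/mean.  Ties are broken
    in favour of earlier genes.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if method == "variance":
        score = x.values.var(axis=1)
    elif method == "dispersion":
        mean = x.values.mean(axis=1)
        score = x.values.var(axis=1) / np.maximum(mean, 1e-12)
    else:
        raise ValueError(f"unknown HVG method: {method!r}")
    n_keep = min(n_top, x.n_genes)
    # stable sort on -score keeps earlier genes on ties
    top = np.sort(np.argsort(-score, kind="stable")[:n_keep])
    provenance = dict(x.provenance)
    provenance.update({"hvg_method": method, "hvg_n_top": n_top})
    return ProcessedMatrix(
        x.values[top, :],
        [x.gene_ids[i] for i in top],
        list(x.cell_ids),
        provenance,
    )


def preprocess(
    x: CountMatrix,
    min_cells: int = 3,
    n_top: int = 2000,
    hvg_method: str = "variance",
) -> ProcessedMatrix:
    """filter -> log-normalize -> HVG, the fixed preprocessing order."""
    filtered = filter_genes(x, min_cells=min_cells)
    normed = log_normalize(filtered)
    normed.provenance["gene_filter_min_cells"] = min_cells
    return select_hvgs(normed, n_top=n_top, method=hvg_method)
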