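"""Chunked, compressed storage of cell x feature count matrices.

The central container is :class:`AssayStore`: a dense cells-as-rows matrix
held either in memory or as a compressed, chunked Zarr array on disk.  All
downstream operations consume the matrix chunk-wise through
:func:`iter_chunks`, so nothing in the pipeline ever requires the full
matrix to be resident (the in-memory path exists for tests and small data).

Cell and feature annotations live outside the matrix in :class:`CellTable`
and :class:`FeatureTable` (thin wrappers over pandas DataFrames with a
mandatory unique ``ids`` column and a boolean ``valid_mask``).  A
:class:`Dataset` groups one store per assay and designates a default assay
that receives operations unless another is named.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
import zarr
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "AssayStore",
    "CellTable",
    "FeatureTable",
    "Dataset",
    "read_counts",
    "iter_chunks",
    "export_subset",
    "write_counts",
]

DEFAULT_CHUNK = (2000, 2000)


class StoreError(Exception):
    """Malformed input or inconsistent sidecar structure."""


@dataclass
class CellTable:
    """Per-cell attribute table; ``ids`` unique, one row per matrix row."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "ids" not in self.table.columns:
            raise StoreError("cell table requires an 'ids' column")
        if self.table["ids"].duplicated().any():
            dup = self.table["ids"][self.table["ids"].duplicated()].iloc[0]
            raise StoreError(f"duplicate cell id: {dup!r}")
        if "valid_mask" not in self.table.columns:
            self.table["valid_mask"] = True

    @classmethod
    def from_ids(cls, ids) -> "CellTable":
        return cls(pd.DataFrame({"ids": np.asarray(ids, dtype=object)}))

    @property
    def ids(self) -> np.ndarray:
        return self.table["ids"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.table.loc[np.asarray(mask)].reset_index(drop=True).copy())


class FeatureTable(CellTable):
    """Per-feature attribute table; same contract as :class:`CellTable`."""

    def __post_init__(self) -> None:
        if "ids" not in self.table.columns:
            raise StoreError("feature table requires an 'ids' column")
        if self.table["ids"].duplicated().any():
            dup = self.table["ids"][self.table["ids"].duplicated()].iloc[0]
            raise StoreError(f"duplicate feature id: {dup!r}")
        if "valid_mask" not in self.table.columns:
            self.table["valid_mask"] = True

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.table.loc[np.asarray(mask)].reset_index(drop=True).copy()
        )


class AssayStore:
    """Dense cells x features matrix, chunked and optionally on disk.

    Parameters
    ----------
    counts
        2-D array-like of non-negative values (numpy array or zarr array).
    chunk_shape
        (rows, cols) chunking used when persisting; default 2000 x 2000.
    assay_name
        Label for the assay (e.g. ``"RNA"``, ``"ATAC"``).
    """

    def __init__(self, counts, chunk_shape=DEFAULT_CHUNK, assay_name="RNA"):
        if counts.ndim != 2:
            raise StoreError("counts must be 2-D")
        self._counts = counts
        self.chunk_shape = (
            min(int(chunk_shape[0]), counts.shape[0]) or 1,
            min(int(chunk_shape[1]), counts.shape[1]) or 1,
        )
        self.assay_name = assay_name

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self._counts.shape)

    @property
    def n_cells(self) -> int:
        return self._counts.shape[0]

    @property
    def n_features(self) -> int:
        return self._counts.shape[1]

    @property
    def compressed(self) -> bool:
        return isinstance(self._counts, zarr.Array)

    def to_array(self) -> np.ndarray:
        """Materialise the full matrix in memory (small data only)."""
        return np.asarray(self._counts[:, :])

    def rows(self, start: int, stop: int) -> np.ndarray:
        return np.asarray(self._counts[start:stop, :])

    # -- persistence -----------------------------------------------------
    @classmethod
    def from_array(
        cls, arr: np.ndarray, chunk_shape=DEFAULT_CHUNK, assay_name="RNA", path=None
    ) -> "AssayStore":
        arr = np.asarray(arr)
        if arr.size and arr.min() < 0:
            raise StoreError("counts must be non-negative")
        if path is None:
            return cls(arr, chunk_shape, assay_name)
        chunks = (
            max(1, min(chunk_shape[0], arr.shape[0])),
            max(1, min(chunk_shape[1], arr.shape[1])),
        )
        z = zarr.open_array(
            str(path), mode="w", shape=arr.shape, chunks=chunks, dtype=arr.dtype
        )
        z[:, :] = arr
        return cls(z, chunk_shape, assay_name)

    @classmethod
    def open(cls, path, assay_name="RNA") -> "AssayStore":
        z = zarr.open_array(str(path), mode="r")
        return cls(z, z.chunks, assay_name)

    def save(self, path) -> "AssayStore":
        """Write to a compressed chunked Zarr array at *path*."""
        return AssayStore.from_array(
            self.to_array(), self.chunk_shape, self.assay_name, path=path
        )


@dataclass
class Dataset:
    """A named group of assays sharing one cell table.

    Mirrors multi-modal experiments (e.g. CITE-seq): cell-level attributes
    are shared while each assay keeps its own matrix and feature table.
    Operations that take a :class:`Dataset` act on ``default_assay`` unless
    told otherwise.
    """

    cells: CellTable
    assays: dict = field(default_factory=dict)
    feature_tables: dict = field(default_factory=dict)
    default_assay: str | None = None

    def add_assay(
        self, store: AssayStore, features: FeatureTable, make_default=False
    ) -> None:
        if store.n_cells != len(self.cells):
            raise StoreError(
                f"assay {store.assay_name!r} has {store.n_cells} cells; "
                f"cell table has {len(self.cells)}"
            )
        if store.n_features != len(features):
            raise StoreError("feature table length does not match matrix columns")
        self.assays[store.assay_name] = store
        self.feature_tables[store.assay_name] = features
        if make_default or self.default_assay is None:
            self.default_assay = store.assay_name

    def assay(self, name: str | None = None) -> AssayStore:
        return self.assays[name or self.default_assay]

    def features(self, name: str | None = None) -> FeatureTable:
        return self.feature_tables[name or self.default_assay]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_sidecar(path: str, fallback_prefix: str, n: int) -> np.ndarray:
    if path is not None and os.path.exists(path):
        ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        return ids
    return np.array([f"{fallback_prefix}{i}" for i in range(n)], dtype=object)


def _read_mtx(path, barcodes, features):
    try:
        mat = mmread(path)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise StoreError(f"malformed Matrix Market file {path}: {exc}") from exc
    arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    # MTX convention from 10x-style exports: features x cells; ours is
    # cells x features, so transpose only when sidecars say so.
    cell_ids = _read_sidecar(barcodes, "cell_", arr.shape[0])
    feat_ids = _read_sidecar(features, "feat_", arr.shape[1])
    if len(cell_ids) == arr.shape[1] and len(cell_ids) != arr.shape[0]:
        arr = arr.T
    if len(cell_ids) != arr.shape[0]:
        raise StoreError(
            f"barcode sidecar lists {len(cell_ids)} cells but matrix has "
            f"{arr.shape[0]} rows"
        )
    if len(feat_ids) != arr.shape[1]:
        raise StoreError(
            f"feature sidecar lists {len(feat_ids)} features but matrix has "
            f"{arr.shape[1]} columns"
        )
    return arr, cell_ids, feat_ids


def _read_10x_h5(path):
    with h5py.File(path, "r") as f:
        group = None
        for key in f.keys():
            if "data" in f[key]:
                group = f[key]
                break
        if group is None:
            raise StoreError(f"{path}: no CSC matrix group found")
        data = group["data"][:]
        indices = group["indices"][:]
        indptr = group["indptr"][:]
        shape = group["shape"][:]  # features x cells (10x convention)
        from scipy.sparse import csc_matrix

        mat = csc_matrix((data, indices, indptr), shape=tuple(shape))
        cell_ids = np.array([b.decode() for b in group["barcodes"][:]], dtype=object)
        if "features" in group:
            raw = group["features"]["id"][:]
        else:  # legacy layout
            raw = group["genes"][:]
        feat_ids = np.array([b.decode() for b in raw], dtype=object)
    arr = np.asarray(mat.T.todense())
    if len(cell_ids) != arr.shape[0] or len(feat_ids) != arr.shape[1]:
        raise StoreError("10x HDF5 sidecar lengths disagree with matrix shape")
    return arr, cell_ids, feat_ids


def _read_csv(path, sep=","):
    df = pd.read_csv(path, sep=sep, index_col=0)
    return (
        df.to_numpy(),
        df.index.astype(str).to_numpy(),
        df.columns.astype(str).to_numpy(),
    )


def read_counts(
    path,
    format: str,
    barcodes=None,
    features=None,
    chunk_shape=DEFAULT_CHUNK,
    assay_name="RNA",
):
    """Read a count matrix into (AssayStore, CellTable, FeatureTable).

    ``format`` is one of ``mtx`` (with optional barcodes/features TSV
    sidecars; defaults to ``<dir>/barcodes.tsv`` and ``<dir>/features.tsv``),
    ``10x-h5`` (CSC feature-barcode matrix) or ``csv``/``tsv`` (dense,
    header row = feature ids, first column = cell ids).  Integer inputs stay
    integer.
    """
    fmt = format.lower()
    if fmt == "mtx":
        d = os.path.dirname(os.path.abspath(path))
        if barcodes is None:
            barcodes = os.path.join(d, "barcodes.tsv")
        if features is None:
            features = os.path.join(d, "features.tsv")
        arr, cell_ids, feat_ids = _read_mtx(path, barcodes, features)
    elif fmt in ("10x-h5", "h5"):
        arr, cell_ids, feat_ids = _read_10x_h5(path)
    elif fmt == "csv":
        arr, cell_ids, feat_ids = _read_csv(path, sep=",")
    elif fmt == "tsv":
        arr, cell_ids, feat_ids = _read_csv(path, sep="\t")
    else:
        raise StoreError(f"unknown format {format!r}")
    if arr.size and arr.min() < 0:
        raise StoreError("negative values in count matrix")
    store = AssayStore(arr, chunk_shape, assay_name)
    return store, CellTable.from_ids(cell_ids), FeatureTable.from_ids(feat_ids)


def write_counts(store: AssayStore, cells: CellTable, feats: FeatureTable, out_dir):
    """Write an MTX triplet (matrix.mtx, barcodes.tsv, features.tsv)."""
    os.makedirs(out_dir, exist_ok=True)
    arr = store.to_array()
    mmwrite(os.path.join(out_dir, "matrix.mtx"), coo_matrix(arr))
    pd.Series(cells.ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(feats.ids).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# streaming and subsetting
# ---------------------------------------------------------------------------


def iter_chunks(store: AssayStore, row_block: int | None = None) -> Iterator[np.ndarray]:
    """Stream contiguous, disjoint, ordered dense row blocks.

    Vertical concatenation of the yielded blocks reproduces the matrix
    exactly; chunk boundaries never change values.
    """
    if row_block is None:
        row_block = store.chunk_shape[0]
    if row_block <= 0:
        raise ValueError(f"row_block must be positive, got {row_block}")
    n = store.n_cells
    for start in range(0, n, row_block):
        yield store.rows(start, min(start + row_block, n))


def export_subset(
    store: AssayStore,
    cells: CellTable,
    feats: FeatureTable,
    cell_mask,
    feat_mask,
):
    """Subset a store (and its tables) by boolean masks.

    Returns a new ``(AssayStore, CellTable, FeatureTable)`` triple holding
    exactly the masked submatrix.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    feat_mask = np.asarray(feat_mask, dtype=bool)
    if cell_mask.shape[0] != store.n_cells:
        raise StoreError("cell_mask length does not match cell count")
    if feat_mask.shape[0] != store.n_features:
        raise StoreError("feat_mask length does not match feature count")
    if not cell_mask.any():
        raise StoreError("cell_mask selects no cells")
    blocks = [blk[:, feat_mask] for blk in iter_chunks(store)]
    offsets = np.cumsum([0] + [b.shape[0] for b in blocks])
    kept = [
        blocks[i][cell_mask[offsets[i] : offsets[i + 1]]] for i in range(len(blocks))
    ]
    sub = np.concatenate(kept, axis=0)
    new_store = AssayStore(sub, store.chunk_shape, store.assay_name)
    return new_store, cells.subset(cell_mask), feats.subset(feat_mask)
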