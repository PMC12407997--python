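"""Spatial transcriptomics dataset container and plain-text I/O.

The universal input throughout the package is an :class:`STDataset`: a
cell/location-by-gene count matrix, a 2-D coordinate table, and an optional
per-cell domain/cell-type label vector. Counts may be dense or any scipy
sparse matrix; on disk a dataset is a directory of Matrix Market + CSV files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["STDataset", "read_dataset", "write_dataset"]


def _is_integral(counts) -> bool:
    if sp.issparse(counts):
        data = counts.data
    else:
        data = np.asarray(counts).ravel()
    if data.size == 0:
        return True
    if np.issubdtype(data.dtype, np.integer):
        return True
    return bool(np.all(data == np.rint(data)))


@dataclass
class STDataset:
    """Counts, coordinates and optional labels for one tissue section.

    Parameters
    ----------
    counts
        ``(n, g)`` matrix of nonnegative integer counts (dense ndarray or
        scipy sparse; stored as given, CSR recommended for large data).
    coords
        ``(n, 2)`` array of spatial coordinates, one unit system per dataset.
    labels
        Optional length-``n`` categorical vector (domain / cell-type labels).
    ids
        Length-``n`` unique identifiers; generated as ``cell_<i>`` if omitted.
    """

    counts: "sp.spmatrix | np.ndarray"
    coords: np.ndarray
    labels: "np.ndarray | None" = None
    ids: "np.ndarray | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        n = self.coords.shape[0]
        if self.counts.shape[0] != n:
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but coords has {n}"
            )
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not _is_integral(self.counts):
            raise ValueError("counts must contain integers")
        if (self.counts.min() if not sp.issparse(self.counts)
                else (self.counts.data.min() if self.counts.nnz else 0)) < 0:
            raise ValueError("counts must be nonnegative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length must match number of cells")
        if self.ids is None:
            self.ids = np.array([f"cell_{i}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if self.ids.shape[0] != n:
                raise ValueError("ids length must match number of cells")
            if len(set(self.ids.tolist())) != n:
                raise ValueError("ids must be unique")

    @property
    def n(self) -> int:
        """Number of cells / locations."""
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell library size (row sums of counts)."""
        totals = self.counts.sum(axis=1)
        return np.asarray(totals).ravel().astype(float)

    def subset(self, index) -> "STDataset":
        """Row subset preserving the order of ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        counts = self.counts[index]
        return STDataset(
            counts=counts,
            coords=self.coords[index],
            labels=None if self.labels is None else self.labels[index],
            ids=self.ids[index],
            meta=dict(self.meta),
        )


def write_dataset(dataset: STDataset, path: "str | Path") -> Path:
    """Write a dataset directory: counts.mtx, coords.csv, labels.csv, config.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = dataset.counts
    if not sp.issparse(counts):
        counts = sp.csr_matrix(counts)
    mmwrite(path / "counts.mtx", counts.tocoo(), field="integer")
    pd.DataFrame(
        {"id": dataset.ids, "x": dataset.coords[:, 0], "y": dataset.coords[:, 1]}
    ).to_csv(path / "coords.csv", index=False)
    if dataset.labels is not None:
        pd.DataFrame({"id": dataset.ids, "label": dataset.labels}).to_csv(
            path / "labels.csv", index=False
        )
    with open(path / "config.json", "w") as fh:
        json.dump(dataset.meta, fh, indent=2, default=str)
    return path


def read_dataset(path: "str | Path") -> STDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    counts = sp.csr_matrix(mmread(path / "counts.mtx"))
    coords_df = pd.read_csv(path / "coords.csv")
    labels = None
    if (path / "labels.csv").exists():
        labels_df = pd.read_csv(path / "labels.csv")
        labels = (
            labels_df.set_index("id").loc[coords_df["id"], "label"].to_numpy()
        )
    meta = {}
    if (path / "config.json").exists():
        with open(path / "config.json") as fh:
            meta = json.load(fh)
    return STDataset(
        counts=counts,
        coords=coords_df[["x", "y"]].to_numpy(float),
        labels=labels,
        ids=coords_df["id"].to_numpy(object),
        meta=meta,
    )
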