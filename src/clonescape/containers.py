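"""Dataset containers shared across the pipeline.

Two spatial modalities are handled:

* spot-level, Visium-like data — barcoded 55 µm capture spots on a grid,
  each sampling a small mixture of cells (:class:`SpotDataset`);
* single-cell-resolution imaging data, CosMx-like — segmented cells with
  centroid coordinates grouped into fields of view (:class:`CellDataset`).

Counts are kept as sparse CSR matrices (units x genes). Containers are
thin: analysis lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["SpotDataset", "CellDataset", "ReferenceProfiles"]


def _as_csr(counts) -> sp.csr_matrix:
    mat = sp.csr_matrix(counts)
    if (mat.data < 0).any():
        raise ValueError("counts must be non-negative")
    return mat


@dataclass
class SpotDataset:
    """Spot-level spatial expression: counts plus array coordinates."""

    counts: sp.csr_matrix
    spot_ids: np.ndarray
    coordinates: np.ndarray  # (n_spots, 2) array row/col or x/y
    gene_ids: np.ndarray

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(np.unique(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicate spot_ids")
        if self.counts.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if self.coordinates.shape != (len(self.spot_ids), 2):
            raise ValueError("coordinates must be (n_spots, 2)")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_spots(self, mask_or_idx) -> "SpotDataset":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            counts=self.counts[idx],
            spot_ids=self.spot_ids[idx],
            coordinates=self.coordinates[idx],
        )


@dataclass
class CellDataset:
    """Cell-level spatial expression: counts, centroids (pixels) and FOV ids."""

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    centroids: np.ndarray  # (n_cells, 2) x/y in pixels
    fov_id: np.ndarray
    gene_ids: np.ndarray
    type_label: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.fov_id = np.asarray(self.fov_id)
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        n = len(self.cell_ids)
        if self.counts.shape != (n, len(self.gene_ids)):
            raise ValueError("counts shape inconsistent with id lists")
        if self.centroids.shape != (n, 2):
            raise ValueError("centroids must be (n_cells, 2)")
        if len(self.fov_id) != n:
            raise ValueError("fov_id required for every cell")
        if self.type_label is not None:
            self.type_label = np.asarray(self.type_label, dtype=object)
            if len(self.type_label) != n:
                raise ValueError("type_label length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_fovs(self) -> int:
        return len(np.unique(self.fov_id))

    def subset_cells(self, mask_or_idx) -> "CellDataset":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            centroids=self.centroids[idx],
            fov_id=self.fov_id[idx],
            type_label=None if self.type_label is None else self.type_label[idx],
        )


@dataclass
class ReferenceProfiles:
    """Library-size-normalised mean expression per cell type (types x genes)."""

    profiles: pd.DataFrame  # index: cell types, columns: gene ids

    def __post_init__(self):
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("reference profiles must be non-negative")
        nonzero = (self.profiles.to_numpy() > 0).sum(axis=1)
        if (nonzero == 0).any():
            bad = self.profiles.index[nonzero == 0].tolist()
            raise ValueError(f"reference types with no nonzero gene: {bad}")

    @property
    def cell_types(self):
        return list(self.profiles.index)

    @property
    def gene_ids(self):
        return np.asarray(self.profiles.columns, dtype=object)
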