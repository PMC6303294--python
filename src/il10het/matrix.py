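"""Core expression-matrix container shared by every pipeline stage.

The matrix is stored genes x cells (the orientation of 10x MatrixMarket
exports and of full-length gene x cell TSV tables).  Per-gene flags mark
ERCC spike-in and mitochondrial genes; per-cell metadata carries the
dataset label, cell-cycle phase, and (for simulated data) ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PHASES = ("G1", "S", "G2M")


@dataclass
class ExpressionMatrix:
    """Genes x cells integer count matrix with gene flags and cell metadata.

    Parameters
    ----------
    counts : ndarray of shape (n_genes, n_cells)
        Non-negative integer counts.
    gene_ids, cell_ids : array-like of str
        Unique identifiers for rows and columns.
    is_spike, is_mito : boolean arrays per gene
        ERCC spike-in and mitochondrial flags.
    dataset_label : per-cell categorical (e.g. tissue of origin).
    phase_label : per-cell cell-cycle phase in {G1, S, G2M}.
    true_cluster : optional per-cell integer simulation truth.
    true_size_factor : optional per-cell positive real simulation truth.
    true_lowq : optional per-cell boolean; planted low-quality cells.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_spike: np.ndarray
    is_mito: np.ndarray
    dataset_label: np.ndarray
    phase_label: np.ndarray
    true_cluster: np.ndarray | None = None
    true_size_factor: np.ndarray | None = None
    true_lowq: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts has negative entries")
        g, c = self.counts.shape
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.is_spike = np.asarray(self.is_spike, dtype=bool)
        self.is_mito = np.asarray(self.is_mito, dtype=bool)
        self.dataset_label = np.asarray(self.dataset_label, dtype=object)
        self.phase_label = np.asarray(self.phase_label, dtype=object)
        for name, arr, n in (
            ("gene_ids", self.gene_ids, g),
            ("is_spike", self.is_spike, g),
            ("is_mito", self.is_mito, g),
            ("cell_ids", self.cell_ids, c),
            ("dataset_label", self.dataset_label, c),
            ("phase_label", self.phase_label, c),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        for name in ("true_cluster", "true_size_factor", "true_lowq"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != c:
                    raise ValueError(f"{name} has length {len(arr)}, expected {c}")
                setattr(self, name, arr)
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != c:
            raise ValueError("cell_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        """Return a new matrix restricted to the selected cells."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids[idx],
            dataset_label=self.dataset_label[idx],
            phase_label=self.phase_label[idx],
            true_cluster=None if self.true_cluster is None else self.true_cluster[idx],
            true_size_factor=None
            if self.true_size_factor is None
            else self.true_size_factor[idx],
            true_lowq=None if self.true_lowq is None else self.true_lowq[idx],
            meta=dict(self.meta),
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        """Return a new matrix restricted to the selected genes."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            is_spike=self.is_spike[idx],
            is_mito=self.is_mito[idx],
            meta=dict(self.meta),
        )

    def gene_index(self, gene_id: str) -> int:
        """Row index of ``gene_id``; raises KeyError if absent."""
        hits = np.flatnonzero(self.gene_ids == gene_id)
        if len(hits) == 0:
            raise KeyError(f"gene {gene_id!r} not found")
        return int(hits[0])

    def cell_table(self) -> pd.DataFrame:
        """Per-cell metadata as a DataFrame indexed by cell id."""
        d = {
            "dataset_label": self.dataset_label,
            "phase_label": self.phase_label,
        }
        if self.true_cluster is not None:
            d["true_cluster"] = self.true_cluster
        if self.true_size_factor is not None:
            d["true_size_factor"] = self.true_size_factor
        if self.true_lowq is not None:
            d["true_lowq"] = self.true_lowq
        return pd.DataFrame(d, index=pd.Index(self.cell_ids, name="cell_id"))
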