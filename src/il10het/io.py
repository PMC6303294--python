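"""Readers and writers for the on-disk formats.

Single-cell matrices round-trip through two dialects:

* ``mtx_10x`` — ``matrix.mtx`` (MatrixMarket, features x barcodes) with
  ``barcodes.tsv`` and a three-column ``features.tsv`` (id, name, type;
  type is "Gene Expression" or "Spike-in").
* ``dense_tsv`` — a gene x cell TSV table (full-length protocol style).

Cell metadata (dataset label, phase, simulation truth) travels as a sidecar
``cells.csv``.  Spike/mito flags are taken from the features type column
when present and otherwise derived from id prefixes ("ERCC-" for spike-ins,
"mt-"/"MT-" case-insensitively for mitochondrial genes).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix
from .synthdata import BulkTable

SPIKE_PREFIX = "ERCC-"
MITO_PREFIX = "mt-"


def _flags_from_ids(gene_ids: np.ndarray, mito_override: list | None = None):
    ids = np.asarray(gene_ids, dtype=str)
    is_spike = np.char.startswith(ids, SPIKE_PREFIX)
    is_mito = np.char.startswith(np.char.lower(ids), MITO_PREFIX.lower())
    if mito_override:
        is_mito |= np.isin(ids, list(mito_override))
    return is_spike, is_mito


def write_matrix(m: ExpressionMatrix, outdir: str | Path, dialect: str = "mtx_10x") -> None:
    """Write an ExpressionMatrix in the requested dialect plus cells.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dialect == "mtx_10x":
        spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(m.counts))
        pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
        feat = pd.DataFrame(
            {
                "id": m.gene_ids,
                "name": m.gene_ids,
                "type": np.where(m.is_spike, "Spike-in", "Gene Expression"),
            }
        )
        feat.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    elif dialect == "dense_tsv":
        df = pd.DataFrame(m.counts, index=pd.Index(m.gene_ids, name="gene_id"),
                          columns=m.cell_ids)
        df.to_csv(outdir / "counts.tsv", sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    m.cell_table().to_csv(outdir / "cells.csv")


def read_matrix(
    path: str | Path, dialect: str = "mtx_10x", mito_override: list | None = None
) -> ExpressionMatrix:
    """Read an ExpressionMatrix written by :func:`write_matrix`.

    Orientation is genes x cells (10x MatrixMarket is features x barcodes).
    """
    path = Path(path)
    if dialect == "mtx_10x":
        counts = np.asarray(spio.mmread(path / "matrix.mtx").todense()).astype(np.int64)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
        feat = pd.read_csv(path / "features.tsv", sep="\t", header=None,
                           names=["id", "name", "type"])
        gene_ids = feat["id"].to_numpy()
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"matrix is {counts.shape} but sidecars give "
                f"{len(gene_ids)} features x {len(barcodes)} barcodes"
            )
        is_spike_ids, is_mito = _flags_from_ids(gene_ids, mito_override)
        is_spike = (feat["type"] == "Spike-in").to_numpy() | is_spike_ids
    elif dialect == "dense_tsv":
        df = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
        counts = df.to_numpy(dtype=np.int64)
        gene_ids = df.index.to_numpy()
        barcodes = df.columns.to_numpy()
        is_spike, is_mito = _flags_from_ids(gene_ids, mito_override)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    cells_path = path / "cells.csv"
    kwargs = {}
    if cells_path.exists():
        meta = pd.read_csv(cells_path, index_col=0).loc[list(barcodes)]
        kwargs["dataset_label"] = meta["dataset_label"].to_numpy()
        kwargs["phase_label"] = meta["phase_label"].to_numpy()
        for col in ("true_cluster", "true_size_factor", "true_lowq"):
            if col in meta.columns:
                kwargs[col] = meta[col].to_numpy()
    else:
        kwargs["dataset_label"] = np.full(len(barcodes), "unknown", dtype=object)
        kwargs["phase_label"] = np.full(len(barcodes), "G1", dtype=object)
    return ExpressionMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=barcodes,
        is_spike=is_spike,
        is_mito=is_mito,
        **kwargs,
    )


def write_bulk(bulk: BulkTable, path: str | Path) -> None:
    """Bulk counts as TSV with a '#group:' header line carrying sample groups."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#group:\t" + "\t".join(bulk.groups.astype(str)) + "\n")
        bulk.counts.to_csv(fh, sep="\t")
    if bulk.true_de is not None:
        bulk.true_de.to_csv(path.with_suffix(".truth.csv"))


def read_bulk(path: str | Path, mito_override: list | None = None) -> BulkTable:
    """Read a bulk TSV written by :func:`write_bulk`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#group:":
            raise ValueError("bulk table lacks the '#group:' header line")
        groups = header[1:]
        counts = pd.read_csv(fh, sep="\t", index_col=0)
    if len(groups) != counts.shape[1]:
        raise ValueError("group header length does not match sample count")
    _, is_mito = _flags_from_ids(counts.index.to_numpy(), mito_override)
    truth_path = path.with_suffix(".truth.csv")
    true_de = None
    if truth_path.exists():
        true_de = pd.read_csv(truth_path, index_col=0).iloc[:, 0].astype(bool)
        true_de = true_de.reindex(counts.index)
    return BulkTable(
        counts=counts,
        groups=pd.Series(groups, index=counts.columns, name="group"),
        is_mito=pd.Series(is_mito, index=counts.index, name="is_mito"),
        true_de=true_de,
    )


def write_markers(t: pd.DataFrame, path: str | Path) -> None:
    """Marker intensity table as CSV with header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    t.to_csv(path)


def read_markers(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, index_col=0)
    if "true_rich" in t.columns:
        t["true_rich"] = t["true_rich"].astype(bool)
    return t
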