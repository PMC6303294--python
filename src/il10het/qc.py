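"""Cell- and gene-level quality control.

Cells are removed when their log library size or log number of detected
genes falls more than ``n_mads`` median absolute deviations below the
median, or when their mitochondrial fraction is an outlier by the same
rule (above the median by default — high mitochondrial content marks
damaged cells; the literal below-median direction is available behind
``mito_direction``).  Cycling cells are removed on their phase label.
Low-abundance genes are removed on mean count, with protocol-dependent
thresholds (1 for full-length reads, 0.05 for droplet UMIs).

Library size, detected-gene counts and the mitochondrial fraction are all
computed over endogenous (non-spike) genes: spike-in content reflects the
protocol, not cell quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .synthdata import BulkTable

#: normal-consistency constant for the MAD
MAD_SCALE = 1.4826

GENE_MEAN_THRESHOLDS = {"full_length": 1.0, "droplet": 0.05}


@dataclass
class QCThresholds:
    """Outlier-rule parameters for cell and gene filtering."""

    n_mads: float = 3.0
    min_gene_mean: float = 1.0
    drop_phases: frozenset = frozenset({"S", "G2M"})
    mito_direction: str = "above"  # "above" (default) or "below" (literal rule)

    def __post_init__(self) -> None:
        if self.n_mads <= 0:
            raise ValueError("n_mads must be positive")
        if self.min_gene_mean <= 0:
            raise ValueError("min_gene_mean must be positive")
        if self.mito_direction not in ("above", "below"):
            raise ValueError("mito_direction must be 'above' or 'below'")

    @classmethod
    def for_protocol(cls, protocol: str, **kw) -> "QCThresholds":
        """Thresholds with the protocol's gene-abundance cutoff."""
        if protocol not in GENE_MEAN_THRESHOLDS:
            raise ValueError(f"unknown protocol {protocol!r}")
        return cls(min_gene_mean=GENE_MEAN_THRESHOLDS[protocol], **kw)


@dataclass
class QCReport:
    """Per-cell / per-gene QC metrics, pass flags, and removal counts."""

    cell_table: pd.DataFrame | None = None
    gene_table: pd.DataFrame | None = None
    removed: dict = field(default_factory=dict)
    cutoffs: dict = field(default_factory=dict)
    mad_scale: float = MAD_SCALE


def _mad_lower_cutoff(x: np.ndarray, n_mads: float) -> float:
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    return med - n_mads * mad


def _mad_upper_cutoff(x: np.ndarray, n_mads: float) -> float:
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    return med + n_mads * mad


def filter_cells(
    m: ExpressionMatrix,
    t: QCThresholds = QCThresholds(),
    cutoffs: dict | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove outlier cells; returns the filtered matrix and a QCReport.

    All criteria are computed on the input matrix, so filtering order cannot
    matter.  When ``cutoffs`` (from a previous report) is given, the frozen
    numeric cutoffs are reused instead of being recomputed — reapplying a
    frozen rule to its own output removes nothing.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty matrix")
    endo = ~m.is_spike
    totals = m.counts[endo].sum(axis=0).astype(float)
    n_detected = (m.counts[endo] > 0).sum(axis=0).astype(float)
    mito_counts = m.counts[endo & m.is_mito].sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lib = np.log(totals)
        log_ng = np.log(n_detected)
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    if cutoffs is None:
        cutoffs = {
            "log_library_size": _mad_lower_cutoff(log_lib, t.n_mads),
            "log_n_genes": _mad_lower_cutoff(log_ng, t.n_mads),
            "mito_fraction": (
                _mad_upper_cutoff(mito_frac, t.n_mads)
                if t.mito_direction == "above"
                else _mad_lower_cutoff(mito_frac, t.n_mads)
            ),
        }
    pass_lib = log_lib >= cutoffs["log_library_size"]
    pass_ng = log_ng >= cutoffs["log_n_genes"]
    if t.mito_direction == "above":
        pass_mito = mito_frac <= cutoffs["mito_fraction"]
    else:
        pass_mito = mito_frac >= cutoffs["mito_fraction"]
    pass_phase = ~np.isin(m.phase_label, list(t.drop_phases))
    overall = pass_lib & pass_ng & pass_mito & pass_phase

    cell_table = pd.DataFrame(
        {
            "log_library_size": log_lib,
            "log_n_genes": log_ng,
            "mito_fraction": mito_frac,
            "pass_library_size": pass_lib,
            "pass_n_genes": pass_ng,
            "pass_mito": pass_mito,
            "pass_phase": pass_phase,
            "pass_overall": overall,
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    removed = {
        "library_size": int((~pass_lib).sum()),
        "n_genes": int((~pass_ng).sum()),
        "mito": int((~pass_mito).sum()),
        "phase": int((~pass_phase).sum()),
        "cells_total": int((~overall).sum()),
    }
    if not overall.any():
        raise ValueError(f"all cells removed by QC; per-criterion counts: {removed}")
    report = QCReport(cell_table=cell_table, removed=removed, cutoffs=dict(cutoffs))
    return m.subset_cells(overall), report


def filter_genes(
    m: ExpressionMatrix, t: QCThresholds = QCThresholds()
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-abundance genes (mean count < threshold).

    Spike-in genes are retained regardless — they anchor the technical
    variance trend — but remain flagged via ``is_spike``.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty matrix")
    means = m.counts.mean(axis=1)
    keep = (means >= t.min_gene_mean) | m.is_spike
    if not (keep & ~m.is_spike).any():
        raise ValueError("all non-spike genes removed by the abundance filter")
    gene_table = pd.DataFrame(
        {"mean_count": means, "pass": keep},
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    report = QCReport(
        gene_table=gene_table,
        removed={"genes_low_abundance": int((~keep).sum())},
        cutoffs={"min_gene_mean": t.min_gene_mean},
    )
    return m.subset_genes(keep), report


def filter_bulk_genes(
    bulk: BulkTable, min_count: int = 5, min_samples: int = 4
) -> tuple[BulkTable, QCReport]:
    """Bulk gene filter: drop mitochondrial genes and genes that fail to have
    over ``min_count`` counts in more than ``min_samples`` samples.

    Both comparisons are strict (> min_count, > min_samples), the reading
    recorded in the report.
    """
    n_samples = bulk.counts.shape[1]
    if n_samples < min_samples + 1:
        raise ValueError(
            f"only {n_samples} samples; the rule needs at least {min_samples + 1}"
        )
    n_over = (bulk.counts > min_count).sum(axis=1)
    keep = (n_over > min_samples) & ~bulk.is_mito
    gene_table = pd.DataFrame(
        {"n_samples_over": n_over, "is_mito": bulk.is_mito, "pass": keep}
    )
    report = QCReport(
        gene_table=gene_table,
        removed={
            "mito": int(bulk.is_mito.sum()),
            "low_count": int(((n_over <= min_samples) & ~bulk.is_mito).sum()),
        },
        cutoffs={
            "min_count": min_count,
            "min_samples": min_samples,
            "interpretation": "strict: count > min_count in > min_samples samples",
        },
    )
    filtered = BulkTable(
        counts=bulk.counts.loc[keep],
        groups=bulk.groups,
        is_mito=bulk.is_mito.loc[keep],
        true_de=None if bulk.true_de is None else bulk.true_de.loc[keep],
    )
    return filtered, report


def reporter_concordance(
    m: ExpressionMatrix, reporter_gene: str, target_gene: str
) -> tuple[float, float]:
    """Concordance between a fluorescent-reporter transcript and its target.

    Returns the fraction of cells expressing the target (count > 0) and the
    Spearman correlation of the two genes' normalized log-expression across
    cells.  Models the check that eGFP-sorted cells indeed express Il10 and
    that the two transcripts correlate.
    """
    ri = m.gene_index(reporter_gene)
    ti = m.gene_index(target_gene)
    target = m.counts[ti].astype(float)
    reporter = m.counts[ri].astype(float)
    fraction = float((target > 0).mean())
    totals = m.counts[~m.is_spike].sum(axis=0).astype(float)
    totals = np.maximum(totals, 1.0)
    factors = totals / totals.mean()
    lt = np.log2(target / factors + 1.0)
    lr = np.log2(reporter / factors + 1.0)
    if np.ptp(lt) == 0 or np.ptp(lr) == 0:
        rho = 1.0 if ti == ri else np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(stats.spearmanr(lr, lt).statistic)
    return fraction, rho
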