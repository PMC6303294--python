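"""Highly-variable-gene detection by mean-variance decomposition.

Per-gene variance of normalized log-expression is split into a technical
component — the value of a smooth mean-variance trend at the gene's mean,
fitted to spike-in genes when available (their variation is purely
technical) or to all genes as a fallback — and a biological component,
the excess over the trend.  A gene is called highly variable when its
biological variance exceeds a protocol-specific threshold (0.5 in log2
units for full-length data, 0.05 for droplet UMIs) at a Benjamini-Hochberg
false discovery rate below 5%.

Significance of the excess uses a one-sided variance-ratio test: under the
null the total variance equals the trend value, and (n-1) * total/technical
is referred to an F distribution with (n_cells - 1, d_trend) degrees of
freedom.  d_trend reflects the precision of the trend estimate; the default
treats the trend as well determined (d_trend -> infinity, collapsing the
reference to a scaled chi-square), and the value used is recorded in the
output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .normalize import LogExpressionMatrix

BIO_THRESHOLDS = {"full_length": 0.5, "droplet": 0.05}


@dataclass
class TechnicalTrend:
    """Smooth nonnegative mean -> technical-variance trend.

    Evaluated by linear interpolation inside the fitted mean range and by
    the nearest endpoint value outside it.
    """

    means: np.ndarray
    variances: np.ndarray
    source: str  # "spikes" or "all_genes"
    span: float
    n_points: int
    meta: dict = field(default_factory=dict)

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(mean, dtype=float), self.means, self.variances)


def fit_technical_trend(
    logm: LogExpressionMatrix, use_spikes: bool = True, span: float = 0.3
) -> TechnicalTrend:
    """Fit the technical mean-variance trend by LOESS local regression.

    Fitted to (mean, variance) pairs of spike-in genes when ``use_spikes``,
    else of all genes; floored at zero.
    """
    if use_spikes:
        sel = logm.is_spike
        source = "spikes"
        if sel.sum() < 10:
            raise ValueError(
                "fewer than 10 spike-in genes; fall back to use_spikes=False"
            )
    else:
        sel = np.ones(logm.n_genes, dtype=bool)
        source = "all_genes"
    x = logm.values[sel].mean(axis=1)
    v = logm.values[sel].var(axis=1, ddof=1)
    if np.unique(x).size < 10:
        raise ValueError(
            "fewer than 10 distinct trend means; fall back to all genes or more data"
        )
    fitted = lowess(v, x, frac=span, return_sorted=True)
    xs, ys = fitted[:, 0], np.maximum(fitted[:, 1], 0.0)
    # collapse duplicate means so interpolation is well defined
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    np.add.at(uy, inv, ys)
    uy /= np.bincount(inv)
    return TechnicalTrend(
        means=ux, variances=uy, source=source, span=span, n_points=int(sel.sum())
    )


def decompose_variance(
    logm: LogExpressionMatrix,
    trend: TechnicalTrend,
    bio_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    d_trend: float | None = None,
) -> pd.DataFrame:
    """Per-gene variance decomposition and HVG calls.

    Returns a DataFrame indexed by gene id with columns ``mean``,
    ``total_var``, ``tech_var``, ``bio_var`` (= total - tech, exactly),
    ``p_value``, ``fdr``, ``is_spike`` and ``is_hvg``.  Spike-in genes are
    never flagged as HVGs.  Parameters used are recorded in ``DataFrame.attrs``.
    """
    n = logm.n_cells
    if n < 3:
        raise ValueError("need at least 3 cells for a variance decomposition")
    if d_trend is None:
        d_trend = np.inf
    mean = logm.values.mean(axis=1)
    total = logm.values.var(axis=1, ddof=1)
    tech = trend(mean)
    bio = total - tech

    # one-sided variance-ratio test of total against the technical expectation;
    # in the d_trend -> inf limit the F reference collapses to a scaled chi-square
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tech > 0, total / np.maximum(tech, 1e-300), np.inf)
    safe_ratio = np.where(tech > 0, ratio, 1.0)
    if np.isinf(d_trend):
        p_pos = stats.chi2.sf(safe_ratio * (n - 1), n - 1)
    else:
        p_pos = stats.f.sf(safe_ratio, n - 1, d_trend)
    p = np.where(tech > 0, p_pos, np.where(total > 0, 0.0, 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    is_hvg = (bio > bio_threshold) & (fdr < fdr_threshold) & ~logm.is_spike

    table = pd.DataFrame(
        {
            "mean": mean,
            "total_var": total,
            "tech_var": tech,
            "bio_var": bio,
            "p_value": p,
            "fdr": fdr,
            "is_spike": logm.is_spike,
            "is_hvg": is_hvg,
        },
        index=pd.Index(logm.gene_ids, name="gene_id"),
    )
    table.attrs.update(
        {
            "bio_threshold": bio_threshold,
            "fdr_threshold": fdr_threshold,
            "n_cells": n,
            "d_trend": d_trend,
            "trend_source": trend.source,
            "trend_span": trend.span,
            "test": "one-sided F ratio, df (n_cells - 1, d_trend)",
        }
    )
    return table


def count_hvgs(table: pd.DataFrame) -> int:
    """Number of genes flagged highly variable."""
    if len(table) == 0:
        return 0
    return int(table["is_hvg"].sum())


def hvg_gene_ids(table: pd.DataFrame) -> np.ndarray:
    """Identifiers of the flagged genes, in table order."""
    return table.index[table["is_hvg"]].to_numpy()
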