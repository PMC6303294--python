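"""Cross-dataset cluster matching, simplified bulk DE, and signature scoring.

Cluster matching follows the non-zero Spearman convention: for each pair of
cluster-average profiles, the correlation is computed over the genes whose
value is non-zero in BOTH profiles (the symmetric reading; an either-non-zero
mode is available).  The bulk differential-expression stage is a deliberately
simplified self-contained pipeline — median-of-ratios size factors and a
per-gene pooled two-sample t-test on log2 normalized counts — with the
published decision rule (fold change above 1.5, FDR below 1%); it does not
reimplement negative-binomial dispersion shrinkage, and says so in its
provenance.  A signature profile (averaged normalized counts of a reference
bulk population, restricted to the single-cell dataset's HVGs) is scored
against each cell by rank correlation over the shared non-zero genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import LogExpressionMatrix
from .synthdata import BulkTable


def cluster_profiles(logm: LogExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster arithmetic mean of normalized log-expression (genes x clusters)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels[labels >= 0])
    if uniq.size == 0:
        raise ValueError("no non-noise clusters")
    cols = {c: logm.values[:, labels == c].mean(axis=1) for c in uniq}
    return pd.DataFrame(cols, index=pd.Index(logm.gene_ids, name="gene_id"))


def _nonzero_spearman(x: np.ndarray, y: np.ndarray, mode: str, min_genes: int):
    if mode == "both":
        mask = (x != 0) & (y != 0)
    elif mode == "either":
        mask = (x != 0) | (y != 0)
    else:
        raise ValueError("mode must be 'both' or 'either'")
    n = int(mask.sum())
    if n < min_genes:
        return np.nan, n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x[mask], y[mask]).statistic
    return float(rho), n


@dataclass
class ClusterSimilarityMatrix:
    """Spearman rho between cluster profiles of two datasets."""

    rho: pd.DataFrame  # clusters of A x clusters of B
    n_genes: pd.DataFrame
    nonzero_mode: str = "both"


def cluster_similarity(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    nonzero_mode: str = "both",
    min_genes: int = 10,
) -> ClusterSimilarityMatrix:
    """Pairwise non-zero Spearman correlation between two profile sets.

    Profiles are intersected on their shared gene universe first; each entry
    is then computed over the genes non-zero in both members of the pair
    (average-rank tie handling).  Entries with fewer than ``min_genes``
    usable genes are set missing with a warning.
    """
    shared = profiles_a.index.intersection(profiles_b.index)
    if shared.empty:
        raise ValueError("no shared genes between the two profile sets")
    pa = profiles_a.loc[shared]
    pb = profiles_b.loc[shared]
    rho = pd.DataFrame(index=pa.columns, columns=pb.columns, dtype=float)
    ng = pd.DataFrame(index=pa.columns, columns=pb.columns, dtype=int)
    for a in pa.columns:
        for b in pb.columns:
            r, n = _nonzero_spearman(
                pa[a].to_numpy(), pb[b].to_numpy(), nonzero_mode, min_genes
            )
            if np.isnan(r):
                warnings.warn(
                    f"pair ({a}, {b}) has {n} < {min_genes} shared non-zero genes"
                )
            rho.loc[a, b] = r
            ng.loc[a, b] = n
    return ClusterSimilarityMatrix(rho=rho, n_genes=ng, nonzero_mode=nonzero_mode)


def median_of_ratios_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors, geometric mean 1.

    The reference is the per-gene geometric mean over samples, using only
    genes with all-positive counts.
    """
    arr = counts.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() < 1:
        raise ValueError("no genes with all-positive counts for the reference")
    logref = np.log(arr[pos]).mean(axis=1)
    ratios = np.log(arr[pos]) - logref[:, None]
    logf = np.median(ratios, axis=0)
    logf = logf - logf.mean()  # geometric mean 1
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


@dataclass
class BulkDEResult:
    """Per-gene bulk DE table with the FC / FDR decision rule applied."""

    table: pd.DataFrame
    group_a: str
    group_b: str
    fc_threshold: float
    fdr_threshold: float
    size_factors: pd.Series
    provenance: dict = field(default_factory=dict)


def bulk_de(
    bulk: BulkTable,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
    pseudocount: float = 0.5,
) -> BulkDEResult:
    """Simplified pairwise bulk DE between two sample groups.

    Median-of-ratios normalization, per-gene pooled two-sample t-test on
    log2(normalized count + pseudocount), Benjamini-Hochberg FDR; a gene is
    DE when |log2 fold change| > log2(fc_threshold) and FDR < fdr_threshold.
    """
    for g in (group_a, group_b):
        if (bulk.groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    factors = median_of_ratios_factors(bulk.counts)
    norm = bulk.counts / factors
    logn = np.log2(norm + pseudocount)
    xa = logn.loc[:, (bulk.groups == group_a).to_numpy()].to_numpy()
    xb = logn.loc[:, (bulk.groups == group_b).to_numpy()].to_numpy()
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    tres = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    p = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
    fdr = multipletests(p, method="fdr_bh")[1]
    is_de = (np.abs(lfc) > np.log2(fc_threshold)) & (fdr < fdr_threshold)
    table = pd.DataFrame(
        {
            f"mean_{group_a}": xa.mean(axis=1),
            f"mean_{group_b}": xb.mean(axis=1),
            "log2fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "is_de": is_de,
        },
        index=bulk.counts.index,
    )
    return BulkDEResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
        size_factors=factors,
        provenance={
            "normalization": "median-of-ratios (geometric-mean reference)",
            "test": "per-gene pooled two-sample t on log2 normalized counts",
            "note": "simplified pipeline; no NB dispersion shrinkage",
            "pseudocount": pseudocount,
        },
    )


@dataclass
class SignatureProfile:
    """Averaged reference expression over a gene set (the signature)."""

    values: pd.Series  # per-gene averaged reference expression
    provenance: dict = field(default_factory=dict)


def signature_from_bulk(
    bulk: BulkTable,
    group: str,
    hvg_genes,
    de_result: BulkDEResult | None = None,
) -> SignatureProfile:
    """Signature = mean normalized counts of one bulk group over the HVGs.

    ``hvg_genes`` is the HVG list of the target single-cell dataset; the
    signature is restricted to the HVGs present in the bulk table.  When a
    DE result is given, its significant genes are recorded in provenance as
    the genes defining the population.
    """
    if (bulk.groups == group).sum() == 0:
        raise ValueError(f"group {group!r} not present in bulk table")
    factors = median_of_ratios_factors(bulk.counts)
    norm = bulk.counts / factors
    avg = norm.loc[:, (bulk.groups == group).to_numpy()].mean(axis=1)
    genes = pd.Index(hvg_genes).intersection(avg.index)
    if len(genes) < 10:
        raise ValueError(
            f"only {len(genes)} signature genes intersect the HVGs; need >= 10"
        )
    prov = {"bulk_group": group, "n_hvg_genes": int(len(genes))}
    if de_result is not None:
        prov["de_genes"] = list(de_result.table.index[de_result.table["is_de"]])
        prov["de_filter"] = (
            f"|FC| > {de_result.fc_threshold}, FDR < {de_result.fdr_threshold}"
        )
    return SignatureProfile(values=avg.loc[genes], provenance=prov)


def signature_correlation(
    logm: LogExpressionMatrix,
    sig: SignatureProfile,
    method: str = "spearman",
    min_genes: int = 10,
) -> pd.Series:
    """Per-cell correlation between expression and the signature profile.

    For each cell, the correlation (Spearman by default, rank-based and hence
    invariant to monotone transformations of the signature; Pearson behind
    ``method``) is computed over signature genes non-zero in both the cell
    and the signature.  Cells with fewer than ``min_genes`` usable genes get
    a missing value.
    """
    gene_pos = {g: i for i, g in enumerate(logm.gene_ids)}
    genes = [g for g in sig.values.index if g in gene_pos]
    if len(genes) < min_genes:
        raise ValueError(
            f"only {len(genes)} signature genes found in the matrix; need >= {min_genes}"
        )
    rows = np.array([gene_pos[g] for g in genes])
    sig_vals = sig.values.loc[genes].to_numpy(dtype=float)
    expr = logm.values[rows, :]
    out = np.full(logm.n_cells, np.nan)
    for j in range(logm.n_cells):
        x = expr[:, j]
        mask = (x != 0) & (sig_vals != 0)
        if mask.sum() < min_genes:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "spearman":
                out[j] = stats.spearmanr(x[mask], sig_vals[mask]).statistic
            elif method == "pearson":
                out[j] = stats.pearsonr(x[mask], sig_vals[mask]).statistic
            else:
                raise ValueError("method must be 'spearman' or 'pearson'")
    return pd.Series(out, index=pd.Index(logm.cell_ids, name="cell_id"), name="rho")
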