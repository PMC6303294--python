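"""t-SNE embedding, DBSCAN clustering, and cluster marker characterization.

The normalized log-expression of the HVGs is reduced to 50 principal
components and embedded in 2-D by t-SNE; clusters are then found by DBSCAN
on the embedding, with the density radius eps either given or set
automatically at the knee of the sorted min_pts-nearest-neighbor distance
curve.  Clusters are characterized by ranking genes on the log2 fold-change
of mean normalized log-expression in-cluster versus all other clustered
cells, and cluster pairs by the overlap of their top-k marker lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .normalize import LogExpressionMatrix


@dataclass
class ClusterModel:
    """2-D embedding with DBSCAN labels (-1 = noise) and parameters used."""

    embedding: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def embed_tsne(
    logm: LogExpressionMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
    n_pca: int = 50,
    max_iter: int = 1000,
    exact: bool = False,
) -> np.ndarray:
    """2-D t-SNE of cells on the given (HVG-restricted) log-expression.

    Deterministic given the seed: PCA uses a full solver and t-SNE is
    initialized from the PCA of the input.
    """
    n = logm.n_cells
    if n < 3 * perplexity:
        raise ValueError(f"need at least 3*perplexity={3 * perplexity:.0f} cells, have {n}")
    X = logm.values.T  # cells x genes
    if X.shape[1] > n_pca:
        X = PCA(n_components=n_pca, svd_solver="full", random_state=seed).fit_transform(X)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=max(n / 12.0, 50.0),
        max_iter=max_iter,
        init="pca",
        random_state=seed,
        method="exact" if exact else "barnes_hut",
        n_jobs=1,
    )
    return tsne.fit_transform(X)


def auto_eps(embedding: np.ndarray, min_pts: int = 10) -> float:
    """eps at the knee (maximum curvature) of the sorted kNN-distance curve.

    The knee is the point of the ascending min_pts-th nearest-neighbor
    distance curve farthest from the chord joining its endpoints.
    """
    n = embedding.shape[0]
    k = min(min_pts, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, _ = nn.kneighbors(embedding)
    curve = np.sort(dist[:, -1])
    if curve[-1] == curve[0]:
        return max(curve[-1], 1e-12)
    x = np.arange(n, dtype=float)
    # distance from each point to the chord between the curve's endpoints
    dx, dy = n - 1.0, curve[-1] - curve[0]
    norm = np.hypot(dx, dy)
    d = np.abs(dy * x - dx * (curve - curve[0])) / norm
    return float(max(curve[int(np.argmax(d))], 1e-12))


def cluster_dbscan(
    embedding: np.ndarray,
    eps: float | str = "auto",
    min_pts: int = 10,
    cell_ids: np.ndarray | None = None,
) -> ClusterModel:
    """Density clustering of the embedding; noise labelled -1."""
    embedding = np.asarray(embedding, dtype=float)
    if np.allclose(embedding, embedding[0]):
        warnings.warn("degenerate embedding (all points identical); single cluster")
        labels = np.zeros(len(embedding), dtype=int)
        eps_used = 1.0
    else:
        eps_used = auto_eps(embedding, min_pts) if eps == "auto" else float(eps)
        labels = DBSCAN(eps=eps_used, min_samples=min_pts).fit_predict(embedding)
    if cell_ids is None:
        cell_ids = np.arange(len(embedding))
    return ClusterModel(
        embedding=embedding,
        labels=labels,
        cell_ids=np.asarray(cell_ids),
        params={"eps": eps_used, "min_pts": min_pts},
    )


@dataclass
class MarkerTable:
    """Per-(cluster, gene) fold-change ranking and top-k marker lists."""

    table: pd.DataFrame  # columns: cluster, gene, mean_in, mean_out, log2fc, rank
    top_k: dict  # cluster -> list of gene ids
    k: int


def cluster_markers(
    logm: LogExpressionMatrix,
    labels: np.ndarray,
    top_k: int = 100,
    wilcoxon_p: bool = False,
) -> MarkerTable:
    """Rank genes per cluster by log2 fold-change in- vs out-of-cluster.

    Fold changes are differences of mean normalized log2-expression between
    the cluster's cells and all other non-noise cells.  Ties are broken by
    the higher in-cluster mean, then lexicographically by gene id.  Noise
    cells are excluded; clusters with fewer than 3 cells are dropped with a
    warning.  Spike-in genes are excluded from marker lists.  A Wilcoxon
    rank-sum p per gene is reported when ``wilcoxon_p`` (informational; the
    ranking itself is fold-change only).
    """
    labels = np.asarray(labels)
    clustered = labels >= 0
    uniq = [c for c in np.unique(labels[clustered])]
    keep_clusters = []
    for c in uniq:
        if (labels == c).sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; excluded from markers")
        else:
            keep_clusters.append(c)
    if len(keep_clusters) < 2:
        raise ValueError("need at least 2 non-noise clusters with >= 3 cells")

    endo = ~logm.is_spike
    values = logm.values[endo]
    gene_ids = logm.gene_ids[endo]
    rows = []
    top = {}
    for c in keep_clusters:
        in_mask = labels == c
        out_mask = clustered & np.isin(labels, keep_clusters) & ~in_mask
        mean_in = values[:, in_mask].mean(axis=1)
        mean_out = values[:, out_mask].mean(axis=1)
        lfc = mean_in - mean_out
        order = np.lexsort((gene_ids.astype(str), -mean_in, -lfc))
        rank = np.empty(len(gene_ids), dtype=int)
        rank[order] = np.arange(1, len(gene_ids) + 1)
        df = pd.DataFrame(
            {
                "cluster": c,
                "gene": gene_ids,
                "mean_in": mean_in,
                "mean_out": mean_out,
                "log2fc": lfc,
                "rank": rank,
            }
        )
        if wilcoxon_p:
            pvals = np.ones(len(gene_ids))
            for i in range(len(gene_ids)):
                x, y = values[i, in_mask], values[i, out_mask]
                if np.ptp(np.concatenate([x, y])) > 0:
                    pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            df["wilcoxon_p"] = pvals
        rows.append(df.sort_values("rank"))
        top[c] = list(gene_ids[order[:top_k]])
    return MarkerTable(table=pd.concat(rows, ignore_index=True), top_k=top, k=top_k)


def top_gene_overlap(t: MarkerTable, cluster_a, cluster_b, k: int | None = None) -> int:
    """Number of genes shared by the two clusters' top-k marker lists."""
    for c in (cluster_a, cluster_b):
        if c not in t.top_k:
            raise KeyError(f"cluster {c!r} not in marker table")
    k = t.k if k is None else min(k, t.k)
    return len(set(t.top_k[cluster_a][:k]) & set(t.top_k[cluster_b][:k]))
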