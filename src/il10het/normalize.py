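"""Size-factor estimation and log-normalization.

Three size-factor estimators are provided:

* ``libsize_factors`` — proportional to total endogenous counts; biased when
  expression composition differs between cell groups.
* ``pooled_factors`` — the deconvolution-by-pooling estimator: cells are
  summed into overlapping pools, each pool's summed profile is compared to a
  reference pseudo-cell by a robust median ratio, and the resulting linear
  system is solved for per-cell factors.  Pooling suppresses the zero
  inflation that breaks per-cell median ratios at single-cell depth.
* ``spike_factors`` — proportional to total spike-in counts; since spike-ins
  are added at fixed concentration, these capture purely technical depth and
  are used to normalize the spike-in genes that anchor the technical trend.

All factor vectors are rescaled to mean 1.  Normalized expression is
``log2(count / factor + pseudocount)`` with pseudocount 1 by default, so the
highly-variable-gene thresholds downstream are in log2 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lsqr

from .matrix import ExpressionMatrix

DEFAULT_POOL_SIZES = tuple(range(21, 102, 5))  # 21, 26, ..., 101


@dataclass
class SizeFactorVector:
    """Per-cell positive factors (mean 1) with the estimating method tag."""

    factors: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")


@dataclass
class LogExpressionMatrix:
    """Genes x cells matrix of log2(count / size_factor + pseudocount)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_spike: np.ndarray
    is_mito: np.ndarray
    pseudocount: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask_or_idx) -> "LogExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LogExpressionMatrix(
            values=self.values[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            is_spike=self.is_spike[idx],
            is_mito=self.is_mito[idx],
            pseudocount=self.pseudocount,
            meta=dict(self.meta),
        )


def libsize_factors(m: ExpressionMatrix) -> SizeFactorVector:
    """Factors proportional to each cell's total endogenous (non-spike) counts."""
    totals = m.counts[~m.is_spike].sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero library size: {list(m.cell_ids[zero])}")
    return SizeFactorVector(totals / totals.mean(), "libsize")


def spike_factors(m: ExpressionMatrix, floor: float = 1e-8) -> SizeFactorVector:
    """Factors proportional to each cell's total spike-in counts."""
    if not m.is_spike.any():
        raise ValueError(
            "no spike-in genes present; fit the technical trend on endogenous genes"
        )
    totals = m.counts[m.is_spike].sum(axis=0).astype(float)
    if totals.sum() == 0:
        raise ValueError("all spike-in counts are zero; use the all-gene trend fallback")
    if (totals == 0).any():
        warnings.warn("cells with zero spike counts; factors floored")
        totals = np.maximum(totals, floor)
    return SizeFactorVector(totals / totals.mean(), "spike")


def _ring_order(totals: np.ndarray, cell_ids: np.ndarray) -> np.ndarray:
    """Cells on a ring, alternating smallest/largest library size.

    Canonical regardless of input column order: ties on the total are broken
    by cell id, so shuffling the input columns cannot change pool membership.
    """
    order = np.lexsort((np.asarray(cell_ids, dtype=str), totals))
    ring = np.empty_like(order)
    half = (len(order) + 1) // 2
    ring[0::2] = order[:half]
    ring[1::2] = order[len(order) - 1 : half - 1 : -1]
    return ring


def pooled_factors(
    m: ExpressionMatrix,
    pool_sizes: tuple | None = None,
    ridge_weight: float = 1e-3,
    floor_frac: float = 1e-6,
) -> SizeFactorVector:
    """Deconvolution-by-pooling size factors.

    Algorithm: (1) reference pseudo-cell = per-gene mean over all cells;
    (2) cells ordered on a ring by library size, alternating smallest and
    largest so every window mixes depths; (3) for every pool size and every
    rotation of the ring, the median across genes of pool-summed counts over
    the reference gives one linear equation — the sum of the pool's factors;
    (4) the overdetermined sparse system is solved by least squares, with
    low-weight per-cell identity equations anchored at the library-size
    factors for numerical uniqueness; (5) factors rescaled to mean 1.
    """
    endo = ~m.is_spike
    counts = m.counts[endo].astype(float)
    n = m.n_cells
    if pool_sizes is None:
        pool_sizes = tuple(min(s, n) for s in DEFAULT_POOL_SIZES)
    pool_sizes = tuple(sorted({min(int(s), n) for s in pool_sizes}))
    if n < min(pool_sizes):
        raise ValueError(f"need at least {min(pool_sizes)} cells, have {n}")

    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("cells with zero library size cannot be pooled")
    ref = counts.mean(axis=1)
    pos = ref > 0
    if pos.sum() < 1:
        raise ValueError("reference pseudo-cell is all zero")
    ref_pos = ref[pos]
    counts_pos = counts[pos]

    ring = _ring_order(totals, m.cell_ids)
    ring_counts = counts_pos[:, ring]
    # wrap-around cumulative sums: pool sums for every rotation in O(g*n)
    csum = np.concatenate(
        [np.zeros((ring_counts.shape[0], 1)), np.cumsum(ring_counts, axis=1)], axis=1
    )
    total_per_gene = csum[:, -1]

    rows, cols, vals, b = [], [], [], []
    eq = 0
    member_base = np.arange(n)
    for s in pool_sizes:
        offs = member_base[:, None] + np.arange(s)[None, :]  # n rotations x s members
        wrapped = offs % n
        ends = member_base + s
        pool_sums = np.where(
            (ends <= n)[None, :],
            csum[:, np.minimum(ends, n)] - csum[:, member_base],
            (csum[:, [-1]] - csum[:, member_base]) + csum[:, np.maximum(ends - n, 0)],
        )
        est = np.median(pool_sums / ref_pos[:, None], axis=0)  # per rotation
        members = ring[wrapped]  # n x s
        rows.append(np.repeat(np.arange(eq, eq + n), s))
        cols.append(members.ravel())
        vals.append(np.ones(n * s))
        b.append(est)
        eq += n

    lib = totals / totals.mean()
    # ridge-like identity equations guarantee a unique solution
    rows.append(np.arange(eq, eq + n))
    cols.append(np.arange(n))
    vals.append(np.full(n, ridge_weight))
    b.append(ridge_weight * lib)
    eq += n

    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(eq, n),
    )
    rhs = np.concatenate(b)
    sol = lsqr(A, rhs, atol=1e-10, btol=1e-10, iter_lim=10000)[0]
    if np.any(~np.isfinite(sol)):
        raise ValueError("singular pooling system; add more pool sizes")
    floor = floor_frac * np.abs(sol).mean()
    if np.any(sol <= 0):
        warnings.warn(
            f"{int((sol <= 0).sum())} non-positive pooled factors clipped to floor"
        )
        sol = np.maximum(sol, floor)
    sol = sol / sol.mean()
    return SizeFactorVector(
        sol, "pooled", meta={"pool_sizes": pool_sizes, "ridge_weight": ridge_weight}
    )


def log_normalize(
    m: ExpressionMatrix,
    f: SizeFactorVector,
    pseudocount: float = 1.0,
    spike_f: SizeFactorVector | None = None,
) -> LogExpressionMatrix:
    """log2(count / factor + pseudocount), genes x cells.

    When ``spike_f`` is given, spike-in rows are normalized by the spike
    factors (technical depth) while endogenous rows use ``f``.
    """
    factors = np.asarray(f.factors, dtype=float)
    if factors.shape != (m.n_cells,):
        raise ValueError("factor vector length does not match cell count")
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor")
    per_gene_factors = np.tile(factors, (m.n_genes, 1))
    if spike_f is not None and m.is_spike.any():
        per_gene_factors[m.is_spike, :] = spike_f.factors
    values = np.log2(m.counts / per_gene_factors + pseudocount)
    return LogExpressionMatrix(
        values=values,
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        is_spike=m.is_spike,
        is_mito=m.is_mito,
        pseudocount=pseudocount,
        meta={"size_factor_method": f.method, "log_base": 2},
    )
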