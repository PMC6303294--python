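"""Bootstrap HVG-count statistic for comparing transcriptional heterogeneity.

A dataset's heterogeneity is summarized by repeatedly drawing fixed-size
cell subsamples (100 cells by default), re-running the full HVG procedure —
size factors, normalization, technical trend and variance decomposition are
all recomputed on the subsample — and recording the number of HVGs.  Two
datasets are then compared by a two-tailed pooled-variance Student's t-test
on their per-repeat HVG counts.

Each repeat draws its cells without replacement from the full pool
(a repeat is a set of distinct cells); successive repeats draw independently
from the full pool again.  Sampling cells with replacement within a repeat
is available behind ``within_replacement=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import hvg as hvg_mod
from . import normalize as norm_mod
from .matrix import ExpressionMatrix
from .qc import GENE_MEAN_THRESHOLDS


@dataclass
class BootstrapResult:
    """Per-repeat HVG counts for two datasets plus their t comparison."""

    counts_a: np.ndarray
    counts_b: np.ndarray
    subsample_size: int
    n_repeats: int
    seed: int
    t_statistic: float = np.nan
    p_value: float = np.nan
    shapiro_p: dict = field(default_factory=dict)


def hvg_count_for_cells(
    m: ExpressionMatrix,
    cell_idx: np.ndarray,
    protocol: str = "full_length",
    size_factor_method: str = "pooled",
    use_spikes: bool | None = None,
) -> int:
    """Run the full HVG procedure on a cell subset and count the HVGs.

    Gene abundance filtering, size factors, the technical trend and the
    decomposition are all computed on the subset alone, so the statistic
    for one dataset can never depend on another.
    """
    sub = m.subset_cells(np.asarray(cell_idx))
    means = sub.counts.mean(axis=1)
    keep = (means >= GENE_MEAN_THRESHOLDS[protocol]) | sub.is_spike
    sub = sub.subset_genes(keep)
    if size_factor_method == "pooled":
        f = norm_mod.pooled_factors(sub)
    elif size_factor_method == "libsize":
        f = norm_mod.libsize_factors(sub)
    else:
        raise ValueError(f"unknown size_factor_method {size_factor_method!r}")
    if use_spikes is None:
        use_spikes = bool(sub.is_spike.sum() >= 10)
    spike_f = None
    if use_spikes:
        spike_f = norm_mod.spike_factors(sub)
    logm = norm_mod.log_normalize(sub, f, spike_f=spike_f)
    trend = hvg_mod.fit_technical_trend(logm, use_spikes=use_spikes)
    table = hvg_mod.decompose_variance(
        logm, trend, bio_threshold=hvg_mod.BIO_THRESHOLDS[protocol]
    )
    return hvg_mod.count_hvgs(table)


def bootstrap_hvg_counts(
    m: ExpressionMatrix,
    subsample_size: int = 100,
    n_repeats: int = 100,
    protocol: str = "full_length",
    size_factor_method: str = "pooled",
    use_spikes: bool | None = None,
    within_replacement: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Per-repeat HVG counts over random fixed-size cell subsamples."""
    if m.n_cells < subsample_size:
        raise ValueError(
            f"dataset has {m.n_cells} cells, fewer than subsample_size={subsample_size}"
        )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_repeats, dtype=int)
    for r in range(n_repeats):
        idx = rng.choice(m.n_cells, size=subsample_size, replace=within_replacement)
        counts[r] = hvg_count_for_cells(
            m,
            idx,
            protocol=protocol,
            size_factor_method=size_factor_method,
            use_spikes=use_spikes,
        )
    return counts


def compare_heterogeneity(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed pooled-variance Student's t-test on two HVG-count vectors.

    Implemented by the closed form: t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a
    + 1/n_b)) with the pooled variance s_p^2 on n_a + n_b - 2 degrees of
    freedom.  Degenerate zero-variance inputs give p = 1 for equal means and
    p = 0 (with a warning) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 repeats per dataset")
    ma, mb = a.mean(), b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        if ma == mb:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p degenerates to 0")
        return float(np.sign(ma - mb) * np.inf), 0.0
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def compare_heterogeneity_welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance alternative to :func:`compare_heterogeneity`."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bootstrap_compare(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    subsample_size: int = 100,
    n_repeats: int = 100,
    seed: int = 0,
    **kw,
) -> BootstrapResult:
    """Bootstrap both datasets (independent seeds) and compare their counts."""
    rng = np.random.default_rng(seed)
    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
    ca = bootstrap_hvg_counts(
        m_a, subsample_size=subsample_size, n_repeats=n_repeats, seed=int(seed_a), **kw
    )
    cb = bootstrap_hvg_counts(
        m_b, subsample_size=subsample_size, n_repeats=n_repeats, seed=int(seed_b), **kw
    )
    t, p = compare_heterogeneity(ca, cb)
    shapiro = {}
    for name, c in (("a", ca), ("b", cb)):
        if len(np.unique(c)) > 1 and len(c) >= 3:
            shapiro[name] = float(stats.shapiro(c).pvalue)
        else:
            shapiro[name] = np.nan
    return BootstrapResult(
        counts_a=ca,
        counts_b=cb,
        subsample_size=subsample_size,
        n_repeats=n_repeats,
        seed=seed,
        t_statistic=t,
        p_value=p,
        shapiro_p=shapiro,
    )
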