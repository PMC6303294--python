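"""Synthetic data generators with the statistical structure the pipeline assumes.

Three generators emulate the three data modalities of the study design:

* ``simulate_sc`` — single-cell UMI/read counts: negative-binomial genes with
  cluster-specific fold-change programs, lognormal library-size variation,
  ERCC-like spike-in genes whose expected counts are identical across cells
  (purely technical variation), mitochondrial genes, planted low-quality cells
  and cell-cycle phase labels.
* ``simulate_bulk`` — bulk counts for sorted populations with replicates and
  planted differentially expressed genes.
* ``simulate_markers`` — per-cell log-intensities for the six co-inhibitory /
  surface markers (PD-1, LAG-3, TIGIT, TIM-3, CD49b, CCR5) plus an IL-10
  reporter channel, with a latent CIR-rich subpopulation shifted up on all
  channels and CIR-poor cells shifted on random marker subsets.

Negative-binomial counts use the mean/size parameterization: the ``nb_dispersion``
fields hold the dispersion ``phi`` with ``variance = mu + phi * mu**2``; sampling
uses size ``n = 1/phi``.  All generators are bitwise-reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

MARKER_NAMES = ("PD-1", "LAG-3", "TIGIT", "TIM-3", "CD49b", "CCR5")
REPORTER_NAME = "IL-10"


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid spec field {fieldname!r}: {msg}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with variance mu + phi*mu^2 (size n = 1/phi)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


@dataclass
class SCSimSpec:
    """Parameters of the single-cell count simulation.

    ``cluster_proportions`` defaults to uniform over ``n_clusters``.
    ``de_programs`` (optional) gives explicit DE gene index arrays per cluster,
    letting two simulated "tissues" share a planted expression program; by
    default programs are sampled disjointly from the endogenous non-mito genes.
    ``baseline_means`` (optional) fixes per-gene baseline means, letting a bulk
    simulation share the same gene-level baseline.
    """

    n_genes: int = 2000
    n_cells: int = 500
    n_clusters: int = 2
    cluster_proportions: tuple | None = None
    frac_de_genes_per_cluster: float = 0.05
    de_log2fc: float = 2.0
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 1.0
    nb_dispersion: float = 0.5
    libsize_sdlog: float = 0.3
    n_spike_genes: int = 92  # the ERCC mix has 92 spike species
    spike_mean_levels: tuple | None = None  # default: geometric ladder 0.5..400
    n_mito_genes: int = 20
    frac_lowq_cells: float = 0.0
    lowq_libsize_factor: float = 0.05
    lowq_mito_factor: float = 5.0
    frac_cycling_cells: float = 0.0
    dataset_name: str = "sim"
    de_programs: list | None = None
    baseline_means: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes > 0, "n_genes", "must be positive")
        _require(self.n_cells > 0, "n_cells", "must be positive")
        _require(self.n_clusters > 0, "n_clusters", "must be positive")
        props = self.proportions()
        _require(len(props) == self.n_clusters, "cluster_proportions",
                 "length must equal n_clusters")
        _require(np.all(props > 0), "cluster_proportions", "must be positive")
        _require(abs(props.sum() - 1.0) < 1e-9, "cluster_proportions",
                 "must sum to 1 within 1e-9")
        _require(0.0 <= self.frac_de_genes_per_cluster <= 1.0,
                 "frac_de_genes_per_cluster", "must be in [0, 1]")
        _require(self.de_log2fc >= 0, "de_log2fc", "must be non-negative")
        _require(self.nb_dispersion > 0, "nb_dispersion", "must be positive")
        _require(self.libsize_sdlog >= 0, "libsize_sdlog", "must be non-negative")
        _require(self.n_spike_genes >= 0, "n_spike_genes", "must be non-negative")
        _require(self.n_mito_genes >= 0, "n_mito_genes", "must be non-negative")
        _require(self.n_spike_genes + self.n_mito_genes <= self.n_genes,
                 "n_spike_genes", "n_spike_genes + n_mito_genes must not exceed n_genes")
        _require(0.0 <= self.frac_lowq_cells < 1.0, "frac_lowq_cells",
                 "must be a fraction in [0, 1)")
        _require(0.0 < self.lowq_libsize_factor < 1.0, "lowq_libsize_factor",
                 "must be in (0, 1)")
        _require(0.0 <= self.frac_cycling_cells < 1.0, "frac_cycling_cells",
                 "must be a fraction in [0, 1)")
        if self.baseline_means is not None:
            bm = np.asarray(self.baseline_means, dtype=float)
            n_endo = self.n_genes - self.n_spike_genes
            _require(bm.shape == (n_endo,), "baseline_means",
                     f"must have length n_genes - n_spike_genes = {n_endo}")
            _require(np.all(bm > 0), "baseline_means", "must be positive")

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_proportions, dtype=float)


def simulate_sc(spec: SCSimSpec) -> ExpressionMatrix:
    """Simulate a genes x cells count matrix with planted structure.

    Endogenous gene g in cell c is NB with mean
    ``baseline_g * libsize_c * 2**de_log2fc`` when g is in the DE program of
    c's cluster, else ``baseline_g * libsize_c``.  Spike-in genes have means
    independent of the cell (added at fixed concentration).  Low-quality cells
    have their library-size factor multiplied by ``lowq_libsize_factor`` and
    their mitochondrial means multiplied by ``lowq_mito_factor``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, c = spec.n_genes, spec.n_cells
    n_endo = g - spec.n_spike_genes
    n_mito = spec.n_mito_genes

    # gene universe: endogenous (first n_mito of them mitochondrial), then spikes
    is_spike = np.zeros(g, dtype=bool)
    is_spike[n_endo:] = True
    is_mito = np.zeros(g, dtype=bool)
    is_mito[:n_mito] = True
    gene_ids = np.array(
        [f"mt-Gene{i + 1:04d}" for i in range(n_mito)]
        + [f"Gene{i + 1:04d}" for i in range(n_mito, n_endo)]
        + [f"ERCC-{i + 1:05d}" for i in range(spec.n_spike_genes)],
        dtype=object,
    )
    cell_ids = np.array([f"{spec.dataset_name}_cell{i + 1:05d}" for i in range(c)],
                        dtype=object)

    if spec.baseline_means is not None:
        base = np.asarray(spec.baseline_means, dtype=float).copy()
    else:
        base = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=n_endo)

    # cluster memberships and DE programs (disjoint by default, spikes/mito excluded)
    clusters = rng.choice(spec.n_clusters, size=c, p=spec.proportions())
    if spec.de_programs is not None:
        programs = [np.asarray(p, dtype=int) for p in spec.de_programs]
        _require(len(programs) == spec.n_clusters, "de_programs",
                 "must give one gene-index array per cluster")
        for p in programs:
            _require(p.size == 0 or (p.min() >= n_mito and p.max() < n_endo),
                     "de_programs", "indices must point at endogenous non-mito genes")
    else:
        n_de = int(round(spec.frac_de_genes_per_cluster * n_endo))
        eligible = rng.permutation(np.arange(n_mito, n_endo))
        _require(n_de * spec.n_clusters <= eligible.size, "frac_de_genes_per_cluster",
                 "disjoint DE programs exceed the endogenous non-mito gene pool")
        programs = [eligible[k * n_de:(k + 1) * n_de] for k in range(spec.n_clusters)]

    # library-size factors, lognormal normalized to mean 1; low-quality scaled down
    if spec.libsize_sdlog > 0:
        size_factor = rng.lognormal(0.0, spec.libsize_sdlog, size=c)
    else:
        size_factor = np.ones(c)
    size_factor /= size_factor.mean()
    lowq = np.zeros(c, dtype=bool)
    n_lowq = int(round(spec.frac_lowq_cells * c))
    if n_lowq:
        lowq[rng.choice(c, size=n_lowq, replace=False)] = True
    eff_factor = np.where(lowq, size_factor * spec.lowq_libsize_factor, size_factor)

    # endogenous means: baseline x library size x per-cluster fold change
    mean = base[:, None] * eff_factor[None, :]
    fc = 2.0 ** spec.de_log2fc
    for k in range(spec.n_clusters):
        cells_k = clusters == k
        if programs[k].size and cells_k.any():
            mean[np.ix_(programs[k], cells_k)] *= fc
    if n_mito and spec.lowq_mito_factor != 1.0 and lowq.any():
        mean[np.ix_(np.arange(n_mito), np.flatnonzero(lowq))] *= spec.lowq_mito_factor

    counts = np.zeros((g, c), dtype=np.int64)
    counts[:n_endo] = _nb_draw(rng, mean, spec.nb_dispersion)

    if spec.n_spike_genes:
        if spec.spike_mean_levels is None:
            spike_mean = np.geomspace(0.5, 400.0, spec.n_spike_genes)
        else:
            levels = np.asarray(spec.spike_mean_levels, dtype=float)
            spike_mean = levels[np.arange(spec.n_spike_genes) % len(levels)]
        counts[n_endo:] = _nb_draw(
            rng, np.repeat(spike_mean[:, None], c, axis=1), spec.nb_dispersion
        )

    phases = np.full(c, "G1", dtype=object)
    n_cyc = int(round(spec.frac_cycling_cells * c))
    if n_cyc:
        cyc = rng.choice(c, size=n_cyc, replace=False)
        phases[cyc] = rng.choice(["S", "G2M"], size=n_cyc)

    return ExpressionMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        is_spike=is_spike,
        is_mito=is_mito,
        dataset_label=np.full(c, spec.dataset_name, dtype=object),
        phase_label=phases,
        true_cluster=clusters,
        true_size_factor=eff_factor,
        true_lowq=lowq,
        meta={
            "de_programs": [p.tolist() for p in programs],
            "de_program_gene_ids": [list(gene_ids[p]) for p in programs],
            "baseline_means": base,
            "seed": spec.seed,
        },
    )


@dataclass
class BulkSimSpec:
    """Parameters of the bulk RNA-seq simulation (sorted populations x replicates)."""

    n_genes: int = 2000
    groups: tuple = (("rich", 2), ("poor", 2), ("neg", 2))
    frac_de: float = 0.1
    de_log2fc: float = 2.0
    de_group: str | None = None  # group carrying the shift; default first group
    nb_dispersion: float = 0.01
    baseline_meanlog: float = 6.5
    baseline_sdlog: float = 1.2
    n_mito_genes: int = 10
    libsize_sdlog: float = 0.15
    de_genes: np.ndarray | None = None  # explicit DE gene indices
    baseline_means: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes > 0, "n_genes", "must be positive")
        _require(len(self.groups) >= 1, "groups", "at least one group required")
        for name, n_rep in self.groups:
            _require(n_rep >= 2, "groups", f"group {name!r} needs >= 2 replicates")
        _require(0.0 <= self.frac_de <= 1.0, "frac_de", "must be in [0, 1]")
        _require(self.de_log2fc >= 0, "de_log2fc", "must be non-negative")
        _require(self.nb_dispersion > 0, "nb_dispersion", "must be positive")
        _require(0 <= self.n_mito_genes <= self.n_genes, "n_mito_genes",
                 "must be in [0, n_genes]")
        names = [g[0] for g in self.groups]
        _require(len(set(names)) == len(names), "groups", "group names must be unique")
        if self.de_group is not None:
            _require(self.de_group in names, "de_group", "must name one of the groups")
        if self.baseline_means is not None:
            bm = np.asarray(self.baseline_means, dtype=float)
            _require(bm.shape == (self.n_genes,), "baseline_means",
                     "must have length n_genes")
            _require(np.all(bm > 0), "baseline_means", "must be positive")


@dataclass
class BulkTable:
    """Bulk count table plus sample groups and simulation truth."""

    counts: pd.DataFrame  # genes x samples
    groups: pd.Series  # per sample
    is_mito: pd.Series  # per gene
    true_de: pd.Series | None = None  # per gene


def simulate_bulk(spec: BulkSimSpec) -> BulkTable:
    """Simulate bulk NB counts with planted DE genes in one designated group."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    if spec.baseline_means is not None:
        base = np.asarray(spec.baseline_means, dtype=float).copy()
    else:
        base = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=g)

    is_mito = np.zeros(g, dtype=bool)
    is_mito[:spec.n_mito_genes] = True
    gene_ids = [f"mt-Gene{i + 1:04d}" if is_mito[i] else f"Gene{i + 1:04d}"
                for i in range(g)]

    if spec.de_genes is not None:
        de_idx = np.asarray(spec.de_genes, dtype=int)
        _require(de_idx.size == 0 or (de_idx.min() >= 0 and de_idx.max() < g),
                 "de_genes", "indices out of range")
    else:
        n_de = int(round(spec.frac_de * g))
        eligible = np.flatnonzero(~is_mito)
        de_idx = rng.choice(eligible, size=min(n_de, eligible.size), replace=False)
    true_de = np.zeros(g, dtype=bool)
    true_de[de_idx] = True

    de_group = spec.de_group if spec.de_group is not None else spec.groups[0][0]
    sample_names, sample_groups, cols = [], [], []
    fc = 2.0 ** spec.de_log2fc
    for name, n_rep in spec.groups:
        for r in range(n_rep):
            mu = base.copy()
            if name == de_group:
                mu[de_idx] *= fc
            depth = rng.lognormal(0.0, spec.libsize_sdlog) if spec.libsize_sdlog else 1.0
            cols.append(_nb_draw(rng, mu * depth, spec.nb_dispersion))
            sample_names.append(f"{name}_{r + 1}")
            sample_groups.append(name)

    counts = pd.DataFrame(np.column_stack(cols), index=pd.Index(gene_ids, name="gene"),
                          columns=sample_names)
    return BulkTable(
        counts=counts,
        groups=pd.Series(sample_groups, index=counts.columns, name="group"),
        is_mito=pd.Series(is_mito, index=counts.index, name="is_mito"),
        true_de=pd.Series(true_de, index=counts.index, name="true_de"),
    )


@dataclass
class MarkerSimSpec:
    """Parameters of the cytometry marker-intensity simulation.

    ``poor_subset_size_dist`` is the probability vector over subset sizes
    ``0..5``: a CIR-poor cell receives ``rich_shift`` on a random marker subset
    of that size, while CIR-rich cells receive it on all six markers and the
    reporter.  Intensities are on the log scale (lognormal noise).
    """

    n_cells: int = 2000
    markers: tuple = MARKER_NAMES
    reporter: str = REPORTER_NAME
    frac_cir_rich: float = 0.2
    rich_shift: float = 3.0
    poor_subset_size_dist: tuple = (0.30, 0.25, 0.20, 0.10, 0.10, 0.05)
    intensity_sdlog: float = 0.5
    inter_marker_corr: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_cells > 0, "n_cells", "must be positive")
        _require(len(self.markers) == 6, "markers", "exactly 6 markers required")
        _require(0.0 < self.frac_cir_rich < 1.0, "frac_cir_rich", "must be in (0, 1)")
        _require(self.rich_shift >= 0, "rich_shift", "must be non-negative")
        d = np.asarray(self.poor_subset_size_dist, dtype=float)
        _require(d.shape == (6,), "poor_subset_size_dist",
                 "must give probabilities for subset sizes 0..5")
        _require(np.all(d >= 0) and abs(d.sum() - 1.0) < 1e-9,
                 "poor_subset_size_dist", "must be a probability vector")
        _require(self.intensity_sdlog > 0, "intensity_sdlog", "must be positive")
        _require(0.0 <= self.inter_marker_corr < 1.0, "inter_marker_corr",
                 "must be in [0, 1)")


def simulate_markers(spec: MarkerSimSpec) -> pd.DataFrame:
    """Simulate per-cell marker log-intensities with a latent CIR-rich subset.

    Returns a DataFrame with one column per marker, one for the reporter, and
    a boolean ``true_rich`` truth column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_cells, 7  # 6 markers + reporter
    rich = rng.random(n) < spec.frac_cir_rich

    # equicorrelated Gaussian noise on the log scale
    rho = spec.inter_marker_corr
    cov = spec.intensity_sdlog ** 2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
    noise = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")

    shift = np.zeros((n, k))
    shift[rich, :] = spec.rich_shift  # all markers + reporter
    poor_idx = np.flatnonzero(~rich)
    sizes = rng.choice(6, size=poor_idx.size, p=np.asarray(spec.poor_subset_size_dist))
    for i, s in zip(poor_idx, sizes):
        if s:
            shift[i, rng.choice(6, size=s, replace=False)] = spec.rich_shift

    values = noise + shift
    cols = list(spec.markers) + [spec.reporter]
    out = pd.DataFrame(values, columns=cols,
                       index=pd.Index([f"cell{i + 1:05d}" for i in range(n)],
                                      name="cell_id"))
    out["true_rich"] = rich
    return out
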