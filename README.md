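# il10het

Computational pipeline for analyzing the heterogeneity of IL-10-producing
Foxp3⁻ CD4⁺ T cells — the population containing the regulatory TR1 subset.
The scientific question it addresses: is IL-10 production alone a reliable
marker of regulatory function, or does the IL-10⁺ compartment hide distinct
subpopulations, of which only the co-inhibitory-receptor-rich (CIR-rich,
TR1-like) subset — co-expressing PD-1, LAG-3, TIGIT, TIM-3, CD49b and
CCR5 — is suppressive?

The package is aimed at computational immunologists who want the full
analysis chain as tested, reusable code: single-cell RNA-seq quality
control, normalization, highly-variable-gene (HVG) detection, a bootstrap
heterogeneity statistic, clustering and cross-tissue cluster matching, a
bulk RNA-seq signature stage, and sensitivity/specificity evaluation of
cytometry sorting gates. A synthetic-data module generates inputs with
planted structure for every stage, so the whole pipeline is testable
without any external download.

## Methods at a glance

- **Cell QC** — a cell is removed when its log library size or log detected
  genes falls below `median − 3·MAD` (MAD scaled by 1.4826), when its
  mitochondrial fraction is an outlier by the same rule (above the median by
  default), or when it carries an S/G2M phase label. Genes with mean count
  < 1 (full-length) or < 0.05 (droplet UMIs) are dropped.
- **Normalization** — deconvolution-by-pooling size factors: cells are
  summed into overlapping pools along a library-size-ordered ring, each pool
  is compared to a reference pseudo-cell by the median gene-wise ratio, and
  the resulting sparse linear system `Σ_{j∈pool} f_j = median_g(V_g/ref_g)`
  is solved by least squares. Spike-in (ERCC) genes get their own factors
  from total spike counts. Expression is `log2(count/factor + 1)`.
- **HVG detection** — per-gene variance of log-expression is decomposed
  against a LOESS mean–variance trend fitted to spike-ins (or to all genes);
  the biological variance is the excess over the trend. A gene is an HVG
  when biological variance > 0.5 (0.05 for droplet data) at
  Benjamini–Hochberg FDR < 5%, with p-values from a one-sided
  variance-ratio test.
- **Bootstrap heterogeneity statistic** — draw 100 random cells, rerun the
  entire HVG procedure on them, count HVGs; repeat 100 times per dataset;
  compare two datasets by a two-tailed pooled-variance Student's t-test on
  the count vectors.
- **Clustering** — t-SNE on the HVG log-expression (PCA-50 pre-reduction),
  DBSCAN on the embedding with an automatic knee-of-kNN-distance `eps`.
  Clusters are characterized by log2 fold-change marker rankings and
  compared across tissues by Spearman correlation over genes non-zero in
  both cluster-average profiles.
- **Bulk DE and signature scoring** — median-of-ratios normalization, a
  per-gene pooled t-test on log2 normalized counts, and the decision rule
  |FC| > 1.5 at FDR < 1%; the averaged expression of a reference population
  restricted to the single-cell HVGs is scored against each cell by rank
  correlation.
- **Gating evaluation** — per-channel positivity thresholds (quantile or
  Otsu), a CIR-rich reference population (positive on all 6 markers), and
  sensitivity/specificity of every AND-combined marker subset; nested
  subsets trade sensitivity for specificity exactly monotonically.

## Worked example

```python
import numpy as np
from il10het import synthdata as sd, qc, normalize as nz, hvg, heterogeneity as het

spec = sd.SCSimSpec(n_genes=2000, n_cells=600, n_clusters=3,
                    frac_de_genes_per_cluster=0.05, de_log2fc=3.0,
                    frac_lowq_cells=0.05, seed=1)
m = sd.simulate_sc(spec)
thr = qc.QCThresholds.for_protocol("full_length")
m, cell_report = qc.filter_cells(m, thr)
m, gene_report = qc.filter_genes(m, thr)
print(f"after QC: {m.n_cells} cells x {m.n_genes} genes "
      f"(removed {cell_report.removed['cells_total']} cells, "
      f"{gene_report.removed['genes_low_abundance']} genes)")

factors = nz.pooled_factors(m)
logm = nz.log_normalize(m, factors, spike_f=nz.spike_factors(m))
trend = hvg.fit_technical_trend(logm, use_spikes=True)
table = hvg.decompose_variance(logm, trend, bio_threshold=0.5)
print(f"highly variable genes: {hvg.count_hvgs(table)}")

uniform = sd.simulate_sc(sd.SCSimSpec(n_genes=2000, n_cells=600, n_clusters=1,
                                      frac_de_genes_per_cluster=0.0, seed=2))
res = het.bootstrap_compare(m, uniform, subsample_size=100, n_repeats=50, seed=3)
print(f"mean HVG count: structured {res.counts_a.mean():.1f}, "
      f"uniform {res.counts_b.mean():.1f}")
print(f"Student's t = {res.t_statistic:.2f}, p = {res.p_value:.3g}")
```

Output:

```
after QC: 563 cells x 1718 genes (removed 37 cells, 282 genes)
highly variable genes: 273
mean HVG count: structured 274.0, uniform 0.1
Student's t = 502.61, p = 5.58e-169
```

The QC stage removed the planted shallow cells (5% of the input) plus the
low-abundance genes; the variance decomposition flagged roughly the 300
planted program genes; and the bootstrap statistic cleanly separates a
3-cluster dataset from a uniform one — the structured dataset yields ~274
HVGs per 100-cell subsample, the unstructured one essentially none, a
difference the pooled t-test calls at vanishing p.

A command-line interface mirrors the library
(`il10het simulate|qc|normalize|boot-hvg|gate|run`); `il10het run
--config config.yaml` executes the configured stages end to end and writes
a provenance record with per-output checksums.

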