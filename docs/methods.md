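# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
design choices made where the procedure left room.

## Synthetic data

`simulate_sc` draws endogenous counts from a negative binomial with
variance `mu + phi*mu^2`; the `nb_dispersion` fields hold the dispersion
`phi` (sampling uses the size parameter `n = 1/phi`). Defaults: 2000 genes,
gene baseline means lognormal(meanlog 1, sdlog 1) — a median of ~3 counts,
typical of full-length single-cell libraries after abundance filtering —
dispersion 0.5, and per-cell library-size factors lognormal(0, 0.3)
rescaled to mean 1 so baseline means stay interpretable. Each cluster owns
a differential-expression program (5% of endogenous non-mitochondrial genes
by default, disjoint across clusters) whose genes are multiplied by
`2^de_log2fc` in that cluster's cells. Explicit programs and shared
baseline means can be passed in, which is how tests build two "tissues"
sharing one planted program and a bulk experiment on the same gene
universe. Spike-in genes default to 92 species — the size of the ERCC
mix — on a geometric abundance ladder from 0.5 to 400 expected counts;
their means are identical across cells (fixed added concentration), so all
their variation is technical. Planted low-quality cells have their library
factor multiplied by 0.05 and their mitochondrial means raised 5-fold,
mimicking shallow, leaky cells. Cell-cycle phases are labels only; no
expression program is attached to them.

`simulate_bulk` uses the same NB model with defaults meanlog 6.5 / sdlog
1.2 (median ~650 counts, deep sorted-population libraries) and dispersion
0.01, the regime of technical-replicate-like sorted samples. These defaults
matter: the DE stage is a deliberately simplified per-gene t-test with
3-versus-3 replicates (4 degrees of freedom), and only at low dispersion
and adequate depth does it retain the power regime that a
dispersion-shrinkage pipeline achieves on real sorted bulk data.

`simulate_markers` draws 7 channels (6 surface markers + IL-10 reporter)
of equicorrelated Gaussian log-intensities (sdlog 0.5, correlation 0.2). A
latent CIR-rich fraction (20%) is shifted up by `rich_shift` (default 3 log
units) on all channels; CIR-poor cells receive the shift on a random marker
subset whose size follows a distribution concentrated on 0–2 markers, so
single- and double-positive bystanders exist but full co-expression is
essentially exclusive to rich cells.

What the generators do **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond cluster programs, read-level noise,
cytometry spillover, or autofluorescence. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artifact of real data.

## Quality control

Outlier rules use the median and the MAD scaled by 1.4826 (normal
consistency). Library size and detected genes: fail below
`median − n_mads·MAD` of the log value (n_mads = 3). When MAD = 0 any value
strictly below the median fails — the limiting behavior of the rule.
Mitochondrial fraction: outliers are removed **above** the median by
default even though the same below-median sentence nominally covers all
three parameters; a below rule on mitochondrial content would remove the
healthiest cells, and the literal direction remains available via
`mito_direction="below"`. Spike-in counts are excluded from library size,
detected genes and the mitochondrial denominator: spike content reflects
protocol, not cell quality. Cycling cells are removed on provided phase
labels; re-deriving phases from expression (a trained classifier in the
original tooling) is out of scope. All criteria are computed on the input
matrix, so filter order is irrelevant; a frozen-cutoff mode allows
reapplying recorded thresholds, under which filtering is idempotent.

The bulk gene filter keeps genes with more than 5 counts in more than 4
samples; both comparisons are strict, a reading recorded in the QC report,
and both cutoffs are parameters.

## Normalization

Pooling-based deconvolution: pool sizes default to {21, 26, …, 101} capped
at the cell count; the reference pseudo-cell is the per-gene mean over all
cells; cells are ordered on a ring by library size alternating
smallest/largest so every contiguous window mixes depths; every rotation of
every pool size contributes one equation; the ring order breaks ties by
cell id, making factors invariant to input column order. Low-weight (1e-3)
per-cell identity equations anchored at library-size factors guarantee a
unique least-squares solution on small inputs. Negative solutions are
clipped to a small positive floor with a warning. A single reference
cluster is used (no pre-clustering). Spike-in genes are normalized by
spike-total factors — their depth is the technical capture scale — while
endogenous genes use pooled factors; this split is an interpretive choice
recorded here. Log-expression uses base 2 and pseudocount 1 so the HVG
thresholds are in log2 units.

## HVG detection

The technical trend is a LOESS fit (span 0.3, floored at 0) to the
(mean, variance) pairs of spike-in genes, or of all genes when spike-ins
are absent or fewer than 10; it is evaluated by interpolation inside the
fitted range and by nearest-endpoint value outside. Significance of the
biological excess uses the ratio of total to trend variance referred to an
F distribution with `(n_cells − 1, d_trend)` degrees of freedom; the
default takes the trend as well-determined (`d_trend → ∞`), collapsing the
reference to a scaled chi-square, a choice recorded in the output table
along with the thresholds used. Multiple testing is Benjamini–Hochberg.
Spike-ins are never flagged.

Calibration, measured by simulation: with the all-genes trend on null data
the fraction of genes at p < 0.05 is 0.03–0.05. With the spike trend it is
mildly inflated (0.06–0.12) — simulated spike genes have slightly less
normalized variance than endogenous null genes because their factors are
estimated from the spikes themselves and their means carry no library
variation. This spike-versus-endogenous mismatch is a known limitation of
spike-anchored trends and is why the null-calibration test uses the
all-genes trend, whose premise (no biological variance anywhere) is exactly
true in a null simulation.

## Bootstrap heterogeneity statistic

Each repeat draws `subsample_size` (default 100) **distinct** cells; the
phrase "with replacement at each time" is read as successive repeats
drawing from the full pool anew, with within-repeat replacement available
behind a flag. The full HVG procedure — gene abundance filter, size
factors, trend, decomposition — is recomputed on every subsample, so the
statistic for one dataset can never depend on another. Counts are compared
by the pooled-variance Student's t (as literally specified; Welch available
behind a flag); zero-pooled-variance inputs degenerate to p = 1 (equal
means) or p = 0 with a warning.

Study conditions for the ordering experiment (7-cluster versus 2-cluster
datasets, 2000 genes, 1500 cells) use `de_log2fc = 3`: with balanced
clusters the between-cluster variance of a program gene is
`lfc² · p(1−p)`, which at lfc = 2 and 7 clusters is 4·(1/7)(6/7) ≈ 0.49 —
*below* the 0.5 HVG threshold by construction — so a detectable ordering
requires the stronger effect size, and at lfc = 3 the 7-cluster dataset
yields roughly 2.5× the HVG count of the 2-cluster one.

The type-I calibration study runs two independent bootstrap arms over one
dataset per run. Running the arms on two distinct finite datasets would add
dataset-level variance that the per-run t-test (which only sees bootstrap
repeats) does not model; the test is calibrated for the former design, and
that is the design tested.

## Clustering and comparison

t-SNE uses perplexity 30, learning rate n/12 (floored at 50), 1000
iterations, PCA-50 pre-reduction, PCA initialization, and a fixed seed;
exact-mode t-SNE is available and keeps duplicate cells coincident. DBSCAN
`eps="auto"` takes the knee (maximum distance to the chord) of the sorted
min_pts-nearest-neighbor distance curve; min_pts defaults to 10. Marker
ranking is by log2 fold-change of mean normalized log-expression in-cluster
versus other clustered cells, with ties broken by in-cluster mean then gene
id; a Wilcoxon rank-sum p is available per gene but never used for ranking.
Cluster matching restricts each profile pair to genes non-zero in **both**
profiles (the symmetric reading of "all non-zero values"; either-non-zero
is a flag) and uses Spearman correlation with average-rank ties. Per-cell
signature correlation uses the same non-zero convention and Spearman by
default (Pearson behind a flag); being rank-based it is invariant to
monotone transformations of the signature that preserve zeros.

## Bulk DE

Median-of-ratios size factors over a geometric-mean reference (genes with
all-positive counts), per-gene pooled two-sample t on
log2(normalized + 0.5), BH-adjusted FDR, decision rule |FC| > 1.5 at
FDR < 1%. This intentionally does **not** reimplement NB dispersion
shrinkage; the simplification is stamped into the result's provenance.

## Gating

Default thresholds are per-channel quantiles (q = 1 − expected positive
fraction); Otsu thresholds are provided and are the natural choice for the
strongly bimodal synthetic intensities; manual thresholds are accepted. The
CIR-rich reference is the all-6 AND rule. Subset evaluation AND-combines
each marker subset (with reporter positivity by default) and reports
sensitivity and specificity against the reference; for nested subsets the
trade-off is exactly monotone by construction. Note that against the all-6
rule reference, every reporter-combined subset of the six markers has
sensitivity identically equal to P(reporter⁺ | reference) — the reference
already implies the markers — so the sensitivity comparison between the
3-channel and all-6 gates is made against the simulation truth, where the
all-6 gate genuinely loses rich cells that dip below threshold on any one
channel.

## Numerical notes and degenerate inputs

Least-squares solves use `scipy.sparse.linalg.lsqr` at tolerance 1e-10;
empty matrices, all-cells-removed QC, zero-library cells, missing spike-ins,
degenerate (single-point) embeddings, all-true/all-false gating references
and sub-minimum gene intersections all raise informative errors or warnings
as documented per function. All randomness flows through explicit integer
seeds; pipeline outputs carry a config hash and per-file checksums.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise every
code path with comfortable statistical margins: 1000–2000 genes, 200–1500
cells, 100-cell subsamples with 20–100 bootstrap repeats, 3 bulk replicates
per group, and 3000-cell marker panels.
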