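"""QC rules: MAD outlier filtering, gene abundance, bulk filter, reporter check."""

import numpy as np
import pandas as pd
import pytest

from il10het import qc as qc_mod
from il10het import synthdata as sd
from il10het.matrix import ExpressionMatrix


def make_matrix(counts, is_spike=None, is_mito=None, phases=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    return ExpressionMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=[f"c{j}" for j in range(c)],
        is_spike=np.zeros(g, bool) if is_spike is None else is_spike,
        is_mito=np.zeros(g, bool) if is_mito is None else is_mito,
        dataset_label=["d"] * c,
        phase_label=["G1"] * c if phases is None else phases,
    )


class TestFilterCells:
    def test_identical_cells_none_removed(self):
        m = make_matrix(np.full((5, 10), 3))
        out, rep = qc_mod.filter_cells(m)
        assert out.n_cells == 10
        assert rep.removed["cells_total"] == 0

    def test_zero_mad_removes_strictly_below_median(self):
        # log-library sizes {10,10,10,10,2}: median 10, MAD 0 -> only the
        # low cell fails
        totals = np.array([22026, 22026, 22026, 22026, 7])  # e^10, e^2
        counts = totals[None, :]
        m = make_matrix(counts)
        out, rep = qc_mod.filter_cells(m)
        assert out.n_cells == 4
        assert not rep.cell_table["pass_library_size"].iloc[-1]

    def test_planted_lowq_cells_recovered(self, full_thresholds):
        spec = sd.SCSimSpec(
            n_genes=1000, n_cells=1000, frac_lowq_cells=0.05, seed=42
        )
        m = sd.simulate_sc(spec)
        _, rep = qc_mod.filter_cells(m, full_thresholds)
        passed = rep.cell_table["pass_overall"].to_numpy()
        planted = m.true_lowq
        assert (~passed[planted]).mean() >= 0.95
        assert (~passed[~planted]).mean() <= 0.02

    def test_phase_filter(self):
        m = make_matrix(np.full((3, 6), 5), phases=["G1", "S", "G2M", "G1", "G1", "S"])
        out, rep = qc_mod.filter_cells(m)
        assert out.n_cells == 3
        assert rep.removed["phase"] == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(50, 40))
        m = make_matrix(counts)
        _, rep = qc_mod.filter_cells(m)
        perm = rng.permutation(40)
        mp = m.subset_cells(perm)
        _, rep_p = qc_mod.filter_cells(mp)
        flags = rep.cell_table["pass_overall"].to_numpy()
        assert np.array_equal(flags[perm], rep_p.cell_table["pass_overall"].to_numpy())

    def test_frozen_thresholds_are_idempotent(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(np.geomspace(1, 50, 30)[:, None], size=(30, 200))
        counts[:, :10] //= 20  # a shallow tail so the filter bites
        m = make_matrix(counts)
        out1, rep1 = qc_mod.filter_cells(m)
        assert rep1.removed["cells_total"] > 0
        # frozen: reapplying the recorded cutoffs removes nothing more
        out2, rep2 = qc_mod.filter_cells(out1, cutoffs=rep1.cutoffs)
        assert rep2.removed["cells_total"] == 0
        # recomputing on the filtered matrix may remove more (new median/MAD)
        out3, rep3 = qc_mod.filter_cells(out1)
        assert rep3.removed["cells_total"] >= 0

    def test_report_counts_match_dimensions(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, size=(20, 100))
        counts[:, 0] = 0  # guaranteed failure
        counts[0, 0] = 1
        m = make_matrix(counts)
        out, rep = qc_mod.filter_cells(m)
        assert m.n_cells - out.n_cells == rep.removed["cells_total"]

    def test_all_removed_raises_with_counts(self):
        m = make_matrix(np.full((3, 4), 2), phases=["S"] * 4)
        with pytest.raises(ValueError, match="per-criterion counts"):
            qc_mod.filter_cells(m)


class TestFilterGenes:
    def test_zero_gene_removed_boundary_retained(self):
        counts = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [5, 5, 5, 5]])
        m = make_matrix(counts)
        out, rep = qc_mod.filter_genes(m)
        assert list(out.gene_ids) == ["g1", "g2"]  # mean 1 is not < 1

    def test_droplet_threshold(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 0] = 1  # mean 0.1 >= 0.05
        counts[1, :] = 5
        m = make_matrix(counts)
        t = qc_mod.QCThresholds.for_protocol("droplet")
        out, _ = qc_mod.filter_genes(m, t)
        assert out.n_genes == 2

    def test_spikes_retained_regardless(self):
        counts = np.array([[0, 0], [9, 9]])
        m = make_matrix(counts, is_spike=np.array([True, False]))
        out, _ = qc_mod.filter_genes(m)
        assert "g0" in out.gene_ids


class TestFilterBulkGenes:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([6, 6, 6, 6, 6, 0], True),  # >5 in 5 samples (>4)
            ([6, 6, 6, 6, 0, 0], False),  # >5 in only 4 samples
            ([0, 0, 0, 0, 0, 0], False),
        ],
    )
    def test_strict_count_rule(self, row, kept):
        counts = pd.DataFrame([row, [9] * 6], index=["gene_a", "Gene0002"],
                              columns=[f"s{i}" for i in range(6)])
        bulk = sd.BulkTable(
            counts=counts,
            groups=pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns),
            is_mito=pd.Series([False, False], index=counts.index),
        )
        out, _ = qc_mod.filter_bulk_genes(bulk)
        assert ("gene_a" in out.counts.index) == kept

    def test_mito_removed_and_sample_minimum(self):
        counts = pd.DataFrame(
            np.full((2, 6), 50), index=["mt-x", "y"], columns=[f"s{i}" for i in range(6)]
        )
        bulk = sd.BulkTable(
            counts=counts,
            groups=pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns),
            is_mito=pd.Series([True, False], index=counts.index),
        )
        out, rep = qc_mod.filter_bulk_genes(bulk)
        assert list(out.counts.index) == ["y"]
        with pytest.raises(ValueError, match="samples"):
            qc_mod.filter_bulk_genes(
                sd.BulkTable(
                    counts=counts.iloc[:, :4],
                    groups=bulk.groups.iloc[:4],
                    is_mito=bulk.is_mito,
                )
            )


class TestReporterConcordance:
    def test_self_concordance_is_perfect(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3, size=(10, 50))
        m = make_matrix(counts)
        frac, rho = qc_mod.reporter_concordance(m, "g0", "g0")
        assert frac == (counts[0] > 0).mean()
        assert rho == pytest.approx(1.0)

    def test_independent_genes_uncorrelated(self):
        # enough genes that library-size normalization does not couple the
        # two test genes through a shared small denominator
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(2, 0.3, size=(50, 1000))
        m = make_matrix(counts)
        _, rho = qc_mod.reporter_concordance(m, "g0", "g1")
        assert abs(rho) < 0.1

    def test_missing_gene_errors(self):
        m = make_matrix(np.ones((2, 3), dtype=int))
        with pytest.raises(KeyError):
            qc_mod.reporter_concordance(m, "g0", "nope")
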