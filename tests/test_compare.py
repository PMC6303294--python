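"""Cluster matching, simplified bulk DE, and signature correlation."""

import numpy as np
import pandas as pd
import pytest

from il10het import compare as cp
from il10het import qc as qc_mod
from il10het import synthdata as sd
from tests.test_hvg import make_logm


class TestClusterProfiles:
    def test_hand_arithmetic(self):
        values = np.array(
            [[1.0, 3.0, 2.0, 4.0], [0.0, 2.0, 1.0, 1.0], [5.0, 5.0, 0.0, 0.0]]
        )
        logm = make_logm(values)
        prof = cp.cluster_profiles(logm, np.array([0, 0, 1, 1]))
        assert np.allclose(prof[0], [2.0, 1.0, 5.0])
        assert np.allclose(prof[1], [3.0, 1.0, 0.0])

    def test_singleton_cluster_equals_cell(self):
        values = np.random.default_rng(0).normal(size=(6, 3))
        logm = make_logm(values)
        prof = cp.cluster_profiles(logm, np.array([0, 1, 2]))
        assert np.allclose(prof[1], values[:, 1])


class TestClusterSimilarity:
    def test_self_similarity_and_rank_reversal(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 5, size=50)
        prof = pd.DataFrame({"a": vals}, index=[f"g{i}" for i in range(50)])
        sim = cp.cluster_similarity(prof, prof)
        assert sim.rho.loc["a", "a"] == pytest.approx(1.0)
        rev = pd.DataFrame({"b": -vals}, index=prof.index)
        sim2 = cp.cluster_similarity(prof, rev)
        assert sim2.rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_nonzero_both_restriction_is_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 4, size=80)
        b = rng.uniform(0, 4, size=80)
        a[rng.random(80) < 0.3] = 0.0
        b[rng.random(80) < 0.3] = 0.0
        pa = pd.DataFrame({"x": a}, index=[f"g{i}" for i in range(80)])
        pb = pd.DataFrame({"y": b}, index=pa.index)
        s_ab = cp.cluster_similarity(pa, pb).rho.loc["x", "y"]
        s_ba = cp.cluster_similarity(pb, pa).rho.loc["y", "x"]
        assert s_ab == pytest.approx(s_ba)

    def test_too_few_shared_genes_is_missing(self):
        pa = pd.DataFrame({"x": [1.0, 0, 0, 0, 0]}, index=[f"g{i}" for i in range(5)])
        pb = pd.DataFrame({"y": [2.0, 0, 0, 0, 0]}, index=pa.index)
        with pytest.warns(UserWarning, match="non-zero genes"):
            sim = cp.cluster_similarity(pa, pb)
        assert np.isnan(sim.rho.loc["x", "y"])

    def test_planted_shared_program_attains_maximum(self):
        # two "tissues" whose first clusters share a DE program: that pair
        # must be the most similar
        n_endo = 1200 - 92
        rng = np.random.default_rng(3)
        pool = rng.permutation(np.arange(20, n_endo))
        shared, own_a, own_b = pool[:50], pool[50:100], pool[100:150]
        base = rng.lognormal(1.0, 1.0, size=n_endo)
        common = dict(n_genes=1200, n_cells=250, n_clusters=2, de_log2fc=3.0,
                      baseline_means=base)
        m_a = sd.simulate_sc(sd.SCSimSpec(
            **common, de_programs=[shared, own_a], dataset_name="si", seed=4))
        m_b = sd.simulate_sc(sd.SCSimSpec(
            **common, de_programs=[shared, own_b], dataset_name="sp", seed=5))
        from il10het import normalize as nz

        profs = []
        for m in (m_a, m_b):
            logm = nz.log_normalize(m, nz.libsize_factors(m))
            profs.append(cp.cluster_profiles(logm, m.true_cluster))
        sim = cp.cluster_similarity(profs[0], profs[1])
        arr = sim.rho.to_numpy(dtype=float)
        assert np.unravel_index(np.nanargmax(arr), arr.shape) == (0, 0)


class TestBulkDE:
    def test_median_of_ratios_closed_form(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["a", "b", "c"]
        )
        f = cp.median_of_ratios_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_groups_no_de(self):
        counts = pd.DataFrame(
            np.tile([[100], [50], [20]], (1, 6)), index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        bulk = sd.BulkTable(
            counts=counts,
            groups=pd.Series(["x"] * 3 + ["y"] * 3, index=counts.columns),
            is_mito=pd.Series(False, index=counts.index),
        )
        res = cp.bulk_de(bulk, "x", "y")
        assert not res.table["is_de"].any()

    def test_planted_de_recovered(self):
        spec = sd.BulkSimSpec(
            n_genes=2000, groups=(("rich", 3), ("neg", 3)), frac_de=0.15,
            de_log2fc=2.0, seed=0,
        )
        bulk, _ = qc_mod.filter_bulk_genes(sd.simulate_bulk(spec))
        res = cp.bulk_de(bulk, "rich", "neg")
        truth = bulk.true_de.to_numpy()
        called = res.table["is_de"].to_numpy()
        assert (called & truth).sum() / truth.sum() >= 0.9
        fdr = (called & ~truth).sum() / max(called.sum(), 1)
        assert fdr <= 0.05

    def test_replicate_requirement(self):
        counts = pd.DataFrame(np.ones((3, 3)), columns=["s0", "s1", "s2"])
        bulk = sd.BulkTable(
            counts=counts,
            groups=pd.Series(["x", "y", "y"], index=counts.columns),
            is_mito=pd.Series(False, index=counts.index),
        )
        with pytest.raises(ValueError, match="replicates"):
            cp.bulk_de(bulk, "x", "y")


class TestSignatureCorrelation:
    def test_cell_identical_to_signature(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 4, size=40)
        logm = make_logm(vals[:, None])
        sig = cp.SignatureProfile(
            values=pd.Series(vals, index=[f"g{i}" for i in range(40)])
        )
        rho = cp.signature_correlation(logm, sig)
        assert rho.iloc[0] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0.5, 4, size=(30, 20))
        logm = make_logm(values)
        vals = rng.uniform(0.5, 4, size=30)
        idx = [f"g{i}" for i in range(30)]
        sig = cp.SignatureProfile(values=pd.Series(vals, index=idx))
        sig_t = cp.SignatureProfile(values=pd.Series(np.exp(2 * vals), index=idx))
        a = cp.signature_correlation(logm, sig)
        b = cp.signature_correlation(logm, sig_t)
        assert np.allclose(a, b)

    def test_permuted_signature_scores_near_zero(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.5, 4, size=(200, 100))
        logm = make_logm(values)
        sig = cp.SignatureProfile(
            values=pd.Series(rng.permutation(values[:, 0]),
                             index=[f"g{i}" for i in range(200)])
        )
        rho = cp.signature_correlation(logm, sig)
        assert np.median(np.abs(rho)) < 0.1

    def test_empty_intersection_errors(self):
        logm = make_logm(np.ones((15, 2)))
        sig = cp.SignatureProfile(values=pd.Series([1.0] * 15,
                                                   index=[f"z{i}" for i in range(15)]))
        with pytest.raises(ValueError, match="signature genes"):
            cp.signature_correlation(logm, sig)
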