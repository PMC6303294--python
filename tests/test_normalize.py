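"""Size factors: arithmetic, identifiability, deconvolution oracle, invariances."""

import numpy as np
import pytest

from il10het import normalize as nz
from il10het import synthdata as sd
from tests.test_qc import make_matrix


class TestLibsizeFactors:
    def test_two_cell_arithmetic(self):
        f = nz.libsize_factors(make_matrix(np.array([[100, 300]])))
        assert np.allclose(f.factors, [0.5, 1.5])

    def test_equal_totals_all_one_and_scale_invariance(self):
        counts = np.full((4, 6), 7)
        f = nz.libsize_factors(make_matrix(counts))
        assert np.allclose(f.factors, 1.0)
        f2 = nz.libsize_factors(make_matrix(2 * counts))
        assert np.allclose(f.factors, f2.factors)

    def test_zero_library_names_cell(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c1"):
            nz.libsize_factors(make_matrix(counts))


class TestSpikeFactors:
    def test_arithmetic_and_equal_case(self):
        counts = np.array([[50, 100, 150], [9, 9, 9]])
        m = make_matrix(counts, is_spike=np.array([True, False]))
        f = nz.spike_factors(m)
        assert np.allclose(f.factors, [0.5, 1.0, 1.5])
        m2 = make_matrix(np.array([[5, 5], [1, 2]]), is_spike=np.array([True, False]))
        assert np.allclose(nz.spike_factors(m2).factors, 1.0)

    def test_no_spikes_instructs_fallback(self):
        with pytest.raises(ValueError, match="trend"):
            nz.spike_factors(make_matrix(np.ones((2, 2), dtype=int)))

    def test_uncorrelated_with_cluster_identity(self):
        from scipy import stats

        m = sd.simulate_sc(sd.SCSimSpec(n_genes=800, n_cells=500, n_clusters=2, seed=4))
        f = nz.spike_factors(m)
        rho = stats.spearmanr(f.factors, m.true_cluster).statistic
        assert abs(rho) < 0.1


class TestPooledFactors:
    def test_noiseless_proportional_profiles_recovered(self):
        profile = np.array([4.0, 10.0, 1.0, 7.0, 2.0])
        c = np.array([0.5, 1.0, 1.5, 2.0, 0.8, 1.2, 0.9, 1.1] * 4)
        counts = np.rint(profile[:, None] * c[None, :] * 20).astype(int)
        m = make_matrix(counts)
        f = nz.pooled_factors(m, pool_sizes=(3, 5, 8))
        truth = counts.sum(axis=0) / counts.sum(axis=0).mean()
        assert np.allclose(f.factors, truth, atol=1e-6)

    def test_hand_built_system_matches_dense_least_squares(self):
        # 4 cells, 3 genes, pool size 2: rebuild the documented equations by
        # hand and solve with a generic dense routine as the oracle
        counts = np.array([[10, 20, 5, 8], [3, 6, 2, 4], [7, 15, 3, 5]])
        m = make_matrix(counts)
        f = nz.pooled_factors(m, pool_sizes=(2,), ridge_weight=1e-3)

        totals = counts.sum(axis=0).astype(float)
        order = np.lexsort((np.array([f"c{j}" for j in range(4)]), totals))
        ring = np.array([order[0], order[3], order[1], order[2]])
        ref = counts.mean(axis=1)
        rows, rhs = [], []
        for r in range(4):
            members = [ring[r % 4], ring[(r + 1) % 4]]
            pool_sum = counts[:, members].sum(axis=1)
            est = np.median(pool_sum / ref)
            row = np.zeros(4)
            row[members] = 1.0
            rows.append(row)
            rhs.append(est)
        lib = totals / totals.mean()
        for i in range(4):
            row = np.zeros(4)
            row[i] = 1e-3
            rows.append(row)
            rhs.append(1e-3 * lib[i])
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        sol = sol / sol.mean()
        assert np.allclose(f.factors, sol, atol=1e-6)

    def test_invariant_to_cell_order(self):
        m = sd.simulate_sc(sd.SCSimSpec(n_genes=400, n_cells=120, seed=2))
        f = nz.pooled_factors(m)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        f_p = nz.pooled_factors(m.subset_cells(perm))
        assert np.allclose(f.factors[perm], f_p.factors, atol=1e-8)

    def test_methods_agree_without_de(self):
        # agreement is asymptotic in gene count and tightens as the NB noise
        # per gene shrinks; use a deep, low-dispersion DE-free dataset
        spec = sd.SCSimSpec(
            n_genes=3000, n_cells=200, n_clusters=1, frac_de_genes_per_cluster=0.0,
            nb_dispersion=0.1, baseline_meanlog=2.5, seed=6,
        )
        m = sd.simulate_sc(spec)
        fp = nz.pooled_factors(m).factors
        fl = nz.libsize_factors(m).factors
        assert np.corrcoef(fp, fl)[0, 1] > 0.999

    def test_recovers_true_factors_without_de(self):
        spec = sd.SCSimSpec(
            n_genes=1000, n_cells=300, n_clusters=1, frac_de_genes_per_cluster=0.0,
            seed=0,
        )
        m = sd.simulate_sc(spec)
        truth = m.true_size_factor / m.true_size_factor.mean()
        f = nz.pooled_factors(m)
        assert np.corrcoef(f.factors, truth)[0, 1] > 0.95

    def test_beats_libsize_under_composition_bias(self):
        # DE planted in one cluster only: library totals are inflated there,
        # biasing libsize factors; pooling's median ratio resists
        wins = 0
        for seed in range(6):
            n_endo = 1000 - 92
            rng = np.random.default_rng(1000 + seed)
            prog = rng.choice(np.arange(20, n_endo), size=int(0.3 * n_endo),
                              replace=False)
            spec = sd.SCSimSpec(
                n_genes=1000, n_cells=300, n_clusters=2,
                cluster_proportions=(0.6, 0.4),
                de_programs=[np.array([], dtype=int), prog],
                de_log2fc=2.0, seed=seed,
            )
            m = sd.simulate_sc(spec)
            truth = m.true_size_factor / m.true_size_factor.mean()
            rmse_p = np.sqrt(np.mean((nz.pooled_factors(m).factors - truth) ** 2))
            rmse_l = np.sqrt(np.mean((nz.libsize_factors(m).factors - truth) ** 2))
            wins += rmse_p < rmse_l
        assert wins >= 5


class TestLogNormalize:
    def test_arithmetic(self):
        m = make_matrix(np.array([[0, 3]]))
        f = nz.SizeFactorVector(np.array([1.0, 1.0]), "libsize")
        logm = nz.log_normalize(m, f)
        assert logm.values[0, 0] == 0.0
        assert logm.values[0, 1] == pytest.approx(2.0)  # log2(3/1 + 1)

    def test_doubling_counts_and_factor_leaves_column_unchanged(self):
        counts = np.array([[4, 8], [2, 6]])
        m1 = make_matrix(counts)
        m2 = make_matrix(counts * np.array([2, 1]))
        f1 = nz.SizeFactorVector(np.array([1.0, 1.0]), "m")
        f2 = nz.SizeFactorVector(np.array([2.0, 1.0]), "m")
        a = nz.log_normalize(m1, f1).values
        b = nz.log_normalize(m2, f2).values
        assert np.allclose(a, b)

    def test_nonpositive_factor_rejected(self):
        m = make_matrix(np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError):
            nz.SizeFactorVector(np.array([1.0, 0.0]), "bad")
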