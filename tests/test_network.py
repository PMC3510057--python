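import numpy as np
import pandas as pd
import pytest

from pkdnet import network as net
from pkdnet import simulate as sim
from pkdnet.datatypes import ExpressionMatrix
from tests.conftest import make_expression


def tom_oracle(a):
    """Literal triple-loop topological overlap."""
    n = a.shape[0]
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            omega[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return omega


class TestAdjacency:
    def test_powers_of_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        x = make_expression(np.vstack([base, base, -base]))
        a = net.adjacency(x, beta=6).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)  # unsigned: |cor| = 1

    def test_known_value(self):
        assert 0.8**6 == pytest.approx(0.262144)
        # construct two genes with exact correlation 0.8
        rng = np.random.default_rng(1)
        z1 = rng.standard_normal(2000)
        z2 = rng.standard_normal(2000)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 -= z2 @ z1 / 2000 * z1
        z2 = (z2 - z2.mean()) / z2.std()
        y = 0.8 * z1 + np.sqrt(1 - 0.64) * z2
        x = make_expression(np.vstack([z1, y]))
        a = net.adjacency(x, beta=6).to_numpy()
        assert a[0, 1] == pytest.approx(0.262144, abs=1e-6)

    def test_bounds_symmetry_and_signed_mode(self, study):
        x, _, _ = study
        for signed in (False, True):
            a = net.adjacency(x.subset_genes(x.gene_ids[:40]), signed=signed).to_numpy()
            assert np.allclose(a, a.T)
            assert a.min() >= 0.0 and a.max() <= 1.0
            assert np.allclose(np.diag(a), 1.0)

    def test_constant_gene_errors(self):
        x = make_expression(np.vstack([np.ones(6), np.arange(6.0)]))
        with pytest.raises(ValueError, match="G0"):
            net.adjacency(x)


class TestTOM:
    def test_hand_computed_three_nodes(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        omega = net.tom_similarity(a)
        assert omega[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_identity_adjacency(self):
        assert np.allclose(net.tom_similarity(np.eye(4)), np.eye(4))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            c = rng.uniform(0, 1, size=(20, 20))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 1.0)
            assert np.allclose(net.tom_similarity(a), tom_oracle(a), atol=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0, 1, size=(15, 15))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        omega = net.tom_similarity(a)
        assert np.allclose(omega, omega.T)
        assert omega.min() >= 0.0 and omega.max() <= 1.0 + 1e-12

    def test_asymmetric_errors(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            net.tom_similarity(a)


class TestSoftThreshold:
    def test_exact_log_linear_fit(self):
        # distinct connectivity values land in distinct equal-width bins and
        # their frequencies follow an exact power law: R^2 = 1, slope < 0
        k = np.repeat([10.0, 100.0, 1000.0], [100, 10, 1])
        assert net._scale_free_fit(k, n_bins=100) == pytest.approx(1.0, abs=1e-9)

    def test_postcondition_smallest_beta_reaching_target(self, study):
        x, _, _ = study
        beta, fit = net.pick_soft_threshold(x, rsq_target=0.9)
        ok = fit[fit["signed_rsq"] >= 0.9]
        if len(ok):
            assert beta == ok["beta"].iloc[0]
        else:
            assert beta == fit.loc[fit["signed_rsq"].idxmax(), "beta"]

    def test_zero_target_returns_smallest_candidate(self, study):
        x, _, _ = study
        beta, _ = net.pick_soft_threshold(x, candidate_betas=(2, 4, 6), rsq_target=0.0)
        assert beta == 2

    def test_empty_candidates_error(self, study):
        with pytest.raises(ValueError):
            net.pick_soft_threshold(study[0], candidate_betas=())


class TestDetectModules:
    def _block_dissim(self):
        a = np.full((60, 60), 0.05)
        a[:30, :30] = 0.9
        a[30:, 30:] = 0.9
        np.fill_diagonal(a, 1.0)
        tom = net.tom_similarity(a)
        d = 1.0 - tom
        np.fill_diagonal(d, 0.0)
        ids = [f"G{i}" for i in range(60)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_two_planted_blocks_recovered_exactly(self):
        labels = net.detect_modules(
            self._block_dissim(), net.NetworkParams(min_module_size=10)
        )
        assert set(labels[:30]) == {labels.iloc[0]}
        assert set(labels[30:]) == {labels.iloc[30]}
        assert labels.iloc[0] != labels.iloc[30]
        assert (labels != 0).all()

    def test_min_size_larger_than_clusters_gives_all_grey(self):
        labels = net.detect_modules(
            self._block_dissim(), net.NetworkParams(min_module_size=40)
        )
        assert (labels == 0).all() or labels.max() <= 1

    def test_asymmetry_rejected(self):
        d = self._block_dissim()
        d.iloc[0, 1] = 0.123
        with pytest.raises(ValueError, match="symmetric"):
            net.detect_modules(d, net.NetworkParams())

    def test_labels_ordered_by_size(self, study):
        x, _, _ = study
        mods = net.find_modules(x)
        sizes = mods.labels[mods.labels != 0].value_counts()
        assert (sizes.sort_index(ascending=True).diff().dropna() <= 0).all()


class TestEigengenes:
    def test_single_gene_module(self):
        rng = np.random.default_rng(0)
        x = make_expression(rng.standard_normal((1, 10)))
        mods = net.module_eigengenes(x, pd.Series([1], index=x.values.index))
        z = (x.values.iloc[0] - x.values.iloc[0].mean()) / x.values.iloc[0].std(ddof=1)
        assert abs(np.corrcoef(mods.eigengenes.loc[1], z)[0, 1]) == pytest.approx(1.0)
        assert mods.var_explained.loc[1] == pytest.approx(1.0)

    def test_driver_recovery(self):
        rng = np.random.default_rng(5)
        driver = rng.standard_normal(40)
        lam = rng.uniform(0.4, 0.95, 50)
        x = make_expression(
            lam[:, None] * driver[None, :] + rng.standard_normal((50, 40))
        )
        mods = net.module_eigengenes(x, pd.Series(1, index=x.values.index))
        r = np.corrcoef(mods.eigengenes.loc[1], driver)[0, 1]
        assert abs(r) >= 0.9

    def test_sign_oriented_to_module_mean(self, study):
        x, _, truth = study
        mods = net.module_eigengenes(x, truth)
        v = x.values.to_numpy()
        z = (v - v.mean(1, keepdims=True)) / v.std(1, ddof=1, keepdims=True)
        for m in mods.module_ids:
            idx = truth.to_numpy() == m
            r = np.corrcoef(mods.eigengenes.loc[m], z[idx].mean(0))[0, 1]
            assert r > 0

    def test_unit_variance(self, study):
        x, _, truth = study
        mods = net.module_eigengenes(x, truth)
        assert np.allclose(mods.eigengenes.std(axis=1, ddof=1), 1.0)


class TestModuleTrait:
    def test_formula_evaluation(self):
        t, p = net.correlation_test(0.81, 32)
        assert t == pytest.approx(7.566, abs=1e-3)

    def test_published_eigengene_genotype_p(self):
        _, p = net.correlation_test(0.81, 32)
        assert p == pytest.approx(2.5e-8, rel=1.0)  # within a factor of 2

    def test_zero_correlation(self):
        _, p = net.correlation_test(0.0, 32)
        assert p == pytest.approx(1.0)

    def test_constant_trait_errors(self, study):
        x, meta, truth = study
        from pkdnet.datatypes import SampleMetadata

        mods = net.module_eigengenes(x, truth)
        tab = meta.table.copy()
        tab["trait"] = 0
        with pytest.raises(ValueError, match="constant"):
            net.module_trait_correlation(mods, SampleMetadata(tab))

    def test_null_trait_p_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            r = np.corrcoef(rng.standard_normal(20), rng.standard_normal(20))[0, 1]
            ps.append(net.correlation_test(r, 20)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_genotype_module_has_top_correlation(self, study):
        x, meta, truth = study
        mods = net.module_eigengenes(x, truth)
        tab = net.module_trait_correlation(mods, meta)
        assert tab["r"].abs().idxmax() == 1  # module 1 carries the genotype effect


class TestMergeCloseModules:
    def _split_driver_modules(self):
        rng = np.random.default_rng(2)
        driver = rng.standard_normal(30)
        other = rng.standard_normal(30)
        lam = rng.uniform(0.6, 0.95, 60)
        top = lam[:40, None] * driver[None, :] + 0.6 * rng.standard_normal((40, 30))
        bottom = lam[40:, None] * other[None, :] + 0.6 * rng.standard_normal((20, 30))
        x = make_expression(np.vstack([top, bottom]))
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20, index=x.values.index)
        return x, labels

    def test_same_driver_modules_merge(self):
        x, labels = self._split_driver_modules()
        merged = net.merge_close_modules(net.module_eigengenes(x, labels), x, 0.25)
        lab = merged.labels
        assert lab.iloc[0] == lab.iloc[25]  # modules 1 and 2 shared a driver
        assert lab.iloc[0] != lab.iloc[45]  # module 3 is independent

    def test_zero_threshold_is_identity(self):
        x, labels = self._split_driver_modules()
        mods = net.module_eigengenes(x, labels)
        merged = net.merge_close_modules(mods, x, 0.0)
        assert (merged.labels == mods.labels).all()
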