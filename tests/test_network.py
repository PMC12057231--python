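import numpy as np
import pandas as pd
import pytest
from scipy import stats

import proteostage as ps
from proteostage.network import scale_free_fit

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bicor_oracle(x, y, max_p_outliers=0.05):
    """Direct evaluation of the weighted biweight-midcorrelation formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    joint = np.isfinite(x) & np.isfinite(y)
    x, y = x[joint], y[joint]

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - np.mean(v)
        u = (v - med) / (9 * mad)
        q_lo, q_hi = np.quantile(u, [max_p_outliers, 1 - max_p_outliers])
        if q_lo < -1:
            u = np.where(u < 0, u / (-q_lo), u)
        if q_hi > 1:
            u = np.where(u > 0, u / q_hi, u)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return w * (v - med)

    a, b = transform(x), transform(y)
    return np.sum(a * b) / np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))


def tom_oracle(a):
    """Brute-force double-sum topological overlap."""
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


def random_signed_adjacency(rng, n):
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return ps.signed_adjacency(c, 6)


# ---------------------------------------------------------------------------
# bicor
# ---------------------------------------------------------------------------

class TestBicor:
    def test_self_and_antisymmetry_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        assert ps.bicor(x, x) == 1.0
        assert ps.bicor(x, -x) == -1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            x = rng.normal(size=40) + rng.standard_cauchy(size=40) * 0.2
            y = 0.5 * x + rng.normal(size=40)
            assert abs(ps.bicor(x, y) - bicor_oracle(x, y)) < 1e-12

    def test_matrix_matches_oracle_on_complete_data(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 60)) + rng.standard_cauchy((6, 60)) * 0.1
        C = ps.bicor_matrix(make_matrix(vals), min_pairs=5)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = bicor_oracle(vals[i], vals[j])
                assert abs(C.iloc[i, j] - expect) < 1e-12

    def test_matrix_close_to_per_pair_oracle_with_missing_data(self):
        # with missing entries the matrix routine estimates weights per
        # protein (not per pair); the difference is only in weight estimates
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 80))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        C = ps.bicor_matrix(make_matrix(vals), min_pairs=5)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = bicor_oracle(vals[i], vals[j])
                assert abs(C.iloc[i, j] - expect) < 0.02

    def test_close_to_pearson_without_outliers(self):
        rng = np.random.default_rng(3)
        cov = [[1, 0.6], [0.6, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000)
        b = ps.bicor(xy[:, 0], xy[:, 1])
        p = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert abs(b - p) < 0.05

    def test_mad_zero_falls_back_to_exact_pearson(self):
        # when both vectors are majority-tied (MAD = 0 but SD > 0) the
        # biweights are undefined and the correlation is plain Pearson
        x = np.array([5.0] * 12 + [1.0, 2.0, 9.0, 11.0])
        y = np.array([3.0] * 12 + [0.5, 1.0, 6.0, 8.0])
        assert np.median(np.abs(x - np.median(x))) == 0
        assert np.median(np.abs(y - np.median(y))) == 0
        assert abs(ps.bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 1e-12

    def test_constant_vector_yields_zero_with_warning(self):
        vals = np.vstack([np.full(20, 3.0), np.random.default_rng(5).normal(size=20)])
        with pytest.warns(UserWarning, match="undefined"):
            C = ps.bicor_matrix(make_matrix(vals), min_pairs=5)
        assert C.iloc[0, 1] == 0.0

    def test_min_pairs_guard(self):
        vals = np.full((2, 12), np.nan)
        vals[0, :6] = [1, 2, 3, 4, 5, 6]
        vals[1, 6:] = [1, 2, 3, 4, 5, 6]
        with pytest.warns(UserWarning, match="joint observations"):
            C = ps.bicor_matrix(make_matrix(vals), min_pairs=10)
        assert C.iloc[0, 1] == 0.0


# ---------------------------------------------------------------------------
# soft threshold and adjacency
# ---------------------------------------------------------------------------

class TestSoftThreshold:
    def test_signed_adjacency_closed_forms(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert np.allclose(ps.signed_adjacency(c, 7), 1.0)
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a = ps.signed_adjacency(c, 7)
        assert a[0, 1] == 0.0 and a[0, 0] == 1.0
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.isclose(ps.signed_adjacency(c, 10)[0, 1], 0.5 ** 10)

    def test_planted_power_law_degrees_fit_well(self):
        u = (np.arange(1, 501) - 0.5) / 500
        k = u ** (-1 / 1.5)          # Pareto quantiles, gamma = 2.5
        assert scale_free_fit(k) >= 0.9

    def test_mean_connectivity_non_increasing_in_power(self, network_model):
        diag = ps.select_soft_threshold(
            network_model.cor.to_numpy(), candidates=range(1, 13)
        )
        mc = diag.mean_connectivity
        assert all(mc[i + 1] <= mc[i] + 1e-9 for i in range(len(mc) - 1))
        assert diag.chosen_power in diag.candidate_powers

    def test_degenerate_correlations_rejected(self):
        c = np.full((5, 5), 0.5)
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            ps.select_soft_threshold(c)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

class TestTopologicalOverlap:
    def test_clique_and_empty_graph(self):
        ones = np.ones((3, 3))
        assert np.allclose(ps.topological_overlap(ones), 1.0)
        eye = np.eye(4)
        tom = ps.topological_overlap(eye)
        assert np.allclose(tom, np.eye(4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        a = random_signed_adjacency(rng, 8)
        assert np.abs(ps.topological_overlap(a) - tom_oracle(a)).max() < 1e-10

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_signed_adjacency(rng, 12)
            tom = ps.topological_overlap(a)
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
            assert np.allclose(tom, tom.T)


# ---------------------------------------------------------------------------
# dynamic tree cut
# ---------------------------------------------------------------------------

def block_dissim(rng, sizes, within=0.1, between=0.9, noise=0.0):
    n = sum(sizes)
    D = np.full((n, n), between)
    start = 0
    for s in sizes:
        D[start:start + s, start:start + s] = within
        start += s
    if noise:
        eps = rng.uniform(-noise, noise, size=(n, n))
        eps = (eps + eps.T) / 2
        D = np.clip(D + eps, 0.01, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


class TestCutTreeDynamic:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        D = block_dissim(rng, [20, 20], noise=0.02)
        _, labels = ps.cut_tree_dynamic(D, min_size=10)
        assert set(labels) == {1, 2}
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_all_equal_dissimilarity_gives_no_modules(self):
        D = np.full((30, 30), 0.5)
        np.fill_diagonal(D, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            _, labels = ps.cut_tree_dynamic(D, min_size=5)
        assert (labels == 0).all()

    def test_module_count_non_decreasing_in_deep_split(self):
        # nested blocks: two superclusters each holding two tight subclusters
        rng = np.random.default_rng(1)
        n_sub = 12
        D = np.full((4 * n_sub, 4 * n_sub), 0.9)
        for sup in range(2):
            lo = sup * 2 * n_sub
            D[lo:lo + 2 * n_sub, lo:lo + 2 * n_sub] = 0.45
            for sub in range(2):
                s = lo + sub * n_sub
                D[s:s + n_sub, s:s + n_sub] = 0.1
        eps = rng.uniform(-0.02, 0.02, D.shape)
        D = np.clip(D + (eps + eps.T) / 2, 0.01, 1.0)
        np.fill_diagonal(D, 0.0)
        counts = []
        for ds in range(5):
            _, labels = ps.cut_tree_dynamic(D, deep_split=ds, min_size=10)
            counts.append(len(set(labels) - {0}))
        assert counts == sorted(counts)
        assert counts[0] >= 2 and counts[-1] == 4

    def test_fewer_items_than_min_size(self):
        D = block_dissim(np.random.default_rng(2), [4], noise=0.01)
        with pytest.warns(UserWarning, match="min_size"):
            _, labels = ps.cut_tree_dynamic(D, min_size=10)
        assert (labels == 0).all()

    def test_protein_permutation_equivariance(self, normalized):
        """Permuting protein order yields the same partition."""
        from sklearn.metrics import adjusted_rand_score

        sub = normalized.subset_proteins(normalized.protein_ids[:150])
        net1 = ps.build_network(sub)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sub.protein_ids))
        net2 = ps.build_network(sub.subset_proteins(perm))
        l1 = net1.labels.loc[perm].to_numpy()
        l2 = net2.labels.to_numpy()
        assert adjusted_rand_score(l1, l2) == 1.0
        assert ((l1 == 0) == (l2 == 0)).all()


# ---------------------------------------------------------------------------
# eigenproteins, kME, merging
# ---------------------------------------------------------------------------

def rank1_module(rng, n_prot, n_samp, noise=0.0):
    factor = rng.normal(size=n_samp)
    loadings = rng.uniform(0.5, 1.0, size=n_prot)
    vals = np.outer(loadings, factor) + rng.normal(0, noise, (n_prot, n_samp))
    return vals, factor


class TestEigenproteins:
    def test_noiseless_rank1_recovery(self):
        rng = np.random.default_rng(0)
        vals, factor = rank1_module(rng, 10, 40)
        summary = ps.compute_eigenproteins(make_matrix(vals), np.ones(10, int))
        e = summary.eigenprotein["M1"].to_numpy()
        assert abs(np.corrcoef(e, factor)[0, 1]) > 1 - 1e-10
        assert summary.variance_explained["M1"] > 0.95

    def test_sign_convention_follows_mean_abundance(self):
        vals = np.tile(np.linspace(-1, 1, 30), (5, 1))  # uniformly increasing
        summary = ps.compute_eigenproteins(make_matrix(vals), np.ones(5, int))
        e = summary.eigenprotein["M1"].to_numpy()
        assert e[-1] > e[0]

    def test_kme_of_protein_identical_to_eigenprotein(self):
        rng = np.random.default_rng(1)
        vals, factor = rank1_module(rng, 8, 50, noise=0.3)
        m = make_matrix(vals)
        summary = ps.compute_eigenproteins(m, np.ones(8, int))
        # append the eigenprotein itself as a protein
        vals2 = np.vstack([vals, summary.eigenprotein["M1"].to_numpy()])
        m2 = make_matrix(vals2)
        kme = ps.compute_kme(m2, summary)
        assert np.isclose(kme.iloc[-1]["M1"], 1.0)

    def test_top_hub_protein_has_maximal_kme(self):
        rng = np.random.default_rng(2)
        vals, _ = rank1_module(rng, 20, 60, noise=0.4)
        m = make_matrix(vals)
        summary = ps.compute_eigenproteins(m, np.ones(20, int))
        kme = ps.compute_kme(m, summary)["M1"]
        adj = ps.signed_adjacency(ps.bicor_matrix(m).to_numpy(), 6)
        np.fill_diagonal(adj, 0.0)
        hub = int(np.argmax(adj.sum(axis=1)))
        assert kme.iloc[hub] >= kme.max() - 1e-9

    def test_noise_protein_has_low_kme(self, network_model, normalized):
        rng = np.random.default_rng(3)
        kme = network_model.summary.kme
        labels = network_model.labels
        noise_prots = labels.index[labels == 0][:50]
        frac_high = (kme.loc[noise_prots].abs() > 0.3).to_numpy().mean()
        assert frac_high < 0.2  # mostly |kME| < 0.3 at n = 140


class TestMergeModules:
    def _two_correlated_modules(self, rho, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        f1 = rng.normal(size=n)
        f2 = rho * f1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        vals = np.vstack([
            np.outer(rng.uniform(0.8, 1.0, 10), f1) + rng.normal(0, 0.05, (10, n)),
            np.outer(rng.uniform(0.8, 1.0, 10), f2) + rng.normal(0, 0.05, (10, n)),
        ])
        labels = np.array([1] * 10 + [2] * 10)
        return make_matrix(vals), labels

    def test_highly_correlated_modules_merge(self):
        m, labels = self._two_correlated_modules(0.97)
        merged = ps.merge_close_modules(m, labels, cut_height=0.2)
        assert len(set(merged)) == 1

    def test_distinct_modules_stay_separate(self):
        m, labels = self._two_correlated_modules(0.5)
        merged = ps.merge_close_modules(m, labels, cut_height=0.2)
        assert len(set(merged)) == 2

    def test_merge_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 150
        f = rng.normal(size=n)
        blocks, labels = [], []
        for k in range(3):  # three mutually similar modules
            fk = 0.97 * f + np.sqrt(1 - 0.97 ** 2) * rng.normal(size=n)
            blocks.append(np.outer(rng.uniform(0.8, 1, 8), fk)
                          + rng.normal(0, 0.05, (8, n)))
            labels += [k + 1] * 8
        m = make_matrix(np.vstack(blocks))
        base = ps.merge_close_modules(m, np.array(labels))
        assert len(set(base)) == 1
        for perm in ([2, 3, 1], [3, 1, 2]):
            relabeled = np.array([perm[l - 1] for l in labels])
            merged = ps.merge_close_modules(m, relabeled)
            assert len(set(merged)) == 1
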