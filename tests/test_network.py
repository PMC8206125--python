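import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locusnet.io import UNASSIGNED
from locusnet.network import (
    CoexpressionNetwork,
    bicor,
    bicor_matrix,
    cluster_and_cut,
    detect_modules,
    merge_close_modules,
    meta_modules,
    module_eigengenes,
    pick_power,
    sft_scan,
    signed_adjacency,
    tom,
)


def tom_triple_loop(adj: np.ndarray) -> np.ndarray:
    """O(n^3) reference implementation of topological overlap."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_signed_adjacency(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2 * n))
    corr = np.corrcoef(x)
    return signed_adjacency(corr, 4)


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(50)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_shift_and_scale_invariance(self, rng):
        x, y = rng.standard_normal((2, 80))
        assert bicor(3 * x + 7, 0.5 * y - 2) == pytest.approx(bicor(x, y), abs=1e-12)

    def test_agrees_with_pearson_on_clean_gaussian(self):
        close = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            z, e = r.standard_normal((2, 1000))
            x, y = z, 0.6 * z + 0.8 * e
            close += abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05
        assert close == 50

    def test_more_robust_than_pearson_to_single_outlier(self):
        # one 10-sigma contaminated pair: the biweight downweights it while
        # Pearson is dragged off the true correlation
        wins = 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            z, e = r.standard_normal((2, 1000))
            x, y = z.copy(), 0.6 * z + 0.8 * e
            x[0], y[0] = 10.0, -10.0 * y.std()
            wins += abs(bicor(x, y) - 0.6) < abs(np.corrcoef(x, y)[0, 1] - 0.6)
        assert wins >= 180

    def test_zero_mad_falls_back_to_pearson_with_warning(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])  # median-absolute-deviation 0
        y = np.array([0.1, 0.2, 0.1, 0.2, 3.0])
        with pytest.warns(UserWarning, match="MAD"):
            value = bicor(x, y)
        assert -1 <= value <= 1

    def test_matrix_version_symmetric_unit_diagonal(self, rng):
        X = rng.standard_normal((10, 40))
        corr = bicor_matrix(X)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(np.abs(corr) <= 1)


class TestSignedAdjacency:
    def test_extremes_and_midpoint(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(signed_adjacency(corr, 8), 1.0)
        corr = np.array([[1.0, -1.0], [-1.0, 1.0]])
        adj = signed_adjacency(corr, 8)
        assert adj[0, 1] == 0.0 and adj[0, 0] == 1.0
        corr = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(corr, 8)[0, 1] == pytest.approx(0.00390625)

    def test_out_of_range_correlations_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.array([[1.0, 1.5], [1.5, 1.0]]), 2)

    @settings(max_examples=30, deadline=None)
    @given(
        c=st.floats(-1, 1),
        beta1=st.integers(1, 12),
    )
    def test_monotone_in_correlation_and_power(self, c, beta1):
        corr = np.array([[1.0, c], [c, 1.0]])
        a1 = signed_adjacency(corr, beta1)[0, 1]
        a2 = signed_adjacency(corr, beta1 + 1)[0, 1]
        assert 0 <= a1 <= 1
        assert a2 <= a1 + 1e-15  # raising the power never increases an entry
        if c < 1:
            higher = np.array([[1.0, min(c + 0.1, 1.0)], [min(c + 0.1, 1.0), 1.0]])
            assert signed_adjacency(higher, beta1)[0, 1] >= a1


class TestSFT:
    def test_lowest_power_reaching_target_selected(self):
        sft = pd.DataFrame(
            {"signed_r2": [0.2, 0.55, 0.78, 0.83, 0.86],
             "slope": [-1.5, -1.6, -1.7, -1.8, -1.9],
             "max_k": [1000.0] * 5, "min_k": [10.0] * 5},
            index=pd.Index([2, 4, 6, 8, 10], name="power"),
        )
        assert pick_power(sft, target_r2=0.8) == 8

    def test_fallback_warns_and_returns_best_fit(self):
        sft = pd.DataFrame(
            {"signed_r2": [0.2, 0.5, 0.6], "slope": [-1.5, -1.6, -1.7],
             "max_k": [1000.0] * 3, "min_k": [10.0] * 3},
            index=pd.Index([2, 4, 6], name="power"),
        )
        with pytest.warns(UserWarning, match="no candidate power"):
            assert pick_power(sft, target_r2=0.8) == 6

    def test_scan_reaches_target_on_modular_cohort(self, default_sim):
        _, ref, *_ = default_sim
        sft = sft_scan(ref)
        beta = pick_power(sft)
        assert beta <= 12
        assert sft.loc[beta, "signed_r2"] >= 0.8

    def test_scan_requires_two_powers(self, small_sim):
        _, ref, *_ = small_sim
        with pytest.raises(ValueError):
            sft_scan(ref, powers=(6,))


class TestTOM:
    def test_hand_worked_three_gene_case(self):
        # all off-diagonal adjacencies 0.5: l_12 = 0.25, k = 1 each,
        # TOM_12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 1.0)
        out = tom(adj)
        np.testing.assert_allclose(out[np.triu_indices(3, 1)], 0.5)

    def test_empty_network_stays_empty(self):
        out = tom(np.eye(4))
        np.testing.assert_allclose(out, np.eye(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        adj = random_signed_adjacency(50, seed)
        np.testing.assert_allclose(tom(adj), tom_triple_loop(adj), atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_range_invariant_on_random_adjacency(self, seed):
        t = tom(random_signed_adjacency(40, seed))
        assert t.min() >= 0 and t.max() <= 1
        np.testing.assert_allclose(t, t.T)


class TestEigengenes:
    def test_identical_genes_give_rank_one_module(self, rng):
        profile = rng.standard_normal(30)
        expr = pd.DataFrame(
            np.tile(profile, (5, 1)), index=[f"g{i}" for i in range(5)]
        )
        partition = pd.Series(1, index=expr.index)
        eig, kme, kme_p = module_eigengenes(expr, partition)
        assert eig.prop_var["M1"] == pytest.approx(1.0)
        standardized = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(
            np.abs(eig.me.loc["M1"].to_numpy()),
            np.abs(standardized / np.linalg.norm(standardized)),
            atol=1e-10,
        )

    def test_matches_full_svd_oracle(self, rng):
        expr = pd.DataFrame(rng.standard_normal((30, 25)),
                            index=[f"g{i}" for i in range(30)])
        partition = pd.Series(1, index=expr.index)
        eig, kme, _ = module_eigengenes(expr, partition)
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        U, S, Vt = np.linalg.svd(Xs)
        np.testing.assert_allclose(
            np.abs(eig.me.loc["M1"].to_numpy()), np.abs(Vt[0]), atol=1e-10
        )
        assert eig.prop_var["M1"] == pytest.approx(S[0] ** 2 / (S**2).sum(), abs=1e-10)

    def test_gene_equal_to_its_eigengene_has_unit_kme(self, rng):
        base = rng.standard_normal(100)
        expr = pd.DataFrame(
            np.vstack([base + 0.01 * rng.standard_normal(100) for _ in range(10)]),
            index=[f"g{i}" for i in range(10)],
        )
        partition = pd.Series(1, index=expr.index)
        eig, kme, kme_p = module_eigengenes(expr, partition)
        top = kme["M1"].abs().idxmax()
        assert kme.loc[top, "M1"] > 0.99
        assert kme_p.loc[top, "M1"] < 1e-10

    def test_sign_alignment_makes_mean_member_kme_positive(self, small_sim):
        _, ref, _, _, truth = small_sim
        eig, kme, _ = module_eigengenes(ref, truth.true_partition)
        for m in (1, 2, 3):
            members = truth.module_members(m)
            assert kme.loc[members, f"M{m}"].mean() > 0

    def test_kme_pvalues_uniform_under_null(self, rng):
        # independent gene vs eigengene at n=100
        from scipy import stats as ss

        from locusnet.network import correlation_pvalues

        me = rng.standard_normal(100)
        genes = rng.standard_normal((5000, 100))
        gc = genes - genes.mean(1, keepdims=True)
        mc = me - me.mean()
        r = gc @ mc / np.sqrt((gc**2).sum(1) * (mc**2).sum())
        p = correlation_pvalues(r, 100)
        assert ss.kstest(p, "uniform").statistic < 0.03


class TestMergeAndMeta:
    def _expr_from_me(self, me_rows, sizes, rng, noise=0.3):
        rows, labels = [], []
        for m, (me, size) in enumerate(zip(me_rows, sizes), start=1):
            for _ in range(size):
                rows.append(me + noise * rng.standard_normal(len(me)))
                labels.append(m)
        expr = pd.DataFrame(np.array(rows), index=[f"g{i}" for i in range(len(rows))])
        return expr, pd.Series(labels, index=expr.index)

    def test_split_module_remerges(self, rng):
        me = rng.standard_normal(60)
        expr, partition = self._expr_from_me([me, me], [20, 20], rng)
        merged, eig = merge_close_modules(expr, partition)
        assert merged.nunique() == 1

    def test_orthogonal_modules_stay_separate(self, rng):
        me1, me2 = rng.standard_normal((2, 60))
        expr, partition = self._expr_from_me([me1, me2], [20, 20], rng)
        merged, _ = merge_close_modules(expr, partition)
        assert merged.nunique() == 2

    def test_correlated_chain_merges_through_average_linkage(self, rng):
        # r(A,B) ~ r(B,C) ~ 0.85 with r(A,C) lower: one merged module
        base = rng.standard_normal(200)
        meA = base
        meB = 0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(200)
        meC = 0.9 * meB + np.sqrt(1 - 0.81) * rng.standard_normal(200)
        expr, partition = self._expr_from_me([meA, meB, meC], [15, 15, 15], rng, noise=0.05)
        merged, _ = merge_close_modules(expr, partition)
        assert merged.nunique() == 1

    def test_meta_modules_group_positively_correlated_eigengenes(self, rng):
        from locusnet.network import EigengeneSet

        me1 = rng.standard_normal(50)
        me2 = 0.7 * me1 + np.sqrt(1 - 0.49) * rng.standard_normal(50)
        me3 = rng.standard_normal(50)
        me = pd.DataFrame([me1, me2, me3], index=["M1", "M2", "M3"])
        eig = EigengeneSet(me=me, prop_var=pd.Series(1.0, index=me.index))
        groups = meta_modules(eig, cut_height=0.5)
        assert groups[1] == groups[2] != groups[3]

    def test_meta_module_recovery_on_correlated_groups(self):
        # two groups of eigengenes with within-group cor ~0.6, between ~0:
        # the grouping is recovered in at least 9 of 10 seeds
        from locusnet.network import EigengeneSet

        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            f1, f2 = r.standard_normal((2, 100))
            rows = [np.sqrt(0.6) * f1 + np.sqrt(0.4) * r.standard_normal(100) for _ in range(3)]
            rows += [np.sqrt(0.6) * f2 + np.sqrt(0.4) * r.standard_normal(100) for _ in range(3)]
            me = pd.DataFrame(rows, index=[f"M{i}" for i in range(1, 7)])
            eig = EigengeneSet(me=me, prop_var=pd.Series(1.0, index=me.index))
            groups = meta_modules(eig, cut_height=0.5)
            g = [groups[m] for m in range(1, 7)]
            hits += (len({*g[:3]}) == 1 and len({*g[3:]}) == 1 and g[0] != g[3])
        assert hits >= 9


class TestClusterAndCut:
    def test_too_few_genes_all_unassigned(self, rng):
        n = 20
        d = 1 - np.abs(np.corrcoef(rng.standard_normal((n, 30))))
        np.fill_diagonal(d, 0)
        _, partition = cluster_and_cut(d, pd.Index([f"g{i}" for i in range(n)]),
                                       min_module_size=30)
        assert (partition == UNASSIGNED).all()

    def test_estimator_recovers_planted_partition(self, small_sim):
        from sklearn.metrics import adjusted_rand_score

        _, ref, _, _, truth = small_sim
        net = detect_modules(ref)
        assert adjusted_rand_score(truth.true_partition.values, net.labels_) > 0.7

    def test_estimator_is_deterministic(self, small_sim):
        _, ref, *_ = small_sim
        a = detect_modules(ref)
        b = detect_modules(ref)
        assert (a.labels_ == b.labels_).all()
        assert a.power_ == b.power_

    def test_sklearn_estimator_contract(self, small_sim):
        from sklearn.base import clone

        _, ref, *_ = small_sim
        net = CoexpressionNetwork(power=6, min_module_size=20)
        params = net.get_params()
        assert params["power"] == 6 and params["merge_cut_height"] == 0.2
        cloned = clone(net)
        labels = cloned.fit_predict(ref.T)
        assert labels.shape == (ref.shape[0],)
        assert cloned.n_features_in_ == ref.shape[0]
        assert set(cloned.kme_.columns) == {f"M{m}" for m in cloned.eigengenes_.modules}
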