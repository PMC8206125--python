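import itertools
import math

import numpy as np
import pandas as pd
import pytest

from locusnet.io import GeneSetCollection
from locusnet.prioritize import (
    assemble_drivers,
    bh_adjust,
    call_hubs,
    enrichment_screen,
    hypergeom_overlap,
    hypergeom_pvalue,
    interval_modules,
    top_neighbors,
)


def enumeration_pvalue(N, K, n, q):
    """Brute-force oracle: enumerate every n-subset of an N-universe."""
    universe = range(N)
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += sum(1 for g in draw if g < K) >= q
    return hits / total


class TestIntervalModules:
    def test_distribution_counts_recovered(self):
        # seven interval-harboring modules with 1,4,1,6,1,3,5 interval genes
        counts = {1: 1, 2: 4, 3: 1, 4: 6, 5: 1, 6: 3, 7: 5}
        genes, labels = [], []
        i = 0
        for m, c in counts.items():
            for _ in range(c):
                genes.append(f"INT{i:02d}")
                labels.append(m)
                i += 1
        for j in range(50):
            genes.append(f"BG{j}")
            labels.append(0 if j % 2 else 8)
        partition = pd.Series(labels, index=genes)
        result = interval_modules(partition, [g for g in genes if g.startswith("INT")])
        assert {m: len(v) for m, v in result.items()} == counts

    def test_unassigned_interval_gene_creates_no_module(self):
        partition = pd.Series({"A": 0, "B": 1})
        result = interval_modules(partition, ["A", "B"])
        assert set(result) == {1}

    def test_all_in_one_module(self):
        partition = pd.Series(1, index=[f"I{k}" for k in range(21)])
        result = interval_modules(partition, list(partition.index))
        assert set(result) == {1} and len(result[1]) == 21

    def test_error_when_nothing_assigned(self):
        partition = pd.Series({"A": 0})
        with pytest.raises(ValueError):
            interval_modules(partition, ["A"])


class TestCallHubs:
    def _tables(self, rows):
        genes = list(rows)
        kme = pd.DataFrame({"M1": [rows[g][0] for g in genes]}, index=genes)
        p = pd.DataFrame({"M1": [rows[g][1] for g in genes]}, index=genes)
        partition = pd.Series(1, index=genes)
        return kme, p, partition

    def test_high_kme_significant_gene_is_hub(self):
        kme, p, part = self._tables({"UBX": (0.84, 8.33e-30)})
        hubs, excluded = call_hubs(kme, p, part, ["UBX"])
        assert hubs == ["UBX"] and excluded == []

    def test_low_kme_nonsignificant_gene_flagged_for_exclusion(self):
        kme, p, part = self._tables({"SMC": (0.11, 0.25)})
        hubs, excluded = call_hubs(kme, p, part, ["SMC"])
        assert hubs == [] and excluded == ["SMC"]

    def test_high_kme_without_significance_is_not_hub(self):
        kme, p, part = self._tables({"G": (0.9, 0.2)})
        hubs, excluded = call_hubs(kme, p, part, ["G"])
        assert hubs == [] and excluded == ["G"]


class TestTopNeighbors:
    def _cohort(self, rng, n=60):
        base = rng.standard_normal(n)
        data = {
            "seed": base,
            "friend": 0.8 * base + 0.6 * rng.standard_normal(n),
            "stranger": rng.standard_normal(n),
            "othermod": 0.95 * base + 0.3 * rng.standard_normal(n),
        }
        expr = pd.DataFrame(data).T
        partition = pd.Series({"seed": 1, "friend": 1, "stranger": 1, "othermod": 2})
        return expr, partition

    def test_correlated_intramodular_gene_kept(self, rng):
        expr, partition = self._cohort(rng)
        ns = top_neighbors(expr, partition, "seed")
        assert "friend" in ns.genes and "stranger" not in ns.genes

    def test_strong_correlation_outside_module_ignored(self, rng):
        expr, partition = self._cohort(rng)
        ns = top_neighbors(expr, partition, "seed")
        assert "othermod" not in ns.genes

    def test_mutual_neighborhood_is_symmetric(self, rng):
        expr, partition = self._cohort(rng)
        a = top_neighbors(expr, partition, "seed")
        b = top_neighbors(expr, partition, "friend")
        assert ("friend" in a.genes) == ("seed" in b.genes)

    def test_isolated_seed_yields_empty_set(self, rng):
        n = 60
        expr = pd.DataFrame(rng.standard_normal((5, n)),
                            index=["seed", "a", "b", "c", "d"])
        partition = pd.Series(1, index=expr.index)
        assert len(top_neighbors(expr, partition, "seed")) == 0

    def test_unassigned_seed_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 30)), index=["s", "t"])
        partition = pd.Series({"s": 0, "t": 1})
        with pytest.raises(ValueError):
            top_neighbors(expr, partition, "s")

    def test_spearman_pvalues_uniform_under_null(self, rng):
        from scipy import stats as ss

        from locusnet.prioritize import spearman_to_seed

        expr = pd.DataFrame(rng.standard_normal((2501, 100)),
                            index=[f"g{i}" for i in range(2501)])
        rho, p = spearman_to_seed(expr, "g0", [f"g{i}" for i in range(1, 2501)])
        assert ss.kstest(p, "uniform").statistic < 0.03


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=5, n=4, q=4: p = C(5,4)/C(10,4) = 5/210
        genes = [f"g{i}" for i in range(10)]
        res = hypergeom_overlap(genes[:4], genes[:5], genes)
        assert res["p_raw"] == pytest.approx(5 / 210, abs=1e-15)

    def test_zero_overlap_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        res = hypergeom_overlap(genes[:3], genes[5:], genes)
        assert res["overlap_count"] == 0 and res["p_raw"] == 1.0

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 3, 3, 4)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(["a"], ["a"], [])

    def test_matches_exhaustive_enumeration_on_grid(self):
        rng = np.random.default_rng(0)
        checked = 0
        for N in (5, 8, 11, 14):
            for _ in range(15):
                K = int(rng.integers(1, N + 1))
                n = int(rng.integers(1, N + 1))
                lo, hi = max(0, n - (N - K)), min(K, n)
                q = int(rng.integers(lo, hi + 1))
                assert hypergeom_pvalue(N, K, n, q) == pytest.approx(
                    enumeration_pvalue(N, K, n, q), abs=1e-12
                )
                checked += 1
        assert checked == 60

    def test_float_path_agrees_with_exact_integers(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(50, 1500))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n - (N - K)), min(K, n)
            q = int(rng.integers(lo, hi + 1))
            exact = hypergeom_pvalue(N, K, n, q)
            floaty = hypergeom_pvalue(N, K, n, q, exact_limit=0)
            assert floaty == pytest.approx(exact, rel=1e-10, abs=1e-12)

    def test_cross_check_against_scipy(self):
        from scipy import stats as ss

        rng = np.random.default_rng(2)
        for _ in range(30):
            N = int(rng.integers(100, 50000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n - (N - K)), min(K, n)
            q = int(rng.integers(lo, hi + 1))
            ref = float(ss.hypergeom.sf(q - 1, N, K, n))
            assert hypergeom_pvalue(N, K, n, q) == pytest.approx(ref, rel=1e-8, abs=1e-250)


class TestBH:
    def test_step_up_worked_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.03])

    def test_single_test_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_families_corrected_separately(self):
        joint = bh_adjust([0.01, 0.04, 0.01, 0.04], families=["a", "a", "b", "b"])
        np.testing.assert_allclose(joint, [0.02, 0.04, 0.02, 0.04])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestScreenAndDrivers:
    def _fake_neighbor_set(self, seed, genes, module=1):
        from locusnet.prioritize import TopNeighborSet

        members = pd.DataFrame(
            {"gene": genes, "rho": 0.7, "pvalue": 1e-6}
        )
        return TopNeighborSet(seed=seed, module=module, members=members)

    def test_empty_neighbor_sets_rejected_only_if_all_empty(self):
        universe = [f"g{i}" for i in range(100)]
        panels = GeneSetCollection(sets={"D": universe[:10]})
        controls = GeneSetCollection(sets={"C": universe[10:20]})
        empty = self._fake_neighbor_set("s1", [])
        with pytest.raises(ValueError):
            enrichment_screen([empty], panels, controls, universe)
        full = self._fake_neighbor_set("s2", universe[:8])
        table, summary = enrichment_screen([empty, full], panels, controls, universe)
        assert set(table["seed"]) == {"s2"}
        assert summary["disease_tests"] == 1 and summary["control_tests"] == 1

    def test_planted_overlap_flagged_and_control_not(self):
        universe = [f"g{i}" for i in range(1000)]
        neighbors = self._fake_neighbor_set("s", universe[:50])
        panels = GeneSetCollection(sets={"D": universe[:30]})  # heavy overlap
        controls = GeneSetCollection(sets={"C": universe[500:530]})
        table, summary = enrichment_screen([neighbors], panels, controls, universe)
        disease = table[table["family"] == "disease"].iloc[0]
        control = table[table["family"] == "control"].iloc[0]
        assert disease["significant"] and not control["significant"]
        assert disease["p_adjusted"] >= disease["p_raw"]

    def test_no_significant_tests_give_empty_driver_set(self):
        screen = pd.DataFrame(
            {"seed": ["s"], "gene_set": ["D"], "family": ["disease"],
             "significant": [False], "overlap_genes": [["x"]]}
        )
        drivers = assemble_drivers(screen, [self._fake_neighbor_set("s", ["x"])])
        assert len(drivers) == 0

    def test_driver_set_is_seed_plus_overlap_genes(self):
        ns = self._fake_neighbor_set("s", ["g1", "g2", "g3"])
        screen = pd.DataFrame(
            {"seed": ["s"], "gene_set": ["D"], "family": ["disease"],
             "significant": [True], "overlap_genes": [["g1", "g2"]]}
        )
        drivers = assemble_drivers(screen, [ns])
        assert drivers.genes == ["g1", "g2", "s"]
        assert set(drivers.provenance["role"]) == {"partner", "seed"}

    def test_driver_assembly_invariant_to_test_order(self):
        ns1 = self._fake_neighbor_set("s1", ["g1", "g2"])
        ns2 = self._fake_neighbor_set("s2", ["g3"])
        rows = [
            {"seed": "s1", "gene_set": "D1", "family": "disease",
             "significant": True, "overlap_genes": ["g1"]},
            {"seed": "s2", "gene_set": "D2", "family": "disease",
             "significant": True, "overlap_genes": ["g3"]},
        ]
        a = assemble_drivers(pd.DataFrame(rows), [ns1, ns2])
        b = assemble_drivers(pd.DataFrame(rows[::-1]), [ns2, ns1])
        assert a.genes == b.genes and a.prioritized_seeds == b.prioritized_seeds

    def test_null_raw_pvalue_rate_calibrated(self):
        # random neighbor sets vs random panels: raw p < 0.05 in 5% +/- 1%
        # of tests; margins are kept wide so the discrete p is near-continuous
        from scipy import stats as ss

        rng = np.random.default_rng(9)
        N, K, n, reps = 100000, 25000, 10000, 2500
        qs = ss.hypergeom.rvs(N, K, n, size=reps, random_state=rng)
        ps = np.array([hypergeom_pvalue(N, K, n, int(q)) for q in qs])
        assert abs((ps < 0.05).mean() - 0.05) < 0.01
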