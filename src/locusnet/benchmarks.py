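"""Property benchmarks: oracle equivalences, planted-truth recovery, and
statistical calibration of the pipeline, computed from scratch on synthetic
cohorts.

Each function here re-runs the relevant pipeline stage against an
independent reference — a brute-force oracle (triple-loop topological
overlap, exhaustive subset enumeration, full SVD), a planted ground truth, or
an analytic null — and returns the measured quantity. The acceptance script
and the acceptance test suite both call these.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import adjusted_rand_score

from .deg import NetworkTargetSets, consensus_degs, map_homologs, validate_enrichment
from .io import GeneSetCollection
from .network import (
    correlation_pvalues,
    detect_modules,
    module_eigengenes,
    signed_adjacency,
    tom,
)
from .preservation import z_summary_pres
from .prioritize import hypergeom_pvalue, prioritize_interval, spearman_to_seed
from .simulate import (
    DEGSpec,
    SimulationConfig,
    plant_disease_sets,
    simulate_cohort,
    simulate_deg_study,
)

# ---------------------------------------------------------------------------
# oracles


def tom_triple_loop(adj: np.ndarray) -> np.ndarray:
    """O(n^3) reference implementation of the topological overlap measure."""
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


def tom_oracle_error(n_matrices: int = 20, size: int = 50, seed: int = 0) -> float:
    """Max elementwise |matrix-product TOM − triple-loop TOM| over random
    signed adjacencies."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        x = rng.standard_normal((size, 2 * size))
        adj = signed_adjacency(np.corrcoef(x), 4)
        worst = max(worst, float(np.abs(tom(adj) - tom_triple_loop(adj)).max()))
    return worst


def hypergeom_enumeration_pvalue(N: int, K: int, n: int, q: int) -> float:
    """Oracle: enumerate every n-subset of an N-universe and count draws
    whose overlap with the first K objects reaches q."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for g in draw if g < K) >= q
    return hits / total


def hypergeom_enumeration_error(seed: int = 0, min_configs: int = 200) -> float:
    """Max |exact upper-tail p − enumeration| over a grid of small
    configurations (N ≤ 25; draw sizes kept small so enumeration stays
    exhaustive yet fast)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    for N in range(10, 26):
        for n in (2, 3, 4):
            for _ in range(5):
                K = int(rng.integers(1, N))
                lo, hi = max(0, n - (N - K)), min(K, n)
                q = int(rng.integers(lo, hi + 1))
                worst = max(
                    worst,
                    abs(hypergeom_pvalue(N, K, n, q) - hypergeom_enumeration_pvalue(N, K, n, q)),
                )
                checked += 1
    assert checked >= min_configs
    return worst


def eigengene_oracle_error(n_modules: int = 20, seed: int = 0) -> float:
    """Max deviation of ME profile, variance explained and kME from a full
    SVD recomputation on random modules."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_modules):
        n_genes = int(rng.integers(10, 60))
        n_samples = int(rng.integers(20, 50))
        expr = pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        partition = pd.Series(1, index=expr.index)
        eig, kme, _ = module_eigengenes(expr, partition)
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        me_ref = Vt[0]
        me = eig.me.loc["M1"].to_numpy()
        if np.dot(me, me_ref) < 0:
            me_ref = -me_ref
        worst = max(worst, float(np.abs(me - me_ref).max()))
        worst = max(worst, abs(eig.prop_var["M1"] - S[0] ** 2 / (S**2).sum()))
        kme_ref = np.array(
            [np.corrcoef(X[i], me_ref)[0, 1] for i in range(n_genes)]
        )
        worst = max(worst, float(np.abs(kme["M1"].to_numpy() - kme_ref).max()))
    return worst


# ---------------------------------------------------------------------------
# planted-truth recovery


def module_recovery(n_sims: int = 10, seed: int = 1) -> dict:
    """Adjusted Rand index of recovered vs planted partitions on the default
    cohort, and the unassigned fraction on pure-noise matrices."""
    aris = []
    for i in range(n_sims):
        ref, _, _, truth = simulate_cohort(SimulationConfig(seed=seed + i))
        net = detect_modules(ref)
        aris.append(adjusted_rand_score(truth.true_partition.values, net.labels_))
    unassigned = []
    rng = np.random.default_rng(seed + 1000)
    for i in range(n_sims):
        noise = pd.DataFrame(
            rng.standard_normal((2000, 100)) + rng.normal(7, 2, (2000, 1)),
            index=[f"N{j}" for j in range(2000)],
        )
        net = detect_modules(noise)
        unassigned.append(float((net.partition_ == 0).mean()))
    return {
        "mean_ari": float(np.mean(aris)),
        "per_seed_ari": aris,
        "noise_unassigned_fraction": float(np.mean(unassigned)),
    }


def preservation_contrast(
    seed: int = 1, n_perm: int = 200, n_scrambled: int = 20, beta: float = 6
) -> dict:
    """Preservation Z for planted modules in the replicate cohort versus the
    same modules against label-scrambled test data."""
    ref, test, _, truth = simulate_cohort(SimulationConfig(seed=seed))
    pres = z_summary_pres(ref, test, truth.true_partition, n_perm=n_perm,
                          seed=seed, beta=beta)
    planted = pres.table["z_summary"]
    scrambled_z: list[float] = []
    rng = np.random.default_rng(seed + 500)
    genes = truth.true_partition.index.to_numpy()
    for i in range(n_scrambled):
        # negative control: the module assignments are scrambled over the
        # genome, so each "module" is a random gene set in both cohorts
        scrambled = pd.Series(
            truth.true_partition.to_numpy(), index=rng.permutation(genes)
        ).reindex(genes)
        res = z_summary_pres(ref, test, scrambled, n_perm=n_perm,
                             seed=seed + i, beta=beta)
        scrambled_z.extend(res.table["z_summary"].tolist())
    return {
        "planted_min_z": float(planted.min()),
        "planted_all_strong": bool((planted > 10).all()),
        "scrambled_frac_below_2": float(np.mean(np.array(scrambled_z) < 2)),
    }


def _planted_panel_sim(sim_seed: int, enrichment: float = 0.5, set_size: int = 40):
    """One prioritization simulation: default cohort, panels planted on the
    highest-loading interval seed of each of the first three modules."""
    cfg = SimulationConfig(seed=sim_seed)
    ref, _, _, truth = simulate_cohort(cfg)
    planted_seeds = []
    for module in (1, 2, 3):
        candidates = [
            g for g in truth.interval_genes
            if truth.true_partition.get(g, 0) == module
        ]
        planted_seeds.append(max(candidates, key=lambda g: truth.true_loadings[g]))
    specs = [(set_size, enrichment, s) for s in planted_seeds for _ in range(2)]
    panels = plant_disease_sets(truth, ref, specs, [set_size] * 4, seed=sim_seed + 1)
    disease = GeneSetCollection(
        sets={k: v for k, v in panels.sets.items() if k.startswith("DISEASE")}
    )
    control = GeneSetCollection(
        sets={k: v for k, v in panels.sets.items() if k.startswith("CONTROL")}
    )
    _, kme, kme_p = module_eigengenes(ref, truth.true_partition)
    result = prioritize_interval(
        ref, truth.true_partition, kme, kme_p, truth.interval_genes, disease, control
    )
    return ref, truth, planted_seeds, result


def prioritization_power(n_sims: int = 20, seed: int = 1) -> dict:
    """Fraction of simulations recovering all three planted seeds, and the
    pooled significant fraction among negative-control tests."""
    hits = 0
    control_sig = control_total = 0
    for i in range(n_sims):
        _, _, planted_seeds, result = _planted_panel_sim(seed + i)
        flagged = set(result["drivers"].prioritized_seeds)
        hits += set(planted_seeds) <= flagged
        control_sig += result["specificity"]["control_significant"]
        control_total += result["specificity"]["control_tests"]
    return {
        "power": hits / n_sims,
        "control_significant_fraction": control_sig / max(control_total, 1),
    }


def deg_validation_power(n_sims: int = 20, seed: int = 1, n_null: int = 100) -> dict:
    """Fraction of DEG-study simulations with significant enrichment at all
    three network scales, plus the false-positive rate per scale for DEG
    lists drawn uniformly at random."""
    successes = 0
    null_sig = null_total = 0
    rng = np.random.default_rng(seed + 99)
    for i in range(n_sims):
        ref, truth, _, result = _planted_panel_sim(seed + i)
        deg_a, deg_b, homology = simulate_deg_study(truth, DEGSpec(), seed=seed + 7000 + i)
        consensus = consensus_degs(deg_a, deg_b)
        mapped = map_homologs(consensus["gene"].tolist(), homology)
        universe = map_homologs(deg_a["gene"].tolist(), homology)
        targets = NetworkTargetSets.from_results(
            truth.true_partition, result["interval_modules"],
            result["neighbor_sets"], result["drivers"],
        )
        table = validate_enrichment(mapped, targets, universe)
        successes += bool((table["p_raw"] < 0.05).all() and len(table) == 3)
        if i == 0:
            # null control: random gene lists of the same size in the same
            # universe against the same targets
            for _ in range(n_null):
                random_degs = list(rng.choice(universe, size=len(mapped), replace=False))
                null_table = validate_enrichment(random_degs, targets, universe)
                null_sig += int((null_table["p_raw"] < 0.05).sum())
                null_total += len(null_table)
    return {
        "success_fraction": successes / n_sims,
        "null_fp_rate": null_sig / max(null_total, 1),
    }


# ---------------------------------------------------------------------------
# statistical calibration


def calibration_ks(seed: int = 0, n_reps: int = 5000) -> dict:
    """Kolmogorov–Smirnov distance from uniformity for kME, Spearman and
    hypergeometric p-values under their nulls."""
    rng = np.random.default_rng(seed)
    me = rng.standard_normal(100)
    genes = rng.standard_normal((n_reps, 100))
    gc = genes - genes.mean(1, keepdims=True)
    mc = me - me.mean()
    r = np.clip(gc @ mc / np.sqrt((gc**2).sum(1) * (mc**2).sum()), -1, 1)
    kme_ks = sstats.kstest(correlation_pvalues(r, 100), "uniform").statistic

    expr = pd.DataFrame(
        rng.standard_normal((min(n_reps, 2500) + 1, 100)),
        index=[f"g{i}" for i in range(min(n_reps, 2500) + 1)],
    )
    _, sp_p = spearman_to_seed(expr, "g0", list(expr.index[1:]))
    spearman_ks = sstats.kstest(sp_p, "uniform").statistic

    N, K, n = 100000, 25000, 10000
    qs = sstats.hypergeom.rvs(N, K, n, size=n_reps, random_state=rng)
    hg_p = np.array([hypergeom_pvalue(N, K, n, int(q)) for q in qs])
    hyper_ks = sstats.kstest(hg_p, "uniform").statistic
    return {
        "kme_p_ks": float(kme_ks),
        "spearman_p_ks": float(spearman_ks),
        "hypergeom_p_ks": float(hyper_ks),
    }
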