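"""Module preservation (reference vs test cohort) and quality (within
reference) via permutation-standardized Z statistics.

For each module, density statistics (mean intramodular signed adjacency,
eigengene variance explained, mean sign-aware kME, mean sign-aware
intramodular correlation) measure how tight the module is in the evaluation
cohort, and connectivity statistics (correlations of intramodular
connectivity, kME and correlation profiles between cohorts) measure whether
the wiring pattern replicates. Observed values are standardized against a
null built by permuting module assignments over the evaluation network's
assigned genes (module sizes fixed): ``Z = (obs − mean_perm)/sd_perm``.
``z_density``/``z_connectivity`` are medians of the component Zs and
``z_summary`` their mean. Thresholds: < 2 no evidence, 2–10 moderate,
> 10 strong (boundaries counted as moderate).

Quality (``z_summary_qual``) applies the same composite to repeated random
half-splits of the reference cohort, averaging the per-split summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UNASSIGNED
from .network import _standardize_rows, signed_adjacency

logger = logging.getLogger(__name__)

DENSITY_STATS = (
    "mean_adj",
    "prop_var_explained",
    "mean_sign_aware_kme",
    "mean_sign_aware_cor",
)
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")


def classify(z: float) -> str:
    """Categorize a Z summary: <2 none, 2–10 moderate, >10 strong."""
    if not np.isfinite(z):
        raise ValueError("z_summary must be finite")
    if z < 2:
        return "none"
    if z <= 10:
        return "moderate"
    return "strong"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _cohort_quantities(values: np.ndarray, beta: float):
    """Correlation matrix, adjacency, kIM, ME-based kME and variance
    explained for one gene set in one cohort."""
    corr = np.corrcoef(values)
    adj = signed_adjacency(corr, beta)
    kim = adj.sum(axis=1) - 1.0
    Xs = _standardize_rows(values)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    me = Vt[0]
    kme = Xs @ (me - me.mean()) / (values.shape[1] * max(me.std(), 1e-12))
    kme = np.clip(kme, -1, 1)
    if kme.mean() < 0:
        kme = -kme
    prop_var = float(S[0] ** 2 / (S**2).sum())
    return corr, adj, kim, kme, prop_var


def stats_for_genes(
    ref_values: np.ndarray, test_values: np.ndarray, beta: float
) -> dict[str, float]:
    """The seven density/connectivity statistics for one gene set evaluated
    in the test cohort against the paired reference."""
    corr_r, adj_r, kim_r, kme_r, _ = _cohort_quantities(ref_values, beta)
    corr_t, adj_t, kim_t, kme_t, pv_t = _cohort_quantities(test_values, beta)
    iu = np.triu_indices_from(corr_t, k=1)
    sign_ref = np.sign(corr_r[iu])
    return {
        "mean_adj": float(adj_t[iu].mean()),
        "prop_var_explained": pv_t,
        "mean_sign_aware_kme": float((np.sign(kme_r) * kme_t).mean()),
        "mean_sign_aware_cor": float((sign_ref * corr_t[iu]).mean()),
        "cor_kim": _pearson(kim_r, kim_t),
        "cor_kme": _pearson(kme_r, kme_t),
        "cor_cor": _pearson(corr_r[iu], corr_t[iu]),
    }


def module_stats(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: pd.Series,
    module: int,
    beta: float = 6,
) -> dict[str, float]:
    """Observed preservation statistics for one module (test vs reference)."""
    genes = [
        g
        for g in partition.index[partition == module]
        if g in ref_expr.index and g in test_expr.index
    ]
    if len(genes) < 3:
        raise ValueError(f"module {module} has fewer than 3 usable genes")
    return stats_for_genes(
        ref_expr.loc[genes].to_numpy(float),
        test_expr.loc[genes].to_numpy(float),
        beta,
    )


@dataclass
class PreservationResult:
    """Per-module composite Z statistics and categorical call."""

    table: pd.DataFrame  # indexed by module

    def category(self, module: int) -> str:
        return str(self.table.loc[module, "category"])


def combine_z(
    density_zs: list[float], connectivity_zs: list[float]
) -> tuple[float, float, float]:
    """Composite: medians of the component Zs, then the mean of the two
    medians — ``(z_density, z_connectivity, z_summary)``."""
    z_density = float(np.median(density_zs))
    z_connectivity = float(np.median(connectivity_zs))
    return z_density, z_connectivity, (z_density + z_connectivity) / 2


def _standardize(
    observed: dict[str, float], null_stats: list[dict[str, float]]
) -> tuple[float, float, float]:
    """Median-of-Z composites from observed stats and their permutation null."""
    z: dict[str, float] = {}
    for name in DENSITY_STATS + CONNECTIVITY_STATS:
        null = np.array([s[name] for s in null_stats], float)
        null = null[np.isfinite(null)]
        if len(null) < 2:
            continue
        sd = null.std(ddof=1)
        if sd == 0:
            logger.warning("permutation sd is 0 for %s; statistic dropped", name)
            continue
        z[name] = (observed[name] - null.mean()) / sd
    return combine_z(
        [z[s] for s in DENSITY_STATS if s in z],
        [z[s] for s in CONNECTIVITY_STATS if s in z],
    )


def _named_modules(partition: pd.Series) -> list[int]:
    return sorted(int(m) for m in partition.unique() if m != UNASSIGNED)


def z_summary_pres(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition: pd.Series,
    n_perm: int = 200,
    max_module_size: int = 1000,
    seed: int = 0,
    beta: float = 6,
) -> PreservationResult:
    """Preservation Z summary per module: observed statistics in the test
    cohort standardized against ``n_perm`` random permutations of the module
    assignments (background excluded, module sizes fixed). Modules larger
    than ``max_module_size`` are subsampled once, seeded.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    rng = np.random.default_rng(seed)
    shared = ref_expr.index.intersection(test_expr.index)
    ref_v = ref_expr.loc[shared].to_numpy(float)
    test_v = test_expr.loc[shared].to_numpy(float)
    pos = {g: i for i, g in enumerate(shared)}

    modules = _named_modules(partition)
    module_idx: dict[int, np.ndarray] = {}
    for m in modules:
        genes = partition.index[partition == m]
        covered = [g for g in genes if g in pos]
        if len(covered) < 0.5 * len(genes):
            raise ValueError(
                f"module {m}: only {len(covered)}/{len(genes)} genes shared "
                "between cohorts (need at least 50%)"
            )
        idx = np.array([pos[g] for g in covered])
        if len(idx) > max_module_size:
            idx = rng.choice(idx, size=max_module_size, replace=False)
        module_idx[m] = idx

    assigned_pool = np.array(
        [pos[g] for g in partition.index[partition != UNASSIGNED] if g in pos]
    )
    rows = []
    observed = {
        m: stats_for_genes(ref_v[idx], test_v[idx], beta)
        for m, idx in module_idx.items()
    }
    null: dict[int, list[dict[str, float]]] = {m: [] for m in modules}
    sizes = [len(module_idx[m]) for m in modules]
    for _ in range(n_perm):
        perm = rng.permutation(assigned_pool)
        offset = 0
        for m, size in zip(modules, sizes):
            idx = perm[offset : offset + size]
            offset += size
            null[m].append(stats_for_genes(ref_v[idx], test_v[idx], beta))
    for m in modules:
        zd, zc, zs = _standardize(observed[m], null[m])
        rows.append(
            {
                "module": m,
                "module_size_used": len(module_idx[m]),
                "z_density": zd,
                "z_connectivity": zc,
                "z_summary": zs,
                "category": classify(zs),
                "n_permutations": n_perm,
            }
        )
    return PreservationResult(pd.DataFrame(rows).set_index("module"))


def z_summary_qual(
    ref_expr: pd.DataFrame,
    partition: pd.Series,
    n_splits: int = 200,
    n_perm_per_split: int = 30,
    seed: int = 0,
    beta: float = 6,
) -> PreservationResult:
    """Quality Z summary: the preservation composite applied to repeated
    random half-splits of the reference cohort (half A as reference, half B
    as test), averaged over splits."""
    if n_splits < 1:
        raise ValueError("n_splits must be positive")
    if ref_expr.shape[1] < 20:
        raise ValueError("quality analysis needs at least 20 samples")
    rng = np.random.default_rng(seed)
    modules = _named_modules(partition)
    values = ref_expr.to_numpy(float)
    pos = {g: i for i, g in enumerate(ref_expr.index)}
    module_idx = {
        m: np.array([pos[g] for g in partition.index[partition == m] if g in pos])
        for m in modules
    }
    assigned_pool = np.concatenate(list(module_idx.values()))
    n_samples = ref_expr.shape[1]
    half = n_samples // 2
    sums = {m: [] for m in modules}
    for _ in range(n_splits):
        order = rng.permutation(n_samples)
        a, b = order[:half], order[half:]
        va, vb = values[:, a], values[:, b]
        observed = {
            m: stats_for_genes(va[idx], vb[idx], beta) for m, idx in module_idx.items()
        }
        null: dict[int, list[dict[str, float]]] = {m: [] for m in modules}
        for _ in range(n_perm_per_split):
            perm = rng.permutation(assigned_pool)
            offset = 0
            for m in modules:
                size = len(module_idx[m])
                idx = perm[offset : offset + size]
                offset += size
                null[m].append(stats_for_genes(va[idx], vb[idx], beta))
        for m in modules:
            sums[m].append(_standardize(observed[m], null[m]))
    rows = []
    for m in modules:
        zd = float(np.mean([t[0] for t in sums[m]]))
        zc = float(np.mean([t[1] for t in sums[m]]))
        zs = float(np.mean([t[2] for t in sums[m]]))
        rows.append(
            {
                "module": m,
                "module_size_used": len(module_idx[m]),
                "z_density": zd,
                "z_connectivity": zc,
                "z_summary": zs,
                "category": classify(zs),
                "n_permutations": n_splits * n_perm_per_split,
            }
        )
    return PreservationResult(pd.DataFrame(rows).set_index("module"))
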