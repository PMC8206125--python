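"""Guilt-by-association driver prioritization for a genomic interval.

Stages: locate the modules harboring interval genes, call interval hubs
(own-module kME > 0.8 with significant p; low-connectivity genes are excluded
from seeding), extract each eligible seed's intramodular *top neighbors*
(Spearman ρ ≥ 0.5, p < 0.05), screen neighbor sets for hypergeometric overlap
with disease gene-set panels against matched negative-control panels
(Benjamini–Hochberg corrected within each family), and assemble the
prioritized driver set: seeds with at least one significant disease overlap
plus their disease-associated top neighbors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import UNASSIGNED, GeneSetCollection
from .network import correlation_pvalues

logger = logging.getLogger(__name__)


def interval_modules(
    partition: pd.Series, interval_genes: list[str]
) -> dict[int, list[str]]:
    """Map each module containing at least one interval gene to the interval
    genes it harbors. Unassigned placements are excluded; interval genes
    absent from the partition are logged, not fatal."""
    out: dict[int, list[str]] = {}
    missing = []
    for g in interval_genes:
        if g not in partition.index:
            missing.append(g)
            continue
        m = int(partition[g])
        if m == UNASSIGNED:
            continue
        out.setdefault(m, []).append(g)
    if missing:
        logger.info("interval genes absent from partition: %s", missing)
    if not out:
        raise ValueError("no interval gene is assigned to any module")
    return dict(sorted(out.items()))


def call_hubs(
    kme: pd.DataFrame,
    kme_p: pd.DataFrame,
    partition: pd.Series,
    interval_genes: list[str],
    kme_cut: float = 0.8,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Interval hub genes (own-module kME > cut, p < alpha) and the
    low-connectivity genes (p ≥ alpha) flagged for downstream exclusion."""
    hubs, excluded = [], []
    for g in interval_genes:
        if g not in partition.index or partition[g] == UNASSIGNED:
            continue
        col = f"M{int(partition[g])}"
        r, p = float(kme.loc[g, col]), float(kme_p.loc[g, col])
        if p >= alpha:
            excluded.append(g)
        elif r > kme_cut:
            hubs.append(g)
    return hubs, excluded


@dataclass
class TopNeighborSet:
    """Intramodular top neighbors of one seed gene."""

    seed: str
    module: int
    members: pd.DataFrame  # columns gene, rho, pvalue

    @property
    def genes(self) -> list[str]:
        return self.members["gene"].tolist()

    def __len__(self) -> int:
        return len(self.members)


def spearman_to_seed(
    expr: pd.DataFrame, seed: str, others: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman ρ (midranks, then Pearson) of a seed against other genes,
    with two-sided p from the t approximation."""
    n = expr.shape[1]
    ranks = stats.rankdata(expr.loc[[seed] + others].to_numpy(float), axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = 1.0
    ranks /= norms[:, None]
    rho = np.clip(ranks[1:] @ ranks[0], -1, 1)
    return rho, correlation_pvalues(rho, n)


def top_neighbors(
    expr: pd.DataFrame,
    partition: pd.Series,
    seed: str,
    rho_cut: float = 0.5,
    alpha: float = 0.05,
) -> TopNeighborSet:
    """Top neighbors of a seed: genes in the seed's module with Spearman
    ρ ≥ ``rho_cut`` and p < ``alpha`` to the seed."""
    if seed not in partition.index or partition[seed] == UNASSIGNED:
        raise ValueError(f"seed {seed!r} is not assigned to a module")
    module = int(partition[seed])
    others = [g for g in partition.index[partition == module] if g != seed and g in expr.index]
    rho, p = spearman_to_seed(expr, seed, others)
    keep = (rho >= rho_cut) & (p < alpha)
    members = pd.DataFrame(
        {"gene": np.array(others)[keep], "rho": rho[keep], "pvalue": p[keep]}
    ).sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)
    return TopNeighborSet(seed=seed, module=module, members=members)


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    from scipy.special import gammaln

    return float(
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_pvalue(N: int, K: int, n: int, q: int, exact_limit: int = 2000) -> float:
    """Upper-tail hypergeometric p: ``P(X ≥ q)`` for X ~ Hypergeom(N, K, n).

    Exact integer arithmetic (``math.comb``) up to ``exact_limit`` objects;
    beyond that, a numerically stable pmf recurrence summed on the shorter
    tail (relative truncation 1e-16, far below any decision threshold).
    """
    if q > min(K, n):
        raise ValueError("overlap exceeds margin sizes")
    lo = max(0, n - (N - K))
    if q <= lo:
        return 1.0
    if N <= exact_limit:
        denom = math.comb(N, n)
        num = sum(
            math.comb(K, k) * math.comb(N - K, n - k) for k in range(q, min(K, n) + 1)
        )
        return num / denom if denom else 1.0
    hi = min(K, n)
    mean = n * K / N
    if q > mean:
        # sum the upper tail upward from q
        t = math.exp(_log_hypergeom_pmf(q, N, K, n))
        s, k = t, q
        while k < hi:
            t *= (K - k) * (n - k) / ((k + 1) * (N - K - n + k + 1))
            s += t
            k += 1
            if t <= s * 1e-16:
                break
        return min(s, 1.0)
    # complement: 1 − P(X ≤ q−1), summed downward from q−1
    t = math.exp(_log_hypergeom_pmf(q - 1, N, K, n))
    s, k = t, q - 1
    while k > lo:
        t *= k * (N - K - n + k) / ((K - k + 1) * (n - k + 1))
        s += t
        k -= 1
        if t <= s * 1e-16:
            break
    return max(1.0 - s, 0.0)


def hypergeom_overlap(
    neighbors: list[str],
    gene_set: list[str],
    universe: list[str],
) -> dict:
    """Exact upper-tail hypergeometric overlap test.

    Both margins are intersected with the universe first. With N = |universe|,
    K = |set ∩ universe|, n = |neighbors ∩ universe| and q the overlap,
    ``p = Σ_{k=q}^{min(K,n)} C(K,k)·C(N−K,n−k)/C(N,n)``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    nb = set(neighbors) & uni
    gs = set(gene_set) & uni
    N, K, n_draw, q = len(uni), len(gs), len(nb), len(nb & gs)
    return {
        "overlap_count": q,
        "universe_size": N,
        "set_size_in_universe": K,
        "neighbors_in_universe": n_draw,
        "p_raw": hypergeom_pvalue(N, K, n_draw, q),
        "overlap_genes": sorted(nb & gs),
    }


def bh_adjust(p_values: list[float], families: list | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, applied within each family."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    fam = np.zeros(len(p)) if families is None else np.asarray(families)
    for f in pd.unique(fam):
        mask = fam == f
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def enrichment_screen(
    neighbor_sets: list[TopNeighborSet],
    disease_panels: GeneSetCollection,
    control_panels: GeneSetCollection,
    universe: list[str],
    alpha_adj: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """All seed × set hypergeometric tests, BH-corrected within the disease
    family and the control family separately; plus a specificity summary
    (significant fraction in each family)."""
    if not any(len(s) for s in neighbor_sets):
        raise ValueError("no seed has a non-empty top-neighbor set")
    rows = []
    for ns in neighbor_sets:
        if len(ns) == 0:
            logger.info("seed %s has no top neighbors; tests skipped", ns.seed)
            continue
        for family, panels in (("disease", disease_panels), ("control", control_panels)):
            for set_name, members in panels.sets.items():
                res = hypergeom_overlap(ns.genes, members, universe)
                rows.append(
                    {"seed": ns.seed, "gene_set": set_name, "family": family, **res}
                )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_raw"].tolist(), table["family"].tolist())
    table["significant"] = table["p_adjusted"] < alpha_adj
    summary = {}
    for family in ("disease", "control"):
        sub = table[table["family"] == family]
        summary[f"{family}_significant"] = int(sub["significant"].sum())
        summary[f"{family}_tests"] = int(len(sub))
        summary[f"{family}_fraction"] = (
            float(sub["significant"].mean()) if len(sub) else np.nan
        )
    return table, summary


@dataclass
class DriverSet:
    """Prioritized interval seeds plus their disease-associated top
    neighbors, with per-gene provenance (which seed/set pair contributed)."""

    prioritized_seeds: list[str]
    partner_drivers: list[str]
    hub_seeds: list[str] = field(default_factory=list)
    provenance: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.prioritized_seeds) | set(self.partner_drivers))

    def __len__(self) -> int:
        return len(self.genes)


def assemble_drivers(
    screen: pd.DataFrame,
    neighbor_sets: list[TopNeighborSet],
    hub_seeds: list[str] | None = None,
) -> DriverSet:
    """Build the driver set from significant disease-family overlap tests:
    the significant seeds plus, for each significant (seed, set) pair, the
    seed's top neighbors that belong to that set."""
    if len(screen) == 0:
        return DriverSet([], [], hub_seeds or [])
    sig = screen[(screen["family"] == "disease") & screen["significant"]]
    sig = sig.sort_values(["seed", "gene_set"], kind="stable")
    neighbors_by_seed = {ns.seed: set(ns.genes) for ns in neighbor_sets}
    seeds = sorted(sig["seed"].unique())
    prov_rows = []
    partners: set[str] = set()
    for _, row in sig.iterrows():
        overlap = set(row["overlap_genes"]) & neighbors_by_seed[row["seed"]]
        partners |= overlap
        for g in sorted(overlap):
            prov_rows.append(
                {"gene": g, "role": "partner", "seed": row["seed"], "gene_set": row["gene_set"]}
            )
    for s in seeds:
        prov_rows.append({"gene": s, "role": "seed", "seed": s, "gene_set": ""})
    provenance = pd.DataFrame(prov_rows).sort_values(
        ["role", "gene", "seed"], kind="stable"
    ).reset_index(drop=True) if prov_rows else None
    return DriverSet(
        prioritized_seeds=seeds,
        partner_drivers=sorted(partners),
        hub_seeds=sorted(set(hub_seeds or []) & set(seeds)),
        provenance=provenance,
    )


def prioritize_interval(
    expr: pd.DataFrame,
    partition: pd.Series,
    kme: pd.DataFrame,
    kme_p: pd.DataFrame,
    interval_genes: list[str],
    disease_panels: GeneSetCollection,
    control_panels: GeneSetCollection,
    universe: list[str] | None = None,
    rho_cut: float = 0.5,
    alpha: float = 0.05,
    alpha_adj: float = 0.05,
    kme_cut: float = 0.8,
) -> dict:
    """Full prioritization stage. Returns a dict with the interval-module
    map, hub calls, per-seed neighbor sets, the screen table, the specificity
    summary and the assembled DriverSet.

    Seeds flagged as low-connectivity (own-module kME p ≥ alpha) are excluded
    before neighbor extraction; seeds with empty neighbor sets are retained
    but untested. The default universe is the whole post-filter network.
    """
    imods = interval_modules(partition, interval_genes)
    hubs, excluded = call_hubs(kme, kme_p, partition, interval_genes, kme_cut, alpha)
    eligible = [
        g
        for g in interval_genes
        if g in partition.index and partition[g] != UNASSIGNED and g not in excluded
    ]
    neighbor_sets = [
        top_neighbors(expr, partition, seed, rho_cut, alpha) for seed in eligible
    ]
    if universe is None:
        universe = expr.index.tolist()
    screen, summary = enrichment_screen(
        neighbor_sets, disease_panels, control_panels, universe, alpha_adj
    )
    drivers = assemble_drivers(screen, neighbor_sets, hub_seeds=hubs)
    return {
        "interval_modules": imods,
        "hub_seeds": hubs,
        "excluded_low_kme": excluded,
        "neighbor_sets": neighbor_sets,
        "screen": screen,
        "specificity": summary,
        "drivers": drivers,
    }
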