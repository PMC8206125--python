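"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* modular expression — gene *i* in module *q* is ``x_i = r_i·ME_q +
  sqrt(1 − r_i²)·ε_i`` with a standard-normal module eigengene ``ME_q`` and
  standard-normal noise, so the population correlation of two co-members is
  ``r_i·r_j`` and the gene–eigengene correlation is ``r_i``;
* a background of pure-noise genes (``r_i = 0``);
* one planted hub per module (loading pinned to the top of the loading range);
* interval genes distributed across modules with one background placement;
* nuisance covariates (sex, age, batch; death classification and postmortem
  interval are carried but effect-free) added as exactly linear offsets, so
  OLS residualization can remove them completely;
* a replicate cohort sharing memberships and loadings but with freshly drawn
  eigengenes and noise (shared structure, independent samples);
* disease gene-set panels enriched in a seed gene's true co-member
  neighborhood, next to size-matched random control panels;
* a two-group negative-binomial DEG study with dosage effects planted on
  interval genes and a fraction of their module partners, analysed by two
  genuinely different tests to make a consensus rule meaningful.

All randomness flows through one ``numpy.random.default_rng`` (PCG64) seed;
fixed seed means bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, HomologyTable, UNASSIGNED


def _default_module_sizes() -> list[int]:
    return [400, 300, 200, 150, 100]


def default_interval_placement(
    n_interval_genes: int, n_modules: int
) -> dict[str, int | str]:
    """Distribute interval genes round-robin over the modules, with the last
    gene placed in the unassigned background."""
    placement: dict[str, int | str] = {
        f"INT{i:02d}": (i - 1) % n_modules + 1 for i in range(1, n_interval_genes)
    }
    placement[f"INT{n_interval_genes:02d}"] = "background"
    return placement


@dataclass
class DEGSpec:
    """Two-group count study design for the proof-of-concept stage."""

    n_per_group: int = 5
    dispersion: float = 0.05
    lfc_on_interval: float = -1.0
    partner_fraction: float = 0.3
    lfc_on_partners: float = -0.8
    homology_coverage: float = 0.95


@dataclass
class SimulationConfig:
    """Desk-scale default: 2,000 genes, five modules, 850 background genes,
    100 reference and 30 test samples, loadings U(0.5, 0.9)."""

    n_genes: int = 2000
    n_samples_ref: int = 100
    n_samples_test: int = 30
    module_sizes: list[int] = field(default_factory=_default_module_sizes)
    loading_range: tuple[float, float] = (0.5, 0.9)
    baseline_mean: float = 7.0  # per-gene log2 abundance baseline
    baseline_sd: float = 2.0
    background_fraction: float | None = None  # derived from the sizes if None
    n_interval_genes: int = 21
    interval_placement: dict[str, int | str] | None = None
    covariate_effect_size: float = 0.0
    disease_set_specs: list[tuple[int, float, str]] = field(default_factory=list)
    control_set_specs: list[int] = field(default_factory=list)
    deg_spec: DEGSpec = field(default_factory=DEGSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed total gene count")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("loading_range must lie within [0, 1]")
        for size, frac, _ in self.disease_set_specs:
            if not 0 <= frac <= 1:
                raise ValueError("enrichment_fraction must lie in [0, 1]")
        n_modules = len(self.module_sizes)
        if self.interval_placement is None:
            self.interval_placement = default_interval_placement(
                self.n_interval_genes, n_modules
            )
        for gene, where in self.interval_placement.items():
            if where != "background" and not (1 <= int(where) <= n_modules):
                raise ValueError(
                    f"interval gene {gene!r} placed in module {where}, but only "
                    f"{n_modules} modules exist"
                )

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recoverable answer key for every stage."""

    true_partition: pd.Series
    true_loadings: pd.Series
    true_eigengenes_ref: pd.DataFrame
    true_eigengenes_test: pd.DataFrame
    interval_genes: list[str]
    planted_disease_members: dict[str, list[str]] = field(default_factory=dict)
    deg_truth: pd.Series | None = None

    def module_members(self, module: int) -> list[str]:
        return self.true_partition.index[self.true_partition == module].tolist()


def _gene_names(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Gene ids and true module labels (0 = background), interval genes
    substituted into their placed slots."""
    labels = np.zeros(config.n_genes, dtype=int)
    names: list[str] = []
    pos = 0
    for q, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = q
        names.extend(f"G{q}_{j:04d}" for j in range(size))
        pos += size
    names.extend(f"BG_{j:04d}" for j in range(config.n_genes - pos))

    # substitute interval genes into their placed slots (never the hub slot 0,
    # so the planted per-module hub keeps its pinned loading)
    next_slot = {q: 1 for q in range(1, len(config.module_sizes) + 1)}
    bg_slot = 0
    starts = np.concatenate([[0], np.cumsum(config.module_sizes)])
    for gene, where in config.interval_placement.items():
        if where == "background":
            idx = pos + bg_slot
            bg_slot += 1
        else:
            q = int(where)
            idx = starts[q - 1] + next_slot[q]
            if next_slot[q] >= config.module_sizes[q - 1]:
                raise ValueError(f"module {q} too small for its interval genes")
            next_slot[q] += 1
        names[idx] = gene
    return names, labels


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate reference and test cohorts plus covariates and ground truth.

    Returns ``(ref, test, covariates, truth)`` where the expression frames are
    genes × samples and the covariate table is indexed by reference-cohort
    sample id (the test cohort is covariate-free by construction).
    """
    rng = np.random.default_rng(config.seed)
    names, labels = _gene_names(config)
    n_modules = len(config.module_sizes)

    lo, hi = config.loading_range
    loadings = np.zeros(config.n_genes)
    in_module = labels > 0
    loadings[in_module] = rng.uniform(lo, hi, size=int(in_module.sum()))
    starts = np.concatenate([[0], np.cumsum(config.module_sizes)])
    for q in range(1, n_modules + 1):
        loadings[starts[q - 1]] = hi  # planted hub

    # per-gene log2 baseline: shared by both cohorts, gives the sample
    # network the mean-structure real expression data has
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(
        config.n_genes
    )

    def _draw(n_samples: int, prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        me = rng.standard_normal((n_modules, n_samples))
        me = (me - me.mean(axis=1, keepdims=True)) / me.std(axis=1, keepdims=True)
        eps = rng.standard_normal((config.n_genes, n_samples))
        x = np.where(
            in_module[:, None],
            loadings[:, None] * me[np.maximum(labels - 1, 0)]
            + np.sqrt(1 - loadings[:, None] ** 2) * eps,
            eps,
        ) + baseline[:, None]
        samples = [f"{prefix}{j:03d}" for j in range(n_samples)]
        expr = pd.DataFrame(x, index=names, columns=samples)
        me_df = pd.DataFrame(
            me, index=[f"M{q}" for q in range(1, n_modules + 1)], columns=samples
        )
        return expr, me_df

    ref, me_ref = _draw(config.n_samples_ref, "REF")
    test, me_test = _draw(config.n_samples_test, "TST")

    cov = _covariate_table(rng, ref.columns)
    if config.covariate_effect_size > 0:
        design = np.column_stack(
            [
                cov["sex"].to_numpy(float),
                (cov["age"] - cov["age"].mean()).to_numpy(float) / cov["age"].std(),
                (cov["batch"] == "B2").to_numpy(float),
            ]
        )
        coef = rng.standard_normal((config.n_genes, design.shape[1]))
        ref.loc[:, :] = ref.to_numpy() + config.covariate_effect_size * coef @ design.T

    truth = SyntheticTruth(
        true_partition=pd.Series(labels, index=names, name="module"),
        true_loadings=pd.Series(loadings, index=names, name="loading"),
        true_eigengenes_ref=me_ref,
        true_eigengenes_test=me_test,
        interval_genes=list(config.interval_placement),
    )
    return ref, test, cov, truth


def _covariate_table(rng: np.random.Generator, samples: Sequence[str]) -> pd.DataFrame:
    n = len(samples)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(20, 79, size=n).round(1),
            "death_class": rng.integers(0, 5, size=n),
            "pmi": rng.uniform(200, 1200, size=n).round(0),
            "batch": np.where(rng.random(n) < 0.5, "B1", "B2"),
        },
        index=list(samples),
    )


def true_neighborhood(
    truth: SyntheticTruth, seed_gene: str, rho_cut: float = 0.5
) -> list[str]:
    """A seed's true top-neighbor pool: co-members whose population
    correlation with the seed (``r_seed·r_g``) clears the neighbor cut."""
    module = int(truth.true_partition[seed_gene])
    if module == UNASSIGNED:
        raise ValueError(f"seed {seed_gene!r} is a background gene")
    r_seed = float(truth.true_loadings[seed_gene])
    members = truth.module_members(module)
    return [
        g
        for g in members
        if g != seed_gene and r_seed * float(truth.true_loadings[g]) >= rho_cut
    ]


def plant_disease_sets(
    truth: SyntheticTruth,
    expr: pd.DataFrame,
    specs: Sequence[tuple[int, float, str]],
    control_specs: Sequence[int],
    seed: int,
    rho_cut: float = 0.5,
) -> GeneSetCollection:
    """Build disease panels enriched in seed neighborhoods plus random
    control panels.

    Each disease spec is ``(size, enrichment_fraction, target_seed)``: a
    fraction of members is drawn uniformly from the seed's true top-neighbor
    pool, the rest uniformly from all other genes. Control sets are uniform
    draws. No set contains its target seed.
    """
    rng = np.random.default_rng(seed)
    all_genes = expr.index.to_numpy()
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for k, (size, frac, target) in enumerate(specs, start=1):
        pool = true_neighborhood(truth, target, rho_cut=rho_cut)
        n_enriched = int(round(size * frac))
        if n_enriched > len(pool):
            raise ValueError(
                f"disease set {k}: requested {n_enriched} enriched members but the "
                f"neighborhood of {target!r} has only {len(pool)} genes"
            )
        planted = list(rng.choice(pool, size=n_enriched, replace=False))
        rest_pool = np.array(
            [g for g in all_genes if g not in set(planted) and g != target]
        )
        rest = list(rng.choice(rest_pool, size=size - n_enriched, replace=False))
        name = f"DISEASE{k}_{target}"
        sets[name] = planted + rest
        provenance[name] = f"planted enrichment {frac} on {target}"
        truth.planted_disease_members[name] = planted
    for k, size in enumerate(control_specs, start=1):
        name = f"CONTROL{k}"
        sets[name] = list(rng.choice(all_genes, size=size, replace=False))
        provenance[name] = "uniform random control"
    return GeneSetCollection(sets=sets, universe=list(all_genes), provenance=provenance)


def _welch_log_test(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    la, lb = np.log2(counts_a + 1.0), np.log2(counts_b + 1.0)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    lfc = lb.mean(axis=1) - la.mean(axis=1)
    return lfc, np.nan_to_num(p, nan=1.0)


def _nb_wald_test(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched negative-binomial Wald test on the log mean ratio."""
    na, nb = counts_a.shape[1], counts_b.shape[1]
    ma = counts_a.mean(axis=1) + 0.5
    mb = counts_b.mean(axis=1) + 0.5
    va = counts_a.var(axis=1, ddof=1)
    vb = counts_b.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion, floored at Poisson
    phi = ((va - ma) / ma**2 + (vb - mb) / mb**2) / 2
    phi = np.clip(phi, 1e-8, None)
    var_log_a = (1 / ma + phi) / na
    var_log_b = (1 / mb + phi) / nb
    z = (np.log(mb) - np.log(ma)) / np.sqrt(var_log_a + var_log_b)
    # t reference with 2(n-1) df: the plug-in variance is estimated from few
    # samples, a normal reference is anticonservative at this design size
    p = 2 * stats.t.sf(np.abs(z), df=na + nb - 2)
    lfc = np.log2(mb / ma)
    return lfc, p


def simulate_deg_study(
    truth: SyntheticTruth,
    deg_spec: DEGSpec,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, HomologyTable]:
    """Two-group NB count study with planted dosage effects.

    Interval genes get ``lfc_on_interval`` (−1 by default: halved dosage); a
    random ``partner_fraction`` of each interval gene's true module co-members
    get ``lfc_on_partners``. Two DEG tables come from two distinct tests
    (Welch t on log2 counts; moment-matched NB Wald), and a homology table
    covers a random ``homology_coverage`` subset of genes. DEG tables are
    keyed in the source-species ("m:" prefixed) namespace.
    """
    if deg_spec.n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    if deg_spec.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = truth.true_partition.index.to_numpy()
    n_genes = len(genes)

    lfc_true = pd.Series(0.0, index=genes, name="log2fc_true")
    lfc_true[truth.interval_genes] = deg_spec.lfc_on_interval
    partner_pool: set[str] = set()
    for g in truth.interval_genes:
        module = int(truth.true_partition[g])
        if module == UNASSIGNED:
            continue
        members = [m for m in truth.module_members(module) if m != g]
        n_pick = int(round(deg_spec.partner_fraction * len(members)))
        partner_pool.update(rng.choice(members, size=n_pick, replace=False))
    partner_pool -= set(truth.interval_genes)
    lfc_true[list(partner_pool)] = deg_spec.lfc_on_partners
    truth.deg_truth = lfc_true

    base = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n_genes)
    mu_wt = base
    mu_mut = base * 2.0 ** lfc_true.to_numpy()
    r = 1.0 / deg_spec.dispersion

    def _nb(mu: np.ndarray, n_samples: int) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(
            r, p[:, None], size=(n_genes, n_samples)
        ).astype(float)

    counts_wt = _nb(mu_wt, deg_spec.n_per_group)
    counts_mut = _nb(mu_mut, deg_spec.n_per_group)

    mouse = np.array([f"m:{g}" for g in genes])
    lfc_a, p_a = _welch_log_test(counts_wt, counts_mut)
    lfc_b, p_b = _nb_wald_test(counts_wt, counts_mut)
    table_a = pd.DataFrame(
        {"gene": mouse, "log2fc": lfc_a, "pvalue": p_a, "method": "welch_log"}
    )
    table_b = pd.DataFrame(
        {"gene": mouse, "log2fc": lfc_b, "pvalue": p_b, "method": "nb_wald"}
    )

    covered = rng.random(n_genes) < deg_spec.homology_coverage
    homology = HomologyTable(
        pairs=[(m, g) for m, g, c in zip(mouse, genes, covered) if c]
    )
    return table_a, table_b, homology
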