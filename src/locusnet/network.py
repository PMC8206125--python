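"""Signed weighted co-expression network construction and module detection.

Primitives: biweight midcorrelation, signed soft-threshold adjacency
``a_ij = ((1 + cor_ij)/2)^β``, scale-free-topology power scan, topological
overlap (TOM), average-linkage clustering with a dynamic hybrid tree cut,
module eigengenes / kME, eigengene-based module merging and meta-modules.

The clustering core is exposed as :class:`CoexpressionNetwork`, a
scikit-learn-style estimator (``fit`` on a samples × genes matrix; fitted
attributes ``labels_``, ``eigengenes_``, ``kme_``, ``power_``, ...).

Three correlation contracts coexist deliberately: network similarity uses
bicor (robust), kME uses Pearson, and top-neighbor screening (in
``locusnet.prioritize``) uses Spearman.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import UNASSIGNED
from .treecut import cut_tree_hybrid

logger = logging.getLogger(__name__)

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


# ---------------------------------------------------------------------------
# correlation and adjacency


def _bicor_prepare(X: np.ndarray, max_p_outliers: float = 1.0) -> np.ndarray:
    """Row-wise robust standardization for bicor: median-center, Tukey
    biweight, unit norm. Rows with zero MAD fall back to Pearson weighting."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()
    if fallback.any():
        warnings.warn(
            f"bicor: {int(fallback.sum())} rows have zero MAD; using Pearson "
            "weights for those rows"
        )
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (X - med) / (9.0 * safe_mad)
    if max_p_outliers < 1.0:
        qlo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        qhi = np.quantile(u, 1 - max_p_outliers, axis=1, keepdims=True)
        u = np.where(u < 0, u / np.maximum(1.0, -qlo), u / np.maximum(1.0, qhi))
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    xt = (X - med) * w
    if fallback.any():
        xt[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    norms = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    if (norms == 0).any():
        raise ValueError("bicor undefined for constant rows")
    return xt / norms


def bicor_matrix(X: np.ndarray | pd.DataFrame, max_p_outliers: float = 1.0) -> np.ndarray:
    """All-pairs biweight midcorrelation of the rows of ``X`` (rows are
    variables, columns observations)."""
    values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if values.shape[1] < 4:
        raise ValueError("bicor needs at least 4 observations")
    xt = _bicor_prepare(values, max_p_outliers)
    corr = xt @ xt.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def bicor(x: np.ndarray, y: np.ndarray, max_p_outliers: float = 1.0) -> float:
    """Biweight midcorrelation of two equal-length vectors."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("bicor needs two equal-length vectors of length >= 4")
    return float(bicor_matrix(np.vstack([x, y]), max_p_outliers)[0, 1])


def signed_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency ``((1 + cor)/2)^β`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr = np.asarray(corr, float)
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlations outside [-1, 1]")
    adj = ((1 + np.clip(corr, -1, 1)) / 2) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


# ---------------------------------------------------------------------------
# scale-free topology


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R² of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; log10 mean
    frequency is regressed on log10 mean connectivity per bin. Returns
    ``(signed_r2, slope)`` with ``signed_r2 = -sign(slope)·R²``.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if len(k) < n_bins or np.isclose(k.max(), k.min()):
        return np.nan, np.nan
    # equal-width bins on k itself (the convention of the reference tool's
    # scale-free fit index)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] = k.max() + 1e-12
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return np.nan, np.nan
    res = stats.linregress(xs, ys)
    return float(-np.sign(res.slope) * res.rvalue**2), float(res.slope)


def sft_scan(
    expr: pd.DataFrame,
    powers: tuple[int, ...] = DEFAULT_POWERS,
    n_bins: int = 10,
    max_p_outliers: float = 1.0,
    corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan candidate soft-threshold powers; one row per power with the
    signed scale-free fit index and connectivity summaries."""
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    if corr is None:
        corr = bicor_matrix(expr, max_p_outliers)
    rows = []
    for beta in powers:
        adj = signed_adjacency(corr, beta)
        k = adj.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k, n_bins)
        rows.append(
            {
                "power": beta,
                "signed_r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
                "min_k": float(k.min()),
            }
        )
    return pd.DataFrame(rows).set_index("power")


def pick_power(
    sft: pd.DataFrame,
    target_r2: float = 0.8,
    slope_range: tuple[float, float] = (-4.0, -0.3),
    plateau_drop: float = 0.05,
    tie_tol: float = 0.02,
    min_k_span: float = 0.3,
) -> int:
    """Select the soft-threshold power from a scan table.

    Primary rule: the lowest power whose signed fit index reaches the target.
    Two practitioner safeguards qualify a power as a *candidate* first:

    * the log-log slope must be an interpretable scale-free exponent
      (``slope_range``), and connectivity must span at least ``min_k_span``
      decades; near-constant connectivities produce wild slopes whose R² is
      meaningless;
    * once the fit curve has formed a genuine plateau (running maximum ≥ 0.5)
      and then fallen more than ``plateau_drop`` below it, later powers are
      discarded — a late re-rise of the index at extreme powers is an
      artifact of a handful of dominant nodes, not scale-free topology.

    If no candidate reaches the target, the lowest candidate within
    ``tie_tol`` of the best fit is returned with a warning (parsimony, as in
    the lowest-power doctrine). With no interpretable candidate at all (for
    example featureless data), the maximum scanned power is returned for
    maximal contrast, with a warning.
    """
    r2 = sft["signed_r2"].to_numpy(float)
    slope = sft["slope"].to_numpy(float)
    finite = np.isfinite(r2) & np.isfinite(slope)
    keep = finite.copy()
    running = -np.inf
    for i in range(len(r2)):
        if not finite[i]:
            continue
        if running >= 0.5 and running - r2[i] > plateau_drop:
            keep[i:] = False
            break
        running = max(running, r2[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        k_span = np.log10(
            sft["max_k"].to_numpy(float) / np.maximum(sft["min_k"].to_numpy(float), 1e-300)
        )
    eligible = (
        keep
        & (slope >= slope_range[0])
        & (slope <= slope_range[1])
        & (k_span >= min_k_span)
    )
    powers = sft.index.to_numpy()
    ok = powers[eligible & (r2 >= target_r2)]
    if len(ok):
        return int(ok[0])
    if eligible.any():
        best = r2[eligible].max()
        near = powers[eligible & (r2 >= best - tie_tol)]
        choice = int(near[0])
        warnings.warn(
            f"no candidate power reached signed R² {target_r2}; using best "
            f"interpretable fit (power={choice}, R²={sft.loc[choice, 'signed_r2']:.3f})"
        )
        return choice
    choice = int(powers[finite].max()) if finite.any() else int(powers.max())
    warnings.warn(
        "no power produced an interpretable scale-free fit; falling back to "
        f"the maximum scanned power ({choice}) for maximal contrast"
    )
    return choice


# ---------------------------------------------------------------------------
# topological overlap


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix via matrix products.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` with
    ``l_ij = Σ_u a_iu·a_uj`` over ``u ≠ i, j`` and ``k_i`` the off-diagonal
    row sum; unit diagonal.
    """
    adj = np.asarray(adj, float)
    a0 = adj.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    assert (denom > 0).all(), "TOM denominator must stay positive"
    out = (l + a0) / denom
    np.fill_diagonal(out, 1.0)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    d = 1.0 - tom(adj)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# clustering and eigengenes


def cluster_and_cut(
    dtom: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage dendrogram + dynamic hybrid cut.

    Returns the scipy linkage matrix and a gene → module-label Series
    (0 = unassigned; labels ordered by decreasing module size).
    """
    dtom = np.asarray(dtom, float)
    condensed = squareform(dtom, checks=False)
    Z = average(condensed)
    labels = cut_tree_hybrid(
        Z,
        dtom,
        min_cluster_size=min_module_size,
        deep_split=deep_split,
        cut_height=cut_height,
        pam_stage=pam_stage,
        pam_respects_dendro=pam_respects_dendro,
    )
    return Z, pd.Series(labels, index=gene_ids, name="module")


@dataclass
class EigengeneSet:
    """Module eigengenes (first principal components; unit norm, sign-aligned
    so member genes correlate positively on average) and the proportion of
    module variance each explains."""

    me: pd.DataFrame  # modules × samples, index "M<label>"
    prop_var: pd.Series

    @property
    def modules(self) -> list[int]:
        return [int(name[1:]) for name in self.me.index]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return Xc / sd


def _corr_with_profiles(expr_values: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation of each expression row with each profile row."""
    xs = _standardize_rows(expr_values)
    ps = _standardize_rows(profiles)
    n = expr_values.shape[1]
    return np.clip(xs @ ps.T / n, -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation via ``t = r·sqrt((n−2)/(1−r²))``."""
    r = np.clip(np.asarray(r, float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def module_eigengenes(
    expr: pd.DataFrame, partition: pd.Series
) -> tuple[EigengeneSet, pd.DataFrame, pd.DataFrame]:
    """Eigengenes plus the full gene × module kME table.

    Returns ``(EigengeneSet, kme_r, kme_p)``. Each module's eigengene is the
    first right-singular vector of its standardized member rows; the sign is
    flipped so the mean member correlation is non-negative. kME is the Pearson
    correlation of every gene with every eigengene.
    """
    modules = sorted(int(m) for m in partition.unique() if m != UNASSIGNED)
    if not modules:
        raise ValueError("partition has no named modules")
    n = expr.shape[1]
    me_rows, pv = [], []
    values = expr.to_numpy(float)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    for m in modules:
        members = [gene_pos[g] for g in partition.index[partition == m] if g in gene_pos]
        Xs = _standardize_rows(values[members])
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        me = Vt[0]
        if _corr_with_profiles(Xs, me[None, :]).mean() < 0:
            me = -me
        me_rows.append(me)
        pv.append(float(S[0] ** 2 / (S**2).sum()))
    me_df = pd.DataFrame(
        me_rows, index=[f"M{m}" for m in modules], columns=expr.columns
    )
    prop_var = pd.Series(pv, index=me_df.index, name="prop_var_explained")
    kme_r = pd.DataFrame(
        _corr_with_profiles(values, me_df.to_numpy()),
        index=expr.index,
        columns=me_df.index,
    )
    kme_p = pd.DataFrame(
        correlation_pvalues(kme_r.to_numpy(), n), index=expr.index, columns=me_df.index
    )
    return EigengeneSet(me=me_df, prop_var=prop_var), kme_r, kme_p


def _relabel_by_size(partition: pd.Series) -> pd.Series:
    sizes = partition[partition != UNASSIGNED].value_counts()
    order = sizes.sort_values(ascending=False).index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return partition.map(mapping)


def merge_close_modules(
    expr: pd.DataFrame,
    partition: pd.Series,
    merge_cut_height: float = 0.2,
    max_iterations: int = 10,
) -> tuple[pd.Series, EigengeneSet]:
    """Amalgamate modules whose eigengenes are strongly correlated.

    Average-linkage clustering of eigengenes on ``1 − cor(ME)``; branches
    below the cut height merge; eigengenes are recomputed and the procedure
    iterates until no eigengene pair exceeds r = 0.8 (the height-0.2
    equivalent) or the iteration cap. The unassigned label never merges.
    """
    partition = partition.copy()
    eigengenes, _, _ = module_eigengenes(expr, partition)
    for _ in range(max_iterations):
        modules = eigengenes.modules
        if len(modules) < 2:
            break
        corr = np.corrcoef(eigengenes.me.to_numpy())
        off = corr[np.triu_indices_from(corr, k=1)]
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        Z = average(squareform(dist, checks=False))
        groups = fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            if off.max() <= 0.8:
                break
            # no branch under the height but a pair still exceeds r=0.8:
            # merge the closest pair directly
            i, j = np.unravel_index(
                np.argmax(corr - np.eye(len(corr))), corr.shape
            )
            groups = np.arange(1, len(modules) + 1)
            groups[j] = groups[i]
        remap = {}
        for m, g in zip(modules, groups):
            remap[m] = min(mm for mm, gg in zip(modules, groups) if gg == g)
        partition = partition.map(lambda m: remap.get(m, m))
        partition = _relabel_by_size(partition)
        eigengenes, _, _ = module_eigengenes(expr, partition)
    return partition, eigengenes


def meta_modules(eigengenes: EigengeneSet, cut_height: float = 0.5) -> dict[int, int]:
    """Group modules into meta-modules: branches of the eigengene dendrogram
    (average linkage on ``1 − cor(ME)``) below the cut height."""
    modules = eigengenes.modules
    if len(modules) < 2:
        raise ValueError("meta-modules need at least 2 modules")
    corr = np.corrcoef(eigengenes.me.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    groups = fcluster(Z, t=cut_height, criterion="distance")
    return {m: int(g) for m, g in zip(modules, groups)}


# ---------------------------------------------------------------------------
# estimator


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Signed weighted co-expression network with dynamic hybrid modules.

    Scikit-learn-style feature clusterer: ``fit(X)`` takes a samples × genes
    matrix (DataFrame preferred, so gene ids are kept) and clusters the
    *genes*. The pipeline is bicor → signed soft-threshold adjacency (power
    chosen by scale-free-topology scan unless fixed) → TOM → average-linkage
    dendrogram → dynamic hybrid cut → eigengenes → merge of close modules →
    kME and meta-modules.

    Parameters
    ----------
    power:
        Soft-threshold exponent β. ``None`` selects the lowest candidate
        whose signed scale-free fit reaches ``sft_target_r2``.
    min_module_size, deep_split, pam_stage, pam_respects_dendro, cut_height:
        Dynamic hybrid cut controls.
    merge_cut_height:
        Eigengene-dissimilarity height below which modules amalgamate (0.2,
        i.e. r > 0.8).
    meta_module_cut_height:
        Eigengene-dendrogram height defining meta-modules.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
        Module label per gene; 0 is the reserved unassigned label.
    partition_ : pandas.Series
        ``labels_`` indexed by gene id.
    power_, sft_ : selected β and the power-scan table.
    eigengenes_ : EigengeneSet
    kme_, kme_p_ : gene × module Pearson kME and two-sided p-values.
    meta_modules_ : module → meta-module map.
    linkage_ : scipy linkage matrix of the gene dendrogram.
    """

    def __init__(
        self,
        power: int | None = None,
        powers: tuple[int, ...] = DEFAULT_POWERS,
        sft_target_r2: float = 0.8,
        min_module_size: int = 30,
        deep_split: int = 2,
        cut_height: float | None = None,
        pam_stage: bool = True,
        pam_respects_dendro: bool = True,
        merge_cut_height: float = 0.2,
        meta_module_cut_height: float = 0.5,
        bicor_max_p_outliers: float = 1.0,
        store_tom: bool = False,
    ):
        self.power = power
        self.powers = powers
        self.sft_target_r2 = sft_target_r2
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.cut_height = cut_height
        self.pam_stage = pam_stage
        self.pam_respects_dendro = pam_respects_dendro
        self.merge_cut_height = merge_cut_height
        self.meta_module_cut_height = meta_module_cut_height
        self.bicor_max_p_outliers = bicor_max_p_outliers
        self.store_tom = store_tom

    def fit(self, X, y=None) -> "CoexpressionNetwork":
        if isinstance(X, pd.DataFrame):
            expr = X.T  # genes × samples
        else:
            X = np.asarray(X, float)
            expr = pd.DataFrame(
                X.T, index=[f"g{i}" for i in range(X.shape[1])]
            )
        self.feature_names_in_ = np.asarray(expr.index)
        self.n_features_in_ = expr.shape[0]

        corr = bicor_matrix(expr, self.bicor_max_p_outliers)
        self.sft_ = sft_scan(expr, self.powers, corr=corr)
        self.power_ = (
            int(self.power) if self.power is not None
            else pick_power(self.sft_, self.sft_target_r2)
        )
        adj = signed_adjacency(corr, self.power_)
        del corr
        tom_matrix = tom(adj)
        del adj
        if self.store_tom:
            self.tom_ = tom_matrix
        dtom = 1.0 - tom_matrix
        np.fill_diagonal(dtom, 0.0)
        del tom_matrix
        self.linkage_, partition = cluster_and_cut(
            dtom,
            expr.index,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            cut_height=self.cut_height,
            pam_stage=self.pam_stage,
            pam_respects_dendro=self.pam_respects_dendro,
        )
        del dtom
        self.pre_merge_partition_ = partition
        if (partition != UNASSIGNED).any():
            partition, eigengenes = merge_close_modules(
                expr, partition, self.merge_cut_height
            )
            eigengenes, kme_r, kme_p = module_eigengenes(expr, partition)
            self.eigengenes_ = eigengenes
            self.kme_ = kme_r
            self.kme_p_ = kme_p
            self.meta_modules_ = (
                meta_modules(eigengenes, self.meta_module_cut_height)
                if len(eigengenes.modules) >= 2
                else {m: 1 for m in eigengenes.modules}
            )
        else:
            self.eigengenes_ = None
            self.kme_ = None
            self.kme_p_ = None
            self.meta_modules_ = {}
        self.partition_ = partition
        self.labels_ = partition.to_numpy()
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def detect_modules(expr: pd.DataFrame, **params) -> CoexpressionNetwork:
    """Functional wrapper: fit a :class:`CoexpressionNetwork` on a genes ×
    samples expression frame."""
    return CoexpressionNetwork(**params).fit(expr.T)
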