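"""Raw expression matrix → analysis-ready residualized matrix.

Steps: missingness/zero-variance filtering, sample-network outlier removal,
and OLS residualization against nuisance covariates (sex, age, death
classification, postmortem interval, batch). Input is assumed already
normalized and log2-transformed; no count-level normalization happens here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ("age", "pmi")
CATEGORICAL_COVARIATES = ("sex", "death_class", "batch")


def filter_genes_samples(
    expr: pd.DataFrame, max_missing_fraction: float = 0.5
) -> pd.DataFrame:
    """Remove genes, then samples, with more than ``max_missing_fraction``
    missing entries (iterated to a fixed point), then zero-variance genes.

    The removal report (counts per step) is attached as
    ``result.attrs["filter_report"]`` and logged.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    out = expr
    report: list[dict] = []
    while True:
        gene_missing = out.isna().mean(axis=1)
        bad_genes = gene_missing > max_missing_fraction
        out = out.loc[~bad_genes]
        sample_missing = out.isna().mean(axis=0)
        bad_samples = sample_missing > max_missing_fraction
        out = out.loc[:, ~bad_samples]
        report.append(
            {"genes_removed": int(bad_genes.sum()), "samples_removed": int(bad_samples.sum())}
        )
        if not bad_genes.any() and not bad_samples.any():
            break
    variances = out.var(axis=1, ddof=1)
    zero_var = variances.isna() | (variances == 0)
    out = out.loc[~zero_var]
    report.append({"zero_variance_genes_removed": int(zero_var.sum())})
    if out.shape[0] == 0:
        raise ValueError("filtering removed every gene")
    out = out.copy()
    out.attrs["filter_report"] = report
    logger.info("filter report: %s", report)
    return out


def impute_gene_mean(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace remaining missing entries with the gene's observed mean."""
    if not expr.isna().any().any():
        return expr
    values = expr.to_numpy(float)
    means = np.nanmean(values, axis=1)
    idx = np.where(np.isnan(values))
    values[idx] = means[idx[0]]
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)


def detect_outlier_samples(expr: pd.DataFrame, z_cut: float = -2.5) -> list[str]:
    """Flag samples whose standardized sample-network connectivity Z.k falls
    below ``z_cut``.

    The sample network uses adjacency ``((1 + cor)/2)²`` on the sample–sample
    Pearson correlation; connectivity is the off-diagonal row sum. One pass,
    no iteration.
    """
    if expr.shape[1] < 10:
        raise ValueError("sample-outlier detection needs at least 10 samples")
    corr = np.corrcoef(expr.to_numpy(float).T)
    adj = ((1 + corr) / 2) ** 2
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    z = (k - k.mean()) / k.std(ddof=1)
    return [s for s, zi in zip(expr.columns, z) if zi < z_cut]


def build_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Covariate design matrix: intercept, centered continuous columns,
    one-hot categoricals with the reference level dropped.

    Death classification (Hardy scale) is treated as unordered categorical.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cov))}
    for name in cov.columns:
        series = cov[name]
        if name in CONTINUOUS_COVARIATES:
            vals = series.astype(float)
            cols[name] = (vals - vals.mean()).to_numpy()
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols[f"{name}[{level}]"] = (series.astype(str) == level).to_numpy(float)
    return pd.DataFrame(cols, index=cov.index)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify offending columns by greedy removal
    collinear = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            collinear.append(design.columns[j])
    raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")


def residualize(expr: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """Per-gene OLS on the covariate design; returns residuals plus the
    per-gene grand mean (so the output keeps the original location).

    Residuals (after re-centering) are exactly orthogonal to every design
    column, and the operation is idempotent.
    """
    missing = [s for s in expr.columns if s not in cov.index]
    if missing:
        raise ValueError(f"covariate rows missing for samples: {missing[:5]}")
    if expr.isna().any().any():
        raise ValueError("residualize requires a complete matrix; impute or filter first")
    cov = cov.loc[expr.columns]
    design = build_design(cov)
    _check_full_rank(design)
    X = design.to_numpy(float)
    Y = expr.to_numpy(float).T  # samples × genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    grand_mean = expr.to_numpy(float).mean(axis=1)
    out = resid.T + grand_mean[:, None]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def preprocess(
    expr: pd.DataFrame,
    cov: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.5,
    z_cut: float = -2.5,
    remove_outliers: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full preprocessing chain: filter → (outlier removal) → residualize.

    Outliers are removed before residualization by default. Returns the
    analysis-ready matrix and a JSON-serializable log.
    """
    log: dict = {}
    out = filter_genes_samples(expr, max_missing_fraction)
    log["filter"] = out.attrs["filter_report"]
    out = impute_gene_mean(out)
    if remove_outliers and out.shape[1] >= 10:
        outliers = detect_outlier_samples(out, z_cut=z_cut)
        log["outlier_samples"] = outliers
        out = out.drop(columns=outliers)
    if cov is not None:
        out = residualize(out, cov)
        log["design_columns"] = list(build_design(cov.loc[out.columns]).columns)
    # residualization can zero out genes that were pure covariate signal
    variances = out.var(axis=1, ddof=1)
    out = out.loc[variances > 0]
    return out, log


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer view of :func:`residualize`.

    ``X`` is samples × genes; the covariate table (indexed like ``X``) is
    given at construction. ``transform`` projects out the covariate design
    fitted on the training samples.
    """

    def __init__(self, covariates: pd.DataFrame | None = None):
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None) -> "CovariateResidualizer":
        if self.covariates is None:
            raise ValueError("covariates table is required")
        design = build_design(self.covariates.loc[X.index])
        _check_full_rank(design)
        self.design_columns_ = list(design.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return residualize(X.T, self.covariates).T
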