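"""Descriptive spatial analysis of the concentration landscape.

Per-metabolite z-scoring, hierarchical clustering of sites into the
stomach / small-intestine / large-intestine compartments, principal
component analysis over all samples, and smoothed longitudinal profiles
with peak-region assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .quantify import ConcentrationMatrix

__all__ = [
    "ZScoreNormalizer",
    "zscore",
    "site_means",
    "cluster_sites",
    "pca",
    "SpatialProfile",
    "spatial_profile",
    "peak_region",
    "moving_average",
]


class ZScoreNormalizer(BaseEstimator, TransformerMixin):
    """Row-wise z-scoring transformer (features = rows, metabolite-wise).

    Uses the sample standard deviation (ddof=1).  Constant rows are
    emitted as all-zero with a warning; NaN entries are ignored in the
    statistics and propagated.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = np.nanmean(X, axis=1, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.scale_ = np.nanstd(X, axis=1, ddof=self.ddof, keepdims=True)
        self.constant_rows_ = (self.scale_ == 0).ravel() | np.isnan(self.scale_).ravel()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        out = (X - self.mean_) / scale
        out[self.constant_rows_, :] = np.where(
            np.isnan(X[self.constant_rows_, :]), np.nan, 0.0
        )
        return out


def zscore(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-metabolite (row) z-transform; masked (NaN) values stay NaN."""
    n_valid = values.notna().sum(axis=1)
    if (n_valid < 2).any():
        bad = values.index[n_valid < 2].tolist()
        raise ValueError(f"rows with <2 non-masked values: {bad[:5]}")
    norm = ZScoreNormalizer(ddof=ddof).fit(values.to_numpy())
    if norm.constant_rows_.any():
        warnings.warn(
            f"{int(norm.constant_rows_.sum())} constant row(s) emitted as zeros",
            stacklevel=2,
        )
    return pd.DataFrame(
        norm.transform(values.to_numpy()), index=values.index, columns=values.columns
    )


def site_means(matrix: ConcentrationMatrix, habitat: str = "lumen") -> pd.DataFrame:
    """Metabolite x site mean over mice for one habitat (sites ordered)."""
    sub = matrix.select(habitat=habitat)
    key = sub.samples["site_index"]
    means = sub.values.T.groupby(key.values).mean().T
    return means[sorted(means.columns)]


def cluster_sites(
    normalized: pd.DataFrame,
    k: int = 3,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[pd.Series, list]:
    """Agglomerative clustering of site columns; also orders the rows.

    Returns (site labels 1..k, metabolite dendrogram leaf order).  With
    the planted three-compartment structure and modest noise, cutting at
    k=3 recovers stomach / small intestine / large intestine.
    """
    if k < 1 or k > normalized.shape[1]:
        raise ValueError("k must be between 1 and the number of sites")
    if normalized.isna().all(axis=1).any():
        raise ValueError("fully-masked rows are not clusterable")
    cols = normalized.fillna(0.0).to_numpy().T
    Z = hierarchy.linkage(pdist(cols, metric=metric), method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    rows = normalized.fillna(0.0).to_numpy()
    if rows.shape[0] > 1:
        Zr = hierarchy.linkage(pdist(rows, metric=metric), method=method)
        leaf_order = [normalized.index[i] for i in hierarchy.leaves_list(Zr)]
    else:
        leaf_order = list(normalized.index)
    return pd.Series(labels, index=normalized.columns, name="cluster"), leaf_order


def pca(
    normalized: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA over samples (columns) of a metabolite x sample matrix.

    Missing values are mean-imputed per metabolite before the
    decomposition (their fraction is reported via a warning above 10%).
    Returns (scores: samples x PCs, loadings: metabolites x PCs,
    explained variance fractions).
    """
    if normalized.shape[0] < 2 or normalized.shape[1] < 2:
        raise ValueError("need at least 2 metabolites and 2 samples")
    X = normalized.to_numpy(dtype=float)
    nan_frac = float(np.isnan(X).mean())
    if nan_frac > 0:
        row_means = np.nanmean(X, axis=1, keepdims=True)
        row_means = np.where(np.isnan(row_means), 0.0, row_means)
        X = np.where(np.isnan(X), row_means, X)
        if nan_frac > 0.10:
            warnings.warn(f"{nan_frac:.1%} of values imputed before PCA", stacklevel=2)
    data = X.T  # samples x metabolites
    max_rank = min(data.shape[0] - 1, data.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = PCA(n_components=k)
    scores = model.fit_transform(data)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=normalized.columns, columns=pcs),
        pd.DataFrame(model.components_.T, index=normalized.index, columns=pcs),
        model.explained_variance_ratio_,
    )


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking windows at the boundaries.

    NaNs are ignored within each window; an all-NaN window yields NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        win = values[lo:hi]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanmean(win)
    return out


@dataclass
class SpatialProfile:
    """Longitudinal profile of one metabolite over the ordered sites."""

    metabolite: str
    habitat: str
    colonization: str
    site_index: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    smoothed: np.ndarray
    regions: list[str]


def spatial_profile(
    matrix: ConcentrationMatrix,
    metabolite: str,
    habitat: str,
    colonization: str | None = None,
    window: int = 3,
) -> SpatialProfile:
    """Per-site mean and s.e.m. over mice plus a moving average."""
    if metabolite not in matrix.metabolites:
        raise KeyError(metabolite)
    criteria = {"habitat": habitat}
    if colonization is not None:
        criteria["colonization"] = colonization
    sub = matrix.select(**criteria)
    sites = sorted(sub.samples["site_index"].unique())
    means, sems, regions = [], [], []
    row = sub.values.loc[metabolite]
    for s in sites:
        ids = sub.samples.index[sub.samples["site_index"] == s]
        vals = row[ids].dropna()
        means.append(vals.mean() if len(vals) else np.nan)
        sems.append(vals.sem() if len(vals) > 1 else (0.0 if len(vals) else np.nan))
        regions.append(sub.samples.loc[ids[0], "region"])
    mean = np.asarray(means)
    return SpatialProfile(
        metabolite=metabolite,
        habitat=habitat,
        colonization=colonization or "all",
        site_index=np.asarray(sites),
        mean=mean,
        sem=np.asarray(sems),
        smoothed=moving_average(mean, window),
        regions=regions,
    )


def peak_region(profile: SpatialProfile, regions: list[str] | None = None) -> str | None:
    """Region containing the site of maximal unsmoothed mean.

    Ties go to the most proximal (oral) site.  ``regions`` optionally
    restricts the candidate sites.  Returns None for all-masked
    profiles.
    """
    mean = profile.mean.copy()
    if regions is not None:
        keep = np.array([r in regions for r in profile.regions])
        if not keep.any():
            raise ValueError("region set does not cover any profile site")
        mean = np.where(keep, mean, np.nan)
    if np.all(np.isnan(mean)):
        return None
    idx = int(np.nanargmax(mean))  # first occurrence = most proximal
    return profile.regions[idx]
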