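"""Feature standardization, PCA, band relevance, and electrode clustering.

The six normalized band powers of the retained electrodes are z-scored and
projected onto the principal components that jointly explain at least 95%
of the variance.  Electrodes are then grouped by hierarchical agglomerative
clustering (Ward linkage, the primary method), with the number of clusters
selected in 3-12 by the silhouette score; k-means (same sweep) and HDBSCAN
are available as robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN, AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .signal_io import PipelineConfig
from .spectral_features import BandPowerMatrix

__all__ = [
    "FeatureSpace",
    "ClusterResult",
    "standardize_and_pca",
    "band_relevance",
    "cluster_electrodes",
]


@dataclass
class FeatureSpace:
    """PCA-reduced spectral features of the retained electrodes."""

    scores: np.ndarray          # retained electrodes x k_retained
    loadings: np.ndarray        # bands x k_retained
    evr: np.ndarray             # explained-variance ratio, k_retained
    evr_all: np.ndarray         # explained-variance ratio of every component
    k_retained: int
    band_names: list
    retained_index: np.ndarray  # row indices into the BandPowerMatrix
    n_electrodes_total: int


@dataclass
class ClusterResult:
    """Cluster labels per electrode; -1 marks excluded electrodes."""

    labels: np.ndarray
    n_clusters: int
    silhouette: float
    silhouette_by_k: pd.DataFrame
    method: str


def standardize_and_pca(bp: BandPowerMatrix, cfg: PipelineConfig) -> FeatureSpace:
    """Z-score the band features over retained electrodes, then PCA.

    The number of retained components is the smallest k whose cumulative
    explained variance reaches ``cfg.pca_var``.  Zero-variance feature
    columns are dropped with a warning.
    """
    retained = bp.retained()
    if retained.size < 2:
        raise ValueError("need at least 2 retained electrodes for PCA")
    X = bp.values[retained]
    band_names = list(bp.band_names)
    variances = X.var(axis=0)
    if np.any(variances == 0):
        dead = [band_names[j] for j in np.flatnonzero(variances == 0)]
        warnings.warn(f"dropping zero-variance band feature(s): {dead}")
        keep = variances > 0
        X = X[:, keep]
        band_names = [b for b, k in zip(band_names, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("all band features have zero variance")
    Xs = StandardScaler().fit_transform(X)
    pca = PCA()
    scores = pca.fit_transform(Xs)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), cfg.pca_var) + 1)
    k = min(k, evr.size)
    return FeatureSpace(
        scores=scores[:, :k],
        loadings=pca.components_[:k].T,
        evr=evr[:k],
        evr_all=evr,
        k_retained=k,
        band_names=band_names,
        retained_index=retained,
        n_electrodes_total=bp.n_electrodes,
    )


def band_relevance(fs: FeatureSpace) -> pd.Series:
    """Contribution of each band to the reduced space.

    Sum over retained components of |loading| weighted by the component's
    explained-variance ratio.
    """
    rel = np.abs(fs.loadings) @ fs.evr
    return pd.Series(rel, index=fs.band_names, name="relevance")


def _fit_k(scores: np.ndarray, k: int, method: str, random_state: int) -> np.ndarray:
    if method == "hierarchical":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(scores)
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(scores)
    raise ValueError(f"unknown clustering method {method!r}")


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters as 0..k-1 in order of first appearance; noise stays -1."""
    out = np.full(labels.shape, -1, dtype=int)
    nxt = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in seen:
            seen[lab] = nxt
            nxt += 1
        out[i] = seen[lab]
    return out


def cluster_electrodes(
    fs: FeatureSpace, cfg: PipelineConfig, method: str = "hierarchical"
) -> ClusterResult:
    """Cluster retained electrodes in PCA space.

    For ``hierarchical`` and ``kmeans`` every k in ``cfg.k_range`` is fit
    and the solution with the highest silhouette score is returned (ties go
    to the smaller k).  ``hdbscan`` returns its native solution with noise
    points mapped to -1.  Labels are reported for every electrode of the
    band-power matrix; excluded electrodes receive -1.
    """
    scores = fs.scores
    n = scores.shape[0]
    if np.allclose(scores, scores[0]):
        raise ValueError("all retained electrodes are identical; silhouette undefined")

    if method == "hdbscan":
        min_size = max(5, int(round(0.02 * n)))
        raw = HDBSCAN(min_cluster_size=min_size).fit_predict(scores)
        raw = _contiguous(raw)
        k_found = int(raw.max() + 1)
        clustered = raw >= 0
        if k_found >= 2 and np.unique(raw[clustered]).size >= 2:
            sil = float(silhouette_score(scores[clustered], raw[clustered]))
        else:
            sil = float("nan")
        table = pd.DataFrame({"k": [k_found], "silhouette": [sil]})
        best_labels, best_sil = raw, sil
        n_clusters = k_found
    else:
        kmin, kmax = cfg.k_range
        if n < kmax + 1:
            raise ValueError(
                f"{n} retained electrodes too few for a k sweep up to {kmax}"
            )
        rows = []
        best_labels, best_sil, n_clusters = None, -np.inf, 0
        for k in range(kmin, kmax + 1):
            labels = _fit_k(scores, k, method, cfg.random_state)
            sil = float(silhouette_score(scores, labels))
            rows.append({"k": k, "silhouette": sil})
            if sil > best_sil:  # strict: ties keep the smaller k
                best_labels, best_sil, n_clusters = labels, sil, k
        table = pd.DataFrame(rows)
        best_labels = _contiguous(best_labels)

    full = np.full(fs.n_electrodes_total, -1, dtype=int)
    full[fs.retained_index] = best_labels
    return ClusterResult(
        labels=full,
        n_clusters=n_clusters,
        silhouette=float(best_sil),
        silhouette_by_k=table,
        method=method,
    )
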