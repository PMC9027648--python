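"""Unsupervised structure: hierarchical clustering and PCA outlier flagging.

Clustering groups features (rows) by Euclidean distance with complete
linkage; the cluster count is chosen at the elbow of the within-cluster
sum-of-squares curve, and the full curve is returned so the choice is
auditable.  PCA embeds samples (columns) and flags outliers by Hotelling's
T² on the leading scores against the small-sample F-distribution limit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .iokit import OmicsMatrix


@dataclass
class ClusteringResult:
    linkage: np.ndarray                 # scipy linkage matrix
    k: int
    assignments: dict[str, int]         # feature -> cluster label (1..k)
    wss_curve: dict[int, float]         # candidate k -> within-cluster SS


@dataclass
class PCAResult:
    scores: pd.DataFrame                # samples x components
    loadings: pd.DataFrame              # features x components
    explained_variance: np.ndarray
    t2: pd.Series                       # Hotelling T² per sample
    t2_limit: float
    outliers: set[str]
    ellipse_alpha: float


def _wss(mat: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = mat[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def elbow_k(wss_curve: dict[int, float]) -> int:
    """Elbow as the argmax of the second difference of the log-WSS curve.

    The log scale locates where the curve *flattens* (the raw-scale second
    difference is dominated by the first split of any decaying curve and
    degenerates to k = 2).  A k whose WSS is numerically zero is a perfect
    partition and returned directly; with fewer than 3 candidate points
    there is no curvature to measure and the smallest k is returned.
    """
    ks = sorted(wss_curve)
    w = np.array([wss_curve[k] for k in ks], dtype=float)
    if np.allclose(w, 0.0):
        return ks[0]
    tiny = w.max() * 1e-12
    perfect = np.nonzero(w <= tiny)[0]
    if perfect.size:
        return ks[int(perfect[0])]
    if len(ks) < 3:
        return ks[0]
    lw = np.log(w)
    d2 = lw[:-2] - 2 * lw[1:-1] + lw[2:]
    return ks[int(np.argmax(d2)) + 1]


def hcluster_elbow(matrix: OmicsMatrix, k_max: int = 12) -> ClusteringResult:
    """Complete-linkage Euclidean clustering of features with elbow-chosen k."""
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("clustering input may not contain missing values "
                         "(filter or impute upstream)")
    n = len(vals)
    if n < 3:
        raise ValueError("need at least 3 features to cluster")
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be smaller than the feature "
                         f"count ({n})")
    mat = vals.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(mat, metric="euclidean"), method="complete")
    wss_curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        wss_curve[k] = _wss(mat, labels)
    k = elbow_k(wss_curve)
    return ClusteringResult(
        linkage=Z,
        k=k,
        assignments=dict(zip(vals.index, map(int, labels_by_k[k]))),
        wss_curve=wss_curve,
    )


def hotelling_t2_limit(n: int, p: int, alpha: float = 0.05) -> float:
    """(1 - alpha) control limit for Hotelling's T² on p PCA scores of n samples.

    T²_crit = p(n-1)/(n-p) * F(1-alpha; p, n-p).
    """
    if n <= p:
        raise ValueError("need more samples than score dimensions")
    return p * (n - 1) / (n - p) * stats.f.ppf(1 - alpha, p, n - p)


def pca_hotelling(
    matrix: OmicsMatrix,
    n_components: int = 2,
    alpha: float = 0.05,
    scale: bool = False,
) -> PCAResult:
    """PCA of sample profiles with Hotelling-ellipse outlier flagging.

    Samples (columns) are the observations; features are centered (and
    optionally unit-variance scaled).  A sample is an outlier when its T²
    over the first ``n_components`` scores exceeds the F-based limit.
    """
    vals = matrix.values.dropna(axis=0, how="any")
    X = vals.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not np.any(X):
        raise ValueError("zero-variance matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    explained = s**2 / (n - 1)
    k = n_components
    lam = explained[:k]
    if np.any(lam <= 0):
        raise ValueError("requested components exceed matrix rank")
    t2 = np.sum(scores[:, :k] ** 2 / lam, axis=1)
    limit = hotelling_t2_limit(n, k, alpha)
    sample_ids = list(vals.columns)
    t2_series = pd.Series(t2, index=sample_ids, name="t2")
    return PCAResult(
        scores=pd.DataFrame(scores[:, :k], index=sample_ids,
                            columns=[f"PC{i+1}" for i in range(k)]),
        loadings=pd.DataFrame(Vt[:k].T, index=vals.index,
                              columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance=explained,
        t2=t2_series,
        t2_limit=float(limit),
        outliers=set(t2_series.index[t2_series > limit]),
        ellipse_alpha=alpha,
    )
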