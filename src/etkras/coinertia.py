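"""Cross-omics concordance by two-table co-inertia analysis.

Transcript and protein matrices are cross-referenced by feature ID and
reduced to one paired profile per condition (the RNA library, and the
replicate-averaged protein profile).  Because the matched tables share one
feature space, co-inertia here finds common feature-space axes that
maximize the covariance between the two tables' sample scores — the
eigenvectors of the symmetrized cross-product of the preprocessed tables,
whose eigenvalues are the pseudo-eigenvalues (the covariance achieved per
axis).  Two summaries quantify agreement:

* the RV coefficient, a matrix-level correlation in [0, 1] between the
  two tables' feature-configuration cross-products.  The feature-space
  form is used because with far more features than samples the
  sample-space Gram matrices of *any* two tables converge to the centering
  projector, driving that form of RV to 1 even for independent noise; the
  feature-space form stays near 0 there and is 1 exactly when the
  cross-product structures are proportional.
* a per-sample dissimilarity: each assay's score vector for a sample
  (over the retained axes) is normalized to unit length and the Euclidean
  distance between the pair is taken — the analogue of the length of the
  line joining an RNA point to its protein point on a co-inertia plot.
  Normalizing per sample rather than per axis makes the line length
  measure *directional* disagreement of the condition's response, so a
  condition whose transcript and protein profiles move coordinately gets
  a short line regardless of response magnitude.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import normalize_counts
from .iokit import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class MatchedTables:
    """Feature-aligned condition-level profiles of the two assays.

    ``rna_sub`` and ``protein_sub`` are features x conditions log2-scale
    DataFrames with identical row and column order and no missing values.
    """

    shared_features: list[str]
    rna_sub: pd.DataFrame
    protein_sub: pd.DataFrame
    n_rna_only: int
    n_protein_only: int


@dataclass
class CoinertiaResult:
    reference_scores: pd.DataFrame        # samples x axes (mean of both assays)
    rna_scores: pd.DataFrame
    protein_scores: pd.DataFrame
    pseudo_eigenvalues: np.ndarray
    sample_dissimilarity: pd.Series
    rv: float


def _dedup_by_mean(df: pd.DataFrame, label: str) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    kept = df.iloc[order]
    kept = kept[~kept.index.duplicated(keep="first")]
    logger.info("%s: %d duplicate feature IDs collapsed to highest-mean row",
                label, df.index.duplicated().sum())
    return kept


def match_features(
    rna: OmicsMatrix,
    protein: OmicsMatrix,
    id_map: Mapping[str, str] | None = None,
) -> MatchedTables:
    """Cross-reference transcripts and proteins into paired condition profiles.

    ``id_map`` translates protein IDs into the transcript namespace when
    the two differ.  Duplicates after mapping keep the highest-mean row.
    RNA profiles are log2(median-of-ratios-normalized counts + pseudocount)
    averaged over libraries per condition; protein profiles are log2 ratios
    averaged over replicates.  Features with any missing protein value are
    dropped so the matched tables are complete.
    """
    prot_vals = np.log2(protein.values)
    if id_map is not None:
        prot_vals = prot_vals.rename(index=dict(id_map))
    prot_vals = _dedup_by_mean(prot_vals, "protein")
    rna_norm = np.log2(normalize_counts(rna))
    rna_norm = _dedup_by_mean(rna_norm, "rna")

    shared = sorted(set(rna_norm.index) & set(prot_vals.index))
    if not shared:
        raise ValueError("no features shared between the two assays")
    conds = [c for c in rna.conditions if c in protein.conditions]
    if not conds:
        raise ValueError("no conditions shared between the two assays")

    rna_sub = pd.concat(
        [rna_norm.loc[shared, rna.columns_for(c)].mean(axis=1).rename(c)
         for c in conds], axis=1
    )
    prot_sub = pd.concat(
        [prot_vals.loc[shared, protein.columns_for(c)].mean(axis=1).rename(c)
         for c in conds], axis=1
    )
    complete = prot_sub.notna().all(axis=1) & rna_sub.notna().all(axis=1)
    rna_sub, prot_sub = rna_sub[complete], prot_sub[complete]
    logger.info("match_features: %d shared features (%d complete), "
                "%d rna-only, %d protein-only",
                len(shared), int(complete.sum()),
                len(rna_norm.index) - len(shared),
                len(prot_vals.index) - len(shared))
    return MatchedTables(
        shared_features=list(rna_sub.index),
        rna_sub=rna_sub,
        protein_sub=prot_sub,
        n_rna_only=len(rna_norm.index) - len(shared),
        n_protein_only=len(prot_vals.index) - len(shared),
    )


def _preprocess(X: np.ndarray, mode: str) -> np.ndarray:
    X = X - X.mean(axis=0)
    if mode == "center":
        return X
    if mode == "center_scale":
        sd = X.std(axis=0, ddof=1)
        return X / np.where(sd > 0, sd, 1.0)
    if mode == "total_variance":
        total = np.sqrt((X**2).sum())
        if total == 0:
            raise ValueError("zero-variance table")
        return X / total
    raise ValueError(f"unknown preprocessing {mode!r}")


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV = <X'X, Y'Y> / (||X'X|| ||Y'Y||), a matrix correlation in [0, 1].

    ``X`` and ``Y`` are samples x features with matched rows.  The
    feature-configuration cross-products X'X are compared, so the
    coefficient is ~0 for independent tables even when features vastly
    outnumber samples, and 1 exactly when the cross-product structures are
    proportional.  Computed via the identities tr(X'X Y'Y) = ||XY'||_F^2
    and tr((X'X)^2) = ||XX'||_F^2, so cost scales with the sample count.
    """
    num = float(np.linalg.norm(X @ Y.T, "fro") ** 2)
    den = float(np.linalg.norm(X @ X.T, "fro") * np.linalg.norm(Y @ Y.T, "fro"))
    if den == 0:
        raise ValueError("degenerate (zero-variance) table")
    return num / den


def coinertia_fit(
    tables: MatchedTables,
    n_axes: int = 2,
    preprocessing: str = "total_variance",
) -> CoinertiaResult:
    """Two-table co-inertia of the matched condition profiles.

    Each table is feature-centered and, by default, scaled to unit total
    variance so neither assay dominates.  Axes are common feature-space
    directions from the eigendecomposition of the symmetrized cross-product
    of the preprocessed tables.  Per-sample dissimilarity is the Euclidean
    distance between the two assays' score vectors on the retained axes,
    each normalized to unit length per sample.
    """
    samples = list(tables.rna_sub.columns)
    X = _preprocess(tables.rna_sub.to_numpy(dtype=float).T, preprocessing)
    Y = _preprocess(tables.protein_sub.to_numpy(dtype=float).T, preprocessing)
    n = X.shape[0]
    if len(tables.shared_features) < n_axes + 2:
        raise ValueError("need at least n_axes + 2 shared features")

    # Matched tables share one feature space, so the co-inertia axes are
    # common feature-space directions w maximizing cov(Xw, Yw): the
    # eigenvectors of the symmetrized cross-product (X'Y + Y'X)/2.  Both
    # tables project onto the SAME axes, so score disagreement measures
    # real cross-assay discordance (separate per-table axes would be free
    # to align the two configurations spuriously when features vastly
    # outnumber samples).  Computed through an orthonormal basis of the
    # joint row space, so cost scales with sample count, not feature count.
    Z = np.vstack([X, Y])                    # 2n x p
    Q, _ = np.linalg.qr(Z.T)                 # p x 2n basis of the row space
    A, B = X @ Q, Y @ Q                      # n x 2n
    core = (A.T @ B + B.T @ A) / 2.0         # 2n x 2n symmetric
    lam, E = np.linalg.eigh(core)
    order = np.argsort(lam)[::-1]            # positive-covariance axes first
    lam, E = lam[order], E[:, order]
    scale = max(abs(lam[0]), abs(lam[-1]))
    rank = int((lam > scale * 1e-12).sum()) if scale > 0 else 0
    if n_axes > rank:
        raise ValueError(f"n_axes ({n_axes}) exceeds the co-inertia rank ({rank})")
    W = Q @ E[:, :n_axes]                    # common axes, orthonormal columns
    scores_x = X @ W
    scores_y = Y @ W

    def unit_rows(S: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(S, axis=1, keepdims=True)
        return S / np.where(norms > 0, norms, 1.0)

    nx, ny = unit_rows(scores_x), unit_rows(scores_y)
    diss = np.linalg.norm(nx - ny, axis=1)
    axes = [f"Axis{i+1}" for i in range(n_axes)]
    return CoinertiaResult(
        reference_scores=pd.DataFrame((nx + ny) / 2, index=samples, columns=axes),
        rna_scores=pd.DataFrame(nx, index=samples, columns=axes),
        protein_scores=pd.DataFrame(ny, index=samples, columns=axes),
        pseudo_eigenvalues=lam[:n_axes],
        sample_dissimilarity=pd.Series(diss, index=samples, name="dissimilarity"),
        rv=rv_coefficient(X, Y),
    )
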