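"""Normalization and threshold-rule differential expression.

Transcripts: a pseudocount of one is added to raw counts, per-sample size
factors are estimated by the median-of-ratios method, and features are
called differentially expressed at a |fold change| threshold (default
2-fold).  With a single library per condition no p-value is attached — the
fold-change rule is the test, as in single-replicate RNA-seq designs.

Proteins: reporter abundance ratios are compared by the ratio of
within-condition medians at a ±1.25-fold threshold, with a two-sample
t-test on log2 values and Benjamini–Hochberg FDR across all tested
proteins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import OmicsMatrix

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


@dataclass
class DEResult:
    """Per-feature differential-expression record for one contrast."""

    feature: str
    log2fc: float
    mean_expr: float
    p: float | None
    fdr: float | None
    direction: str  # up / down / unchanged
    passed: bool


def size_factors(counts: OmicsMatrix, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """Median-of-ratios size factors.

    A pseudocount is added, the per-feature geometric mean across samples
    is formed, and each sample's factor is the median over features of
    count / geometric mean.  Factors are returned unnormalized, matching
    the reference definition of the estimator.
    """
    if counts.assay != "rna_counts":
        raise ValueError("size_factors requires an rna_counts matrix")
    mat = counts.values.to_numpy(dtype=float) + pseudocount
    if mat.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    log_geo = np.mean(np.log(mat), axis=1)
    keep = np.isfinite(log_geo)
    ratios = mat[keep] / np.exp(log_geo[keep, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalize_counts(counts: OmicsMatrix, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Pseudocounted counts divided by their median-of-ratios size factors."""
    sf = size_factors(counts, pseudocount)
    return (counts.values + pseudocount) / sf


def rna_de(
    counts: OmicsMatrix,
    contrast: tuple[str, str],
    fold_threshold: float = 2.0,
) -> list[DEResult]:
    """Fold-change-rule DE for count data (no p-values: n = 1 per condition).

    ``contrast`` is (treated condition, control condition).  log2FC is
    computed on normalized, pseudocounted counts averaged within condition;
    ``mean_expr`` is the feature's average normalized value over all
    conditions (the MA-plot x-coordinate).  A feature passes when its fold
    change is >= +threshold or <= -threshold (inclusive).
    """
    treated, control = contrast
    norm = normalize_counts(counts)
    for cond in contrast:
        counts.columns_for(cond)  # raises if absent
    t_mean = norm[counts.columns_for(treated)].mean(axis=1)
    c_mean = norm[counts.columns_for(control)].mean(axis=1)
    cond_means = pd.concat(
        [norm[counts.columns_for(c)].mean(axis=1) for c in counts.conditions], axis=1
    )
    mean_expr = cond_means.mean(axis=1)
    log2fc = np.log2(t_mean / c_mean)
    log2_thr = np.log2(fold_threshold)
    out = []
    for feat in counts.feature_ids:
        lfc = float(log2fc[feat])
        passed = abs(lfc) >= log2_thr
        direction = "up" if lfc > 0 else "down" if lfc < 0 else "unchanged"
        if not passed:
            direction = "unchanged" if lfc == 0 else direction
        out.append(
            DEResult(
                feature=feat,
                log2fc=lfc,
                mean_expr=float(mean_expr[feat]),
                p=None,
                fdr=None,
                direction=direction,
                passed=bool(passed),
            )
        )
    return out


def replicate_filter(protein: OmicsMatrix, min_present: int = 2) -> OmicsMatrix:
    """Keep proteins observed in >= ``min_present`` replicates of *every* condition."""
    if protein.assay != "protein_ratio":
        raise ValueError("replicate_filter requires a protein_ratio matrix")
    present = protein.values.notna()
    keep = pd.Series(True, index=protein.values.index)
    for cond in protein.conditions:
        cols = protein.columns_for(cond)
        keep &= present[cols].sum(axis=1) >= min_present
    removed = int((~keep).sum())
    if removed:
        logger.info("replicate_filter removed %d of %d features",
                    removed, len(keep))
    return protein.with_values(protein.values.loc[keep].copy())


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def protein_de(
    protein: OmicsMatrix,
    contrast: tuple[str, str],
    fold_threshold: float = 1.25,
    alpha: float = 0.05,
    log_scale: bool = True,
    equal_var: bool = True,
) -> list[DEResult]:
    """Median-ratio + t-test DE for protein abundance ratios.

    Fold change is median(treated replicates) / median(control replicates);
    the t-test (Student by default, Welch via ``equal_var=False``) runs on
    log2 ratios; FDR is Benjamini–Hochberg over all tested proteins.  A
    protein passes when |fold| >= threshold (inclusive) and FDR <= alpha.
    Features with < 2 observed replicates in either contrast condition are
    excluded with a warning.
    """
    treated, control = contrast
    t_cols = protein.columns_for(treated)
    c_cols = protein.columns_for(control)
    vals = protein.values
    mean_expr = vals.mean(axis=1, skipna=True).to_numpy(dtype=float)
    t_block = vals[t_cols].to_numpy(dtype=float)
    c_block = vals[c_cols].to_numpy(dtype=float)

    rows: list[tuple[str, float, float, float]] = []
    skipped = 0
    for i, feat in enumerate(protein.feature_ids):
        tv = t_block[i][~np.isnan(t_block[i])]
        cv = c_block[i][~np.isnan(c_block[i])]
        if len(tv) < 2 or len(cv) < 2:
            skipped += 1
            continue
        fold = np.median(tv) / np.median(cv)
        if log_scale:
            a, b = np.log2(tv), np.log2(cv)
        else:
            a, b = tv, cv
        if np.ptp(a) == 0 and np.ptp(b) == 0 and np.median(a) == np.median(b):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            if not np.isfinite(p):
                p = 1.0
        rows.append((feat, float(np.log2(fold)), float(mean_expr[i]), p))
    if skipped:
        logger.warning("protein_de excluded %d features with <2 observed "
                       "replicates in a contrast condition", skipped)
    if not rows:
        return []
    fdr = bh_adjust([r[3] for r in rows])
    log2_thr = np.log2(fold_threshold)
    out = []
    for (feat, lfc, mx, p), q in zip(rows, fdr):
        passed = abs(lfc) >= log2_thr and q <= alpha
        direction = "up" if lfc > 0 else "down" if lfc < 0 else "unchanged"
        out.append(
            DEResult(feature=feat, log2fc=lfc, mean_expr=mx, p=p,
                     fdr=float(q), direction=direction, passed=bool(passed))
        )
    return out


# ----------------------------------------------------------------------
@dataclass
class VennPartition:
    """Region decomposition of per-contrast DE feature sets."""

    sets: dict[str, tuple[set[str], set[str]]]   # contrast -> (up, down)
    regions: dict[str, set[str]]


def venn_partition(
    per_contrast_passed: Mapping[str, tuple[set[str], set[str]]],
) -> VennPartition:
    """Common/exclusive regions of up- and down-regulated sets across contrasts.

    Emits ``common_up`` / ``common_down`` (intersection over all contrasts)
    and ``<contrast>_only_up`` / ``_only_down`` (features unique to one
    contrast); counts obey inclusion–exclusion by construction.
    """
    labels = list(per_contrast_passed)
    if len(labels) < 2:
        raise ValueError("venn_partition needs at least 2 contrasts")
    regions: dict[str, set[str]] = {}
    for di, dname in ((0, "up"), (1, "down")):
        sets = {lab: set(per_contrast_passed[lab][di]) for lab in labels}
        common = set.intersection(*sets.values())
        regions[f"common_{dname}"] = common
        for lab in labels:
            others = set.union(*(sets[o] for o in labels if o != lab)) if len(labels) > 1 else set()
            regions[f"{lab}_only_{dname}"] = sets[lab] - others
    return VennPartition(
        sets={lab: (set(u), set(d)) for lab, (u, d) in per_contrast_passed.items()},
        regions=regions,
    )


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    """Flatten DE results to a DataFrame (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "log2fc": r.log2fc,
                "mean_expr": r.mean_expr,
                "p": np.nan if r.p is None else r.p,
                "fdr": np.nan if r.fdr is None else r.fdr,
                "direction": r.direction,
                "passed": r.passed,
            }
            for r in results
        ]
    ).set_index("feature")
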