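"""Sign-flip differential co-expression network and hub ranking.

For each condition separately, Pearson correlations are computed over that
condition's replicate columns for every protein pair (proteins with any
missing value are excluded first).  An edge joins a pair whose correlation
*flips sign* in the focal condition relative to all others at a magnitude
threshold (default 0.75):

* ``positive`` edge: r >= +t in the focal condition and r <= -t in every
  other condition;
* ``negative`` edge: r <= -t in the focal condition and r >= +t in every
  other condition.

Thresholds are inclusive.  Pairs whose correlation is undefined in any
condition (constant feature) never qualify.  Hubs are nodes ranked by
degree; a permutation null (shuffling replicate labels within the focal
condition) is available to calibrate the expected edge count by chance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iokit import OmicsMatrix


@dataclass
class CorrelationTensor:
    """Per-condition Pearson correlation matrices over replicate columns."""

    conditions: list[str]
    features: list[str]
    r: dict[str, np.ndarray]            # condition -> symmetric matrix (NaN allowed)
    n_per_condition: dict[str, int]


@dataclass(frozen=True)
class Edge:
    source: str                         # source < target lexicographically
    target: str
    sign_class: str                     # positive / negative
    r: dict[str, float] = field(compare=False, hash=False, default_factory=dict)


@dataclass
class DiffCoexpNetwork:
    edges: list[Edge]
    conditions: list[str]
    focal_condition: str
    threshold: float

    @property
    def nodes(self) -> dict[str, dict[str, int]]:
        """Node -> degree split by incident edge sign."""
        deg: dict[str, dict[str, int]] = {}
        for e in self.edges:
            for node in (e.source, e.target):
                d = deg.setdefault(node, {"degree": 0, "positive": 0, "negative": 0})
                d["degree"] += 1
                d[e.sign_class] += 1
        return deg

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.target, e.sign_class) for e in self.edges}


def condition_correlations(protein: OmicsMatrix) -> CorrelationTensor:
    """Pearson correlation slices per condition, complete-case features only.

    Features with *any* missing value across the whole matrix are dropped
    before computing correlations.  Within a condition, a feature that is
    constant across replicates has undefined correlations, recorded as NaN.
    """
    vals = protein.values.dropna(axis=0, how="any")
    features = list(vals.index)
    conds = protein.conditions
    r: dict[str, np.ndarray] = {}
    n_per: dict[str, int] = {}
    for cond in conds:
        cols = protein.columns_for(cond)
        if len(cols) < 3:
            raise ValueError(
                f"condition {cond!r} has {len(cols)} replicates; "
                "correlations need at least 3"
            )
        block = vals[cols].to_numpy(dtype=float)
        centered = block - block.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = centered / norms[:, None]
            corr = unit @ unit.T
        corr[norms == 0, :] = np.nan
        corr[:, norms == 0] = np.nan
        np.clip(corr, -1.0, 1.0, out=corr)
        np.fill_diagonal(corr, 1.0)
        r[cond] = corr
        n_per[cond] = len(cols)
    return CorrelationTensor(conditions=list(conds), features=features,
                             r=r, n_per_condition=n_per)


def _edge_masks(
    tensor: CorrelationTensor, focal: str, threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pair indices plus boolean masks of qualifying edges."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if focal not in tensor.conditions:
        raise ValueError(f"focal condition {focal!r} not in tensor")
    others = [c for c in tensor.conditions if c != focal]
    rf = tensor.r[focal]
    n = len(tensor.features)
    iu, ju = np.triu_indices(n, k=1)

    defined = ~np.isnan(rf[iu, ju])
    for c in others:
        defined &= ~np.isnan(tensor.r[c][iu, ju])

    pos = defined & (rf[iu, ju] >= threshold)
    neg = defined & (rf[iu, ju] <= -threshold)
    for c in others:
        rc = tensor.r[c][iu, ju]
        pos &= rc <= -threshold
        neg &= rc >= threshold
    return iu, ju, pos, neg


def signflip_edges(
    tensor: CorrelationTensor,
    focal: str,
    threshold: float = 0.75,
) -> DiffCoexpNetwork:
    """Edges whose correlation sign flips in the focal condition.

    Inclusive thresholds; pairs with an undefined correlation in any
    condition are excluded; output is deduplicated (source < target) and
    deterministic.
    """
    iu, ju, pos, neg = _edge_masks(tensor, focal, threshold)
    feats = np.asarray(tensor.features)
    edges: list[Edge] = []
    for sign_class, mask in (("positive", pos), ("negative", neg)):
        for i, j in zip(iu[mask], ju[mask]):
            a, b = sorted((feats[i], feats[j]))
            edges.append(
                Edge(
                    source=a,
                    target=b,
                    sign_class=sign_class,
                    r={c: float(tensor.r[c][i, j]) for c in tensor.conditions},
                )
            )
    edges.sort(key=lambda e: (e.source, e.target))
    return DiffCoexpNetwork(edges=edges, conditions=list(tensor.conditions),
                            focal_condition=focal, threshold=threshold)


def hub_ranking(
    network: DiffCoexpNetwork, top_n: int | None = None
) -> list[tuple[str, int, int, int]]:
    """Nodes by descending total degree (ties broken lexicographically).

    Returns (feature, degree, positive degree, negative degree) tuples.
    """
    nodes = network.nodes
    ranked = sorted(
        ((f, d["degree"], d["positive"], d["negative"]) for f, d in nodes.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked if top_n is None else ranked[:top_n]


def hub_subnetwork(network: DiffCoexpNetwork, hub: str) -> DiffCoexpNetwork:
    """Edges incident to one hub (the per-hub view of the overview network)."""
    sub = [e for e in network.edges if hub in (e.source, e.target)]
    return DiffCoexpNetwork(edges=sub, conditions=list(network.conditions),
                            focal_condition=network.focal_condition,
                            threshold=network.threshold)


def permutation_null_edge_counts(
    protein: OmicsMatrix,
    focal: str,
    threshold: float = 0.75,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Edge counts after shuffling replicate labels within the focal condition.

    Permuting the focal condition's replicate columns independently per
    feature destroys real co-expression there while preserving marginal
    distributions; the resulting edge counts calibrate how many sign-flip
    edges arise by chance.
    """
    rng = np.random.default_rng(seed)
    base = condition_correlations(protein)
    vals = protein.values.dropna(axis=0, how="any")
    cols = protein.columns_for(focal)
    block = vals[cols].to_numpy(dtype=float)
    counts = np.empty(n_permutations, dtype=int)
    tensor = CorrelationTensor(
        conditions=list(base.conditions),
        features=list(base.features),
        r=dict(base.r),
        n_per_condition=dict(base.n_per_condition),
    )
    for it in range(n_permutations):
        perm = rng.permuted(block, axis=1)
        centered = perm - perm.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = centered / norms[:, None]
            corr = unit @ unit.T
        corr[norms == 0, :] = np.nan
        corr[:, norms == 0] = np.nan
        np.clip(corr, -1.0, 1.0, out=corr)
        np.fill_diagonal(corr, 1.0)
        tensor.r[focal] = corr
        _, _, pos, neg = _edge_masks(tensor, focal, threshold)
        counts[it] = int(pos.sum() + neg.sum())
    return counts
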