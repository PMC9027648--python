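"""Gene-set enrichment with a directional z-score.

Each term is tested by the one-sided Fisher exact test (hypergeometric
upper tail) of the overlap between a query feature list and the term's
members within a stated universe, with Benjamini–Hochberg FDR across
terms.  An EASE-style conservative variant (overlap decremented by one
before taking the tail) is available.

The directional z-score summarises which way a term's members move:

    z = (up - down) / sqrt(up + down)

where ``up``/``down`` count term members that are up-/down-regulated in
the query.  Note the subtraction in the numerator: z is 0 for a balanced
term, +sqrt(count) when every member is up, and well defined when one
direction is empty.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .iokit import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    term: str
    name: str
    count: int          # overlap with the query
    up: int
    down: int
    z: float
    fold_enrichment: float
    p: float
    fdr: float


def directional_z(up: int, down: int) -> float:
    """(up - down) / sqrt(up + down); 0 when the term has no assigned members."""
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    count = up + down
    if count == 0:
        return 0.0
    return (up - down) / math.sqrt(count)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    up: Iterable[str] = (),
    down: Iterable[str] = (),
    ease: bool = False,
) -> list[EnrichmentRow]:
    """Fisher-exact term enrichment of ``query`` against ``universe``.

    ``up``/``down`` partition (a subset of) the query by direction and feed
    the z-score; they default to empty, giving z = 0.  Set members outside
    the universe are dropped.  With ``ease=True`` the overlap is
    decremented by one before the tail computation.  FDR is BH over the
    tested terms; rows are ordered by (p, term).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    up, down = set(up) & query, set(down) & query
    N, n = len(universe), len(query)
    rows: list[EnrichmentRow] = []
    for term, (name, members) in sets:
        members_in = members & universe
        if not members_in:
            logger.warning("term %r has no members in the universe; skipped", term)
            continue
        K = len(members_in)
        overlap = query & members_in
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, N, K, n)
        n_up, n_down = len(up & members_in), len(down & members_in)
        rows.append(
            EnrichmentRow(
                term=term,
                name=name,
                count=k,
                up=n_up,
                down=n_down,
                z=directional_z(n_up, n_down),
                fold_enrichment=(k / n) / (K / N),
                p=p,
                fdr=float("nan"),
            )
        )
    if rows:
        for row, q in zip(rows, bh_adjust([r.p for r in rows])):
            row.fdr = float(q)
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "name": r.name, "count": r.count,
                "up": r.up, "down": r.down, "z": r.z,
                "fold_enrichment": r.fold_enrichment, "p": r.p, "fdr": r.fdr,
            }
            for r in rows
        ]
    )
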