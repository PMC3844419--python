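"""Hypergeometric over-representation tests against user-supplied category
maps (GMT-style) and pairwise gene-set overlap tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .expression import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class CategoryMap:
    categories: dict[str, frozenset]
    universe: frozenset
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.categories.items():
            if not members <= self.universe:
                raise ValueError(f"category {cid} has members outside the universe")

    @classmethod
    def from_gmt(cls, path: Path | str, universe: Iterable[str]) -> "CategoryMap":
        """Load a GMT file (name TAB description TAB gene...), restricting each
        category to the given universe."""
        universe = frozenset(universe)
        categories, descriptions = {}, {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 fields")
                name, desc, genes = fields[0], fields[1], fields[2:]
                members = frozenset(g for g in genes if g)
                dropped = members - universe
                if dropped:
                    log.warning("%s: %d gene(s) outside universe dropped", name, len(dropped))
                categories[name] = members & universe
                descriptions[name] = desc
        return cls(categories=categories, universe=universe, descriptions=descriptions)


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    description: str
    overlap: int
    query_size: int
    category_size: int
    universe_size: int
    pvalue: float
    padj: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) where X counts category members (K of N) in a draw of n."""
    if min(k, K, n, N) < 0:
        raise ValueError("sizes must be non-negative")
    if K > N or n > N:
        raise ValueError("category and query must fit inside the universe")
    if k > min(K, n):
        raise ValueError(f"overlap {k} exceeds min(category={K}, query={n})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str], cmap: CategoryMap, min_category: int = 3
) -> list[EnrichmentResult]:
    """One hypergeometric test per sufficiently large category, BH-adjusted."""
    query = set(query)
    dropped = query - cmap.universe
    if dropped:
        log.warning("%d query gene(s) outside universe dropped", len(dropped))
    query &= cmap.universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N = len(cmap.universe)
    n = len(query)
    tested = [
        (cid, members)
        for cid, members in sorted(cmap.categories.items())
        if len(members) >= min_category
    ]
    pvals = [hypergeom_tail(len(query & members), len(members), n, N) for _, members in tested]
    padj = bh_adjust(pvals) if pvals else []
    results = [
        EnrichmentResult(
            category_id=cid,
            description=cmap.descriptions.get(cid, ""),
            overlap=len(query & members),
            query_size=n,
            category_size=len(members),
            universe_size=N,
            pvalue=float(p),
            padj=float(a),
        )
        for (cid, members), p, a in zip(tested, pvals, padj)
    ]
    return sorted(results, key=lambda r: (r.pvalue, r.category_id))


def overlap_test(setA: Iterable[str], setB: Iterable[str], universe: Iterable[str]) -> tuple[int, float]:
    """Hypergeometric overlap test of two gene sets within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    A, B = set(setA) & universe, set(setB) & universe
    k = len(A & B)
    return k, hypergeom_tail(k, len(A), len(B), len(universe))


def results_to_frame(results: list[EnrichmentResult], gene_set: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Term": [r.category_id for r in results],
            "Description": [r.description for r in results],
            "Overlap": [r.overlap for r in results],
            "CategorySize": [r.category_size for r in results],
            "P": [r.pvalue for r in results],
            "AdjustedP": [r.padj for r in results],
            "GeneSet": gene_set,
        }
    )
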