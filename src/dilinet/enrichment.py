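"""Hypergeometric over-representation analysis with BH adjustment.

Pathway collections come in standard GMT (tab-separated: id, description,
member symbols). For a query of n genes drawn from a universe of N genes
of which K belong to a pathway, the over-representation p-value is the
upper tail P(X >= k) of the hypergeometric distribution, where k is the
observed overlap. p-values are adjusted across all tested pathways by the
Benjamini–Hochberg step-up procedure, and results are ranked by adjusted
p-value (ties: larger overlap, then pathway name).

The default universe is the union of all pathway members — the most
reproducible convention when the true assay background is unknown; an
explicit background gene set may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from ._common import ParseError, logger, normalize_gene_symbol
from .network import GeneSet


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]


@dataclass
class PathwayCollection:
    pathways: list[Pathway]
    universe: frozenset[str]

    def restricted(self, universe: frozenset[str]) -> "PathwayCollection":
        """The collection with member sets intersected with ``universe``."""
        return PathwayCollection(
            pathways=[
                Pathway(p.pathway_id, p.name, p.members & universe) for p in self.pathways
            ],
            universe=universe,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    overlap_count: int
    query_size: int
    pathway_size: int
    universe_size: int
    gene_ratio: float
    p_value: float
    p_adjusted: float
    overlap_symbols: tuple[str, ...]


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file; the universe defaults to the union of members."""
    pathways: list[Pathway] = []
    universe: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: GMT line needs id, description and >=1 member", line=lineno
                )
            pid, name = fields[0].strip(), fields[1].strip()
            members = [normalize_gene_symbol(m) for m in fields[2:] if m.strip()]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.info("%s line %d: duplicate members in %s collapsed", path, lineno, pid)
            pathways.append(Pathway(pid, name or pid, unique))
            universe |= unique
    return PathwayCollection(pathways=pathways, universe=frozenset(universe))


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in coll.pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")


def hypergeom_pvalue(overlap: int, query: int, pathway: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, pathway, query).

    scipy evaluates the tail with log-space combinatorics, so the result is
    stable for large universes. The tail includes the observed value, so
    overlap = 0 gives exactly 1.
    """
    if not 0 <= pathway <= universe:
        raise ValueError(f"pathway size {pathway} outside [0, {universe}]")
    if not 0 <= query <= universe:
        raise ValueError(f"query size {query} outside [0, {universe}]")
    if overlap < 0 or overlap > min(query, pathway):
        raise ValueError(
            f"overlap {overlap} impossible for query {query}, pathway {pathway}"
        )
    # sf(k-1) = P(X >= k)
    p = float(hypergeom.sf(overlap - 1, universe, pathway, query))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min over j >= i (sorted order) of m * p(j) / j, capped at 1.
    """
    m = len(p_values)
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value outside (0,1]: {p}")
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = running
    return adjusted


def enrich(
    query: GeneSet,
    coll: PathwayCollection,
    top: int = 20,
    min_set: int = 1,
    max_set: int | None = None,
    universe: frozenset[str] | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each pathway of ``coll``.

    The query is restricted to the universe (the number of genes dropped is
    logged); pathways with no member in the universe, or with restricted
    size outside [min_set, max_set], are not tested. BH adjustment spans
    all tested pathways; the returned list is the top ``top`` results.
    """
    uni = universe if universe is not None else coll.universe
    restricted = coll.restricted(frozenset(uni))
    q = query.symbols & uni
    dropped = len(query.symbols) - len(q)
    if dropped:
        logger.info("%d query genes outside the universe dropped", dropped)
    if not q:
        raise ValueError(
            "query is empty after restriction to the universe; "
            "check that query and pathway collection use the same symbol space"
        )
    n, N = len(q), len(uni)
    tested: list[tuple[Pathway, int]] = []
    for p in restricted.pathways:
        K = len(p.members)
        if K < max(min_set, 1) or (max_set is not None and K > max_set):
            continue
        tested.append((p, K))
    pvals = [hypergeom_pvalue(len(q & p.members), n, K, N) for p, K in tested]
    padj = bh_adjust(pvals) if pvals else []
    results = []
    for (p, K), pv, pa in zip(tested, pvals, padj):
        overlap = sorted(q & p.members)
        results.append(
            EnrichmentResult(
                pathway_id=p.pathway_id,
                name=p.name,
                overlap_count=len(overlap),
                query_size=n,
                pathway_size=K,
                universe_size=N,
                gene_ratio=len(overlap) / n,
                p_value=pv,
                p_adjusted=pa,
                overlap_symbols=tuple(overlap),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, -r.overlap_count, r.name, r.pathway_id))
    return results[: max(top, 0)] if top is not None else results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "overlap_count": r.overlap_count,
                "query_size": r.query_size,
                "pathway_size": r.pathway_size,
                "universe_size": r.universe_size,
                "gene_ratio": r.gene_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "overlap_symbols": ";".join(r.overlap_symbols),
            }
            for r in results
        ]
    )


def bubble_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Bubble-plot export: x = genes enriched, size = gene ratio, color =
    adjusted p-value (one row per pathway, rank order preserved)."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "x_overlap_count": r.overlap_count,
                "size_gene_ratio": r.gene_ratio,
                "color_p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
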