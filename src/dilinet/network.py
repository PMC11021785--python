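"""Drug-target x disease gene intersection and thresholded PPI network.

Gene lists are plain text, one symbol per line (``#`` comments allowed);
symbols are trimmed, uppercased and optionally alias-mapped. The PPI edge
list is a STRING-style TSV with header ``protein1\tprotein2\tcombined_score``;
scores may be 0-1000 integers (STRING exports) or 0-1 reals — the scale is
auto-detected from the maximum score unless forced. The network is
undirected, the default confidence cut-off is 0.7, and hub genes are
ranked by node degree (ties alphabetical).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from ._common import ParseError, logger, normalize_gene_symbol


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of normalized (uppercase) gene symbols."""

    label: str
    symbols: frozenset[str]

    def __post_init__(self):
        for s in self.symbols:
            if not s or s != s.strip().upper():
                raise ValueError(f"gene symbol not normalized: {s!r}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class PPIEdge:
    """One undirected interaction with a combined confidence in [0, 1]."""

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self):
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined_score outside [0,1]: {self.combined_score}")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``alias,canonical`` of gene-symbol remappings."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != ["alias", "canonical"]:
            raise ParseError(f"{path}: expected header alias,canonical")
        for row in reader:
            out[normalize_gene_symbol(row["alias"])] = normalize_gene_symbol(row["canonical"])
    return out


def read_gene_list(
    path: str | Path,
    label: str | None = None,
    aliases: dict[str, str] | None = None,
) -> GeneSet:
    """Read, normalize and deduplicate a one-symbol-per-line gene list."""
    p = Path(path)
    symbols: list[str] = []
    with open(p, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            symbols.append(normalize_gene_symbol(s, aliases))
    unique = frozenset(symbols)
    dupes = len(symbols) - len(unique)
    if dupes:
        logger.info("%s: %d duplicate symbols collapsed", p.name, dupes)
    if not unique:
        logger.warning("%s: empty gene list", p.name)
    return GeneSet(label=label or p.stem, symbols=unique)


def intersect_gene_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Commutative set intersection; the result label joins both labels."""
    return GeneSet(label=f"{a.label}&{b.label}", symbols=a.symbols & b.symbols)


def read_edge_list(path: str | Path, scale: str = "auto") -> list[PPIEdge]:
    """Read a STRING-style TSV edge list.

    ``scale`` is ``auto`` (divide by 1000 when any score exceeds 1),
    ``unit`` (scores already in [0,1]) or ``milli`` (always divide by
    1000). Self-loops after symbol normalization are dropped.
    """
    if scale not in ("auto", "unit", "milli"):
        raise ValueError(f"scale must be auto|unit|milli, got {scale!r}")
    raw: list[tuple[str, str, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = ["protein1", "protein2", "combined_score"]
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != need:
            raise ParseError(f"{path}: expected tab-separated header {need}")
        for lineno, row in enumerate(reader, start=2):
            try:
                score = float(row["combined_score"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: bad combined_score {row['combined_score']!r}", line=lineno
                ) from None
            raw.append(
                (normalize_gene_symbol(row["protein1"]), normalize_gene_symbol(row["protein2"]), score)
            )
    if not raw:
        return []
    divisor = 1.0
    if scale == "milli" or (scale == "auto" and max(s for _, _, s in raw) > 1.0):
        divisor = 1000.0
    edges = []
    for i, (ga, gb, s) in enumerate(raw):
        v = s / divisor
        if not 0.0 <= v <= 1.0:
            raise ParseError(f"{path}: score {s} outside [0,1] after {divisor:g}x scaling", line=i + 2)
        if ga == gb:
            logger.info("%s: self-loop %s dropped", Path(path).name, ga)
            continue
        edges.append(PPIEdge(ga, gb, v))
    return edges


def build_network(
    genes: GeneSet,
    edges: list[PPIEdge],
    min_score: float = 0.7,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Induced PPI subgraph over ``genes`` at the confidence threshold.

    Keeps edges whose endpoints are both in ``genes`` and whose score is
    >= ``min_score``; duplicate/reversed edges collapse keeping the
    maximum score. Isolated members are excluded unless ``keep_isolated``.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0,1], got {min_score}")
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(sorted(genes.symbols))
    for e in edges:
        if e.combined_score < min_score:
            continue
        if e.gene_a not in genes.symbols or e.gene_b not in genes.symbols:
            continue
        u, v = sorted((e.gene_a, e.gene_b))
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], e.combined_score)
        else:
            g.add_edge(u, v, combined_score=e.combined_score)
    return g


def rank_hubs(net: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree, descending; ties broken alphabetically."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > net.number_of_nodes():
        logger.warning("k=%d exceeds node count %d; returning all", k, net.number_of_nodes())
        k = net.number_of_nodes()
    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, int(d)) for g, d in ranked[:k]]


def network_frames(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes, edges) tables for export: gene/degree and endpoint/score."""
    nodes = pd.DataFrame(
        sorted(((g, int(d)) for g, d in net.degree()), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "degree"],
    )
    edges = pd.DataFrame(
        sorted((u, v, net[u][v]["combined_score"]) for u, v in net.edges()),
        columns=["gene_a", "gene_b", "combined_score"],
    )
    return nodes, edges
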