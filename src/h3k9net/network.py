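"""Physical-interaction graphs over interactome nodes and their statistics.

Reference edges (STRING-style scored, or BioPlex/CCSB/HPRD-style unscored)
are confidence-filtered, induced onto interactome nodes, and summarized:
mean degree of the nuclear vs non-nuclear partition, coverage of
nuclear-to-non-nuclear crossing edges by the top-k nuclear hubs, and
attribution of phase-network edges to bait-pair shared interactors.
"""
from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .sets import InteractomeCollection

EDGE_COLUMNS = ("protein_a", "protein_b", "score")


def filter_edges_by_score(
    edges: pd.DataFrame, min_confidence: float = 0.7, unscored: str = "drop"
) -> pd.DataFrame:
    """Keep edges whose confidence score is strictly greater than the cutoff.

    Scores must lie in [0, 1]. Edges without a score (NaN, or no score
    column) are kept only when ``min_confidence == 0``, or always when
    ``unscored="keep"`` (for reference sets that publish no scores).
    """
    if unscored not in ("drop", "keep"):
        raise ValueError("unscored must be 'drop' or 'keep'")
    if "score" not in edges.columns:
        scores = pd.Series(np.nan, index=edges.index)
    else:
        scores = pd.to_numeric(edges["score"], errors="coerce")
        valid = scores.dropna()
        if ((valid < 0) | (valid > 1)).any():
            raise ValueError("confidence scores must lie in [0, 1]")
    has_score = scores.notna()
    keep_unscored = (unscored == "keep") or (min_confidence == 0)
    mask = (has_score & (scores > min_confidence)) | (~has_score & keep_unscored)
    return edges.loc[mask].reset_index(drop=True)


def induce_graph(edges: pd.DataFrame, nodes: Iterable[str]) -> nx.Graph:
    """Simple undirected graph on exactly ``nodes`` with internal edges only.

    Self-loops are dropped and duplicate edges collapse under canonical
    (min, max) node ordering; a ``score`` attribute is kept when present.
    """
    nodes = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    has_score = "score" in edges.columns
    for row in edges.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        if a == b or a not in nodes or b not in nodes:
            continue
        attrs = {}
        if has_score and not pd.isna(row.score):
            attrs["score"] = float(row.score)
        g.add_edge(a, b, **attrs)
    return g


def mean_degree(graph: nx.Graph) -> float:
    """Average connections per node, 2|E| / |V|."""
    if graph.number_of_nodes() == 0:
        raise ValueError("mean degree of an empty graph is undefined")
    return 2.0 * graph.number_of_edges() / graph.number_of_nodes()


def hub_coverage(
    graph: nx.Graph, part_a: Iterable[str], part_b: Iterable[str], k: int
) -> tuple[list[str], float]:
    """Top-k part_a nodes by crossing degree and the crossing-edge fraction they cover.

    Crossing edges run between the two (disjoint) partitions; ties in
    crossing degree break lexicographically by node id; each covered edge is
    counted once. With zero crossing edges the fraction is 0.0.
    """
    part_a, part_b = set(part_a), set(part_b)
    if part_a & part_b:
        raise ValueError("partitions must be disjoint")
    if not 1 <= k <= max(len(part_a), 1):
        raise ValueError(f"k={k} out of range 1..{len(part_a)}")
    crossing = [
        (u, v)
        for u, v in graph.edges()
        if (u in part_a and v in part_b) or (v in part_a and u in part_b)
    ]
    degree: dict[str, int] = {}
    for u, v in crossing:
        a = u if u in part_a else v
        degree[a] = degree.get(a, 0) + 1
    ranked = sorted(part_a, key=lambda n: (-degree.get(n, 0), n))
    top = ranked[:k]
    if not crossing:
        return top, 0.0
    top_set = set(top)
    covered = sum(1 for u, v in crossing if u in top_set or v in top_set)
    return top, covered / len(crossing)


def pair_overlap_edge_share(
    graph: nx.Graph,
    collection: InteractomeCollection,
    pair: tuple[str, str],
    phase: str,
    mode: str = "any",
) -> tuple[int, int]:
    """Edges of the phase network attributable to a bait pair's shared interactors.

    ``shared`` is the intersection of the pair's phase interactomes; an edge
    is attributed when at least one endpoint is shared (``mode="any"``,
    default) or when both are (``mode="both"``); each edge counts once.
    Returns (edges_touched, total_edges of the graph).
    """
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    shared = collection.get(pair[0], phase) & collection.get(pair[1], phase)
    total = graph.number_of_edges()
    if mode == "any":
        touched = sum(1 for u, v in graph.edges() if u in shared or v in shared)
    else:
        touched = sum(1 for u, v in graph.edges() if u in shared and v in shared)
    return touched, total


def degree_statistics(graph: nx.Graph, nuclear: Iterable[str]) -> pd.DataFrame:
    """Mean degree of the nuclear / non-nuclear induced subgraphs plus overall."""
    nuclear = set(nuclear) & set(graph.nodes)
    other = set(graph.nodes) - nuclear
    rows = []
    for name, part in (("all", set(graph.nodes)), ("nuclear", nuclear), ("non_nuclear", other)):
        if part:
            sub = graph.subgraph(part)
            rows.append((name, len(part), sub.number_of_edges(), mean_degree(sub)))
        else:
            rows.append((name, 0, 0, float("nan")))
    return pd.DataFrame(rows, columns=["partition", "nodes", "edges", "mean_degree"])
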