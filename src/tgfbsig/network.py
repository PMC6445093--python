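"""Protein-interaction network construction, hub augmentation and topology.

The progression proteins form a sparse seed subnetwork inside a scored
interaction graph (STRING-dialect edges thresholded at combined score
strictly greater than 500, plus curated edges kept unconditionally).
Connectivity is improved by ranking candidate hub proteins from two
candidate pools by their number of links to the seed set, skipping an
exclusion list (classically albumin), and taking the top hits per pool.
Topology statistics, shortest-path distances to upstream regulators,
hierarchical layer assignment and a generic hypergeometric gene-set
enrichment complete the module.

Graphs are undirected :class:`networkx.Graph` objects with integer
``confidence`` (0-1000) and ``provenance`` ("database" or "curated")
edge attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_CONFIDENCE = 500
DEFAULT_EXCLUSION = frozenset({"ALB"})
DEFAULT_REGULATORS = ("TGFB1", "TNF")


# ---------------------------------------------------------------------------
# loading and merging
# ---------------------------------------------------------------------------

def _add_edge(g: nx.Graph, u: str, v: str, confidence: int, provenance: str) -> None:
    if u == v:
        return  # self-loops carry no interaction information
    if g.has_edge(u, v):
        if confidence > g.edges[u, v]["confidence"]:
            g.edges[u, v]["confidence"] = confidence
            g.edges[u, v]["provenance"] = provenance
    else:
        g.add_edge(u, v, confidence=confidence, provenance=provenance)


def load_and_merge_edges(paths: Sequence[str | Path],
                         min_confidence: int = DEFAULT_MIN_CONFIDENCE) -> nx.Graph:
    """Merge STRING-dialect and curated edge files into one graph.

    Three tab-separated columns (``protein1 protein2 combined_score``)
    mark the STRING dialect; two columns mark curated edges, which are
    stored at confidence 1000 and are exempt from thresholding.  Scored
    edges survive only with confidence strictly greater than
    ``min_confidence``.  Duplicate undirected edges keep the highest
    confidence.
    """
    g = nx.Graph()
    for path in paths:
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() in ("protein1", "source"):
                    continue  # header
                if len(parts) == 2:
                    _add_edge(g, parts[0], parts[1], 1000, "curated")
                elif len(parts) == 3:
                    try:
                        conf = int(parts[2])
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed confidence {parts[2]!r}"
                        ) from exc
                    if not 0 <= conf <= 1000:
                        raise ValueError(
                            f"{path}:{lineno}: confidence {conf} outside [0, 1000]")
                    if conf > min_confidence:
                        _add_edge(g, parts[0], parts[1], conf, "database")
                else:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                        f"got {len(parts)}")
    return g


def filter_graph(graph: nx.Graph,
                 min_confidence: int = DEFAULT_MIN_CONFIDENCE) -> nx.Graph:
    """In-memory analogue of the load-time threshold: keep curated edges
    and scored edges with confidence strictly above the cutoff."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    for u, v, d in graph.edges(data=True):
        if d.get("provenance") == "curated" or d["confidence"] > min_confidence:
            _add_edge(g, u, v, d["confidence"], d.get("provenance", "database"))
    return g


# ---------------------------------------------------------------------------
# seed subnetwork
# ---------------------------------------------------------------------------

@dataclass
class MappingReport:
    """How a seed list mapped into the interaction graph."""

    mapped: list[str]
    unmapped: list[str]
    isolated: list[str]
    components: list[set[str]]

    @property
    def n_components(self) -> int:
        return len(self.components)


def induced_subnetwork(graph: nx.Graph, seed_symbols: Iterable[str]
                       ) -> tuple[nx.Graph, MappingReport]:
    """Subgraph induced on the seed symbols present in the graph.

    The report lists unmapped seeds (symbols absent from the graph,
    e.g. immunoglobulins missing from interaction databases), isolated
    nodes and connected components of the induced subgraph.
    """
    seeds = sorted(set(seed_symbols))
    if not seeds:
        raise ValueError("seed_symbols must be non-empty")
    mapped = [s for s in seeds if s in graph]
    unmapped = [s for s in seeds if s not in graph]
    sub = graph.subgraph(mapped).copy()
    comps = [set(c) for c in
             sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))]
    isolated = sorted(n for n in sub.nodes if sub.degree(n) == 0)
    return sub, MappingReport(mapped=mapped, unmapped=unmapped,
                              isolated=isolated, components=comps)


# ---------------------------------------------------------------------------
# hub augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HubCandidate:
    symbol: str
    pool_id: int
    links_to_seed: int
    excluded: bool = False


def select_hubs(graph: nx.Graph, seeds: Iterable[str],
                pools: Sequence[Iterable[str]], n_per_pool: int = 2,
                exclusion: Iterable[str] = DEFAULT_EXCLUSION
                ) -> tuple[list[HubCandidate], list[HubCandidate]]:
    """Rank candidate hubs per pool by links to the seed set.

    For each pool, candidates are ranked by the number of distinct seed
    nodes they are adjacent to (descending, ties broken alphabetically
    by symbol) and the top ``n_per_pool`` are returned after removing
    exclusion-listed symbols.  Skipped top-ranked symbols are reported
    with their counts in the second return value (the classical skip is
    albumin at 9 links).  Candidates already in the seed set are ignored.
    """
    if n_per_pool < 1:
        raise ValueError("n_per_pool must be at least 1")
    seed_set = set(seeds)
    exclusion = set(exclusion)
    selected: list[HubCandidate] = []
    skipped: list[HubCandidate] = []
    for pool_id, pool in enumerate(pools, start=1):
        ranked = []
        for symbol in set(pool) - seed_set:
            if symbol not in graph:
                continue
            links = sum(1 for nb in graph.neighbors(symbol) if nb in seed_set)
            ranked.append((symbol, links))
        ranked.sort(key=lambda sl: (-sl[1], sl[0]))
        taken = 0
        for symbol, links in ranked:
            if taken >= n_per_pool:
                break
            if symbol in exclusion:
                skipped.append(HubCandidate(symbol, pool_id, links, excluded=True))
                continue
            selected.append(HubCandidate(symbol, pool_id, links))
            taken += 1
    return selected, skipped


def augment_with_hubs(graph: nx.Graph, subnetwork: nx.Graph,
                      hubs: Iterable[str], regulators: Iterable[str] = ()
                      ) -> nx.Graph:
    """Seed subnetwork plus hub/regulator nodes and all their edges to it."""
    nodes = set(subnetwork.nodes) | {h for h in hubs if h in graph} \
        | {r for r in regulators if r in graph}
    return graph.subgraph(nodes).copy()


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyReport:
    """Global topology statistics of an undirected graph.

    ``clustering_coefficient`` is the mean local clustering with the
    degree-<2 convention of 0; ``characteristic_path_length`` averages
    shortest-path lengths over ordered connected pairs only (None when
    no pair is connected).
    """

    n_nodes: int
    n_edges: int
    n_isolated: int
    clustering_coefficient: float
    avg_neighbors: float
    characteristic_path_length: float | None

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_isolated": self.n_isolated,
            "clustering_coefficient": self.clustering_coefficient,
            "avg_neighbors": self.avg_neighbors,
            "characteristic_path_length": self.characteristic_path_length,
        }


def topology_metrics(graph: nx.Graph) -> TopologyReport:
    """Clustering coefficient, mean degree and characteristic path length."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("topology metrics undefined on an empty graph")
    e = graph.number_of_edges()
    clustering = float(nx.average_clustering(graph, count_zeros=True))
    total, pairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        total += sum(lengths.values())  # includes distance 0 to self
        pairs += len(lengths) - 1
    cpl = (total / pairs) if pairs else None
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_isolated=sum(1 for v in graph if graph.degree(v) == 0),
        clustering_coefficient=clustering,
        avg_neighbors=2.0 * e / n,
        characteristic_path_length=cpl,
    )


def regulator_step_size(graph: nx.Graph, node: str, regulator: str) -> int | None:
    """Unweighted shortest-path edge count node -> regulator; None if
    unreachable."""
    for symbol in (node, regulator):
        if symbol not in graph:
            raise KeyError(f"symbol not in graph: {symbol}")
    try:
        return nx.shortest_path_length(graph, node, regulator)
    except nx.NetworkXNoPath:
        return None


def assign_layers(graph: nx.Graph, top_nodes: Iterable[str]) -> dict[str, int]:
    """Hierarchical layer per node: minimum step size to any top node.

    Top (regulator) nodes sit in layer 0; unreachable nodes are placed
    in a distinct bottom layer one below the deepest reachable layer.
    """
    tops = [t for t in top_nodes]
    if not tops:
        raise ValueError("top_nodes must be non-empty")
    missing = [t for t in tops if t not in graph]
    if missing:
        raise KeyError(f"top node(s) not in graph: {missing}")
    dist = nx.multi_source_dijkstra_path_length(graph, set(tops), weight=None)
    dist = {k: int(v) for k, v in dist.items()}
    bottom = (max(dist.values()) if dist else 0) + 1
    return {node: dist.get(node, bottom) for node in graph.nodes}


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def geneset_enrichment(query: Iterable[str],
                       annotation: Mapping[str, Iterable[str]],
                       universe: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per term.

    For a universe of size ``M`` containing ``K`` annotated symbols and
    a query of size ``n`` overlapping ``k`` of them, p is the
    probability of observing at least ``k`` annotated symbols in a
    random size-``n`` draw; q is Benjamini-Hochberg across terms.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= universe:
        raise ValueError(f"query symbols outside universe: "
                         f"{sorted(query - universe)[:5]}")
    m = len(universe)
    n = len(query)
    rows = []
    for term, symbols in annotation.items():
        term_set = set(symbols) & universe
        k = len(term_set & query)
        p = float(stats.hypergeom.sf(k - 1, m, len(term_set), n))
        rows.append({"term": term, "overlap": k, "term_size": len(term_set),
                     "query_size": n, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["p", "term"], kind="stable")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def node_attribute_table(graph: nx.Graph, layers: Mapping[str, int] | None = None,
                         fold_changes: Mapping[str, float] | None = None
                         ) -> pd.DataFrame:
    """Per-node attributes (degree, layer, fold change) for rendering."""
    rows = []
    for node in sorted(graph.nodes):
        rows.append({
            "protein_symbol": node,
            "degree": graph.degree(node),
            "layer": layers.get(node) if layers else None,
            "fold_change": fold_changes.get(node) if fold_changes else None,
        })
    return pd.DataFrame(rows).set_index("protein_symbol")
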