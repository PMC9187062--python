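"""miRNA-target graph tools: edge-table loading, hypergeometric set
enrichment with BH correction, and MCODE-style dense-complex detection.

MCODE (Molecular Complex Detection) scores each vertex by the density of
the highest k-core of its closed neighborhood, then grows clusters from
high-scoring seeds, admitting neighbors whose weight is within a fraction
(the node score cutoff) of the seed's.  A candidate cluster is kept only
if it contains a k-core; its score is density x node count, so a clique of
n nodes scores exactly n.  The haircut/fluff post-processing steps of the
original tool are not applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .prefilter import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class MCODEParams:
    """MCODE inclusion criteria: degree cutoff 2, node score cutoff 0.2,
    k-core 2, maximum depth 100; reported clusters must score >= 5."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    min_cluster_score: float = 5.0

    def __post_init__(self):
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not 0.0 < self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must be in (0,1)")
        if self.min_cluster_score < 0:
            raise ValueError("min_cluster_score must be >= 0")


@dataclass
class Cluster:
    nodes: Set[str]
    score: float
    seed: str


@dataclass
class ClusterResult:
    clusters: List[Cluster] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters, start=1):
            for node in sorted(c.nodes):
                rows.append({"cluster_id": i, "node": node,
                             "score": c.score, "seed": c.seed})
        return pd.DataFrame(rows, columns=["cluster_id", "node", "score", "seed"])


def load_edge_table(path) -> nx.Graph:
    """Read a 2/3-column TSV (source, target[, kind]) into an undirected
    graph; duplicate edges collapse, self-loops are dropped with a warning."""
    G = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty node identifier")
            n_lines += 1
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                G.add_node(u)
                continue
            G.add_edge(u, v)
            if len(parts) == 3 and parts[2].strip():
                G.nodes[u].setdefault("kind", parts[2].strip())
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found")
    return G


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # name, hits, set_size, query_size, universe_size, p, q

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] <= alpha]


def hypergeom_enrich(query: Iterable[str], pathways: Dict[str, Iterable[str]],
                     universe: Iterable[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``query`` in each pathway.

    With universe size N, pathway size K (after intersection with the
    universe), query size n and overlap k, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); q-values are BH-adjusted across pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in pathways.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"name": name, "hits": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values(["p", "name"], kind="stable").reset_index(drop=True)
    else:
        table["q"] = []
    return EnrichmentResult(table=table)


# ----------------------------------------------------------------------
# MCODE
# ----------------------------------------------------------------------
def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def _vertex_weights(G: nx.Graph, degree_cutoff: int) -> Dict[str, float]:
    """Weight = k * density of the highest-k-core of the closed neighborhood;
    vertices below the degree cutoff weigh 0."""
    weights: Dict[str, float] = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        H = G.subgraph(set(G[v]) | {v})
        core = nx.core_number(H)
        k_max = max(core.values())
        core_sub = H.subgraph([u for u, c in core.items() if c == k_max])
        weights[v] = k_max * _density(core_sub)
    return weights


def _expand(G: nx.Graph, seed, weights, cutoff: float, max_depth: int) -> Set:
    members = {seed}
    frontier = [(seed, 0)]
    threshold = weights[seed] * (1.0 - cutoff)
    while frontier:
        node, depth = frontier.pop()
        if depth >= max_depth:
            continue
        for nb in G[node]:
            if nb not in members and weights[nb] >= threshold:
                members.add(nb)
                frontier.append((nb, depth + 1))
    return members


def mcode_cluster(graph: nx.Graph, params: MCODEParams | None = None
                  ) -> ClusterResult:
    """MCODE-style clustering; returns clusters scoring >= the threshold,
    sorted by descending score.  Empty graphs yield an empty result; an
    isolated node can never seed or join a cluster, so adding one leaves
    the report unchanged."""
    params = params or MCODEParams()
    if graph.number_of_nodes() == 0:
        return ClusterResult()
    weights = _vertex_weights(graph, params.degree_cutoff)
    seeds = sorted((v for v, w in weights.items() if w > 0),
                   key=lambda v: (-weights[v], str(v)))
    assigned: Set = set()
    clusters: List[Cluster] = []
    for seed in seeds:
        if seed in assigned:
            continue
        members = _expand(graph, seed, weights, params.node_score_cutoff,
                          params.max_depth)
        sub = graph.subgraph(members)
        core = nx.core_number(sub)
        if not core or max(core.values()) < params.k_core:
            continue
        assigned |= members
        score = _density(sub) * sub.number_of_nodes()
        clusters.append(Cluster(nodes=set(members), score=score, seed=seed))
    kept = [c for c in clusters if c.score >= params.min_cluster_score]
    kept.sort(key=lambda c: (-c.score, c.seed))
    logger.info("MCODE: %d candidate clusters, %d at score >= %g",
                len(clusters), len(kept), params.min_cluster_score)
    return ClusterResult(clusters=kept)


def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT gene-set file: name, description, then members, tab-sep."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, "
                                 "description and at least one member")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
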