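"""Protein-interaction network topology and essentiality ranking.

The interaction graph is simple and undirected, built from score-filtered
edges.  Centralities follow the cytoHubba conventions:

* degree — number of incident edges;
* closeness — harmonic centrality, the sum of reciprocal shortest-path
  distances to every reachable node (unreachable nodes contribute 0);
* betweenness — shortest-path betweenness over *ordered* source/target
  pairs, i.e. twice the usual undirected unordered-pair value;
* MCC (maximal clique centrality) — the sum over the maximal cliques C
  containing the node of (|C| - 1)!.

A node is called *essential* when it is dense-rank 1 on all four metrics
simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from tfdegrome.tables import ScoredEdge

METRICS = ("degree", "closeness", "betweenness", "mcc")

#: Default cap on the number of maximal cliques enumerated before giving up.
DEFAULT_CLIQUE_BUDGET = 1_000_000


class CliqueBudgetExceeded(RuntimeError):
    """Maximal-clique enumeration hit its budget; nothing was truncated."""


def build_graph(
    edges: Iterable[ScoredEdge],
    restrict_to: Iterable[str] | None = None,
) -> tuple[nx.Graph, set[str]]:
    """Build the simple undirected graph over the endpoints of the retained
    edges.

    With ``restrict_to``, only edges between listed symbols are kept and the
    second return value reports the listed symbols left without any edge
    (they are not added as isolated nodes).  Duplicate unordered pairs are
    merged keeping the maximum score.
    """
    allowed = {s for s in restrict_to} if restrict_to is not None else None
    g = nx.Graph()
    for e in edges:
        if allowed is not None and (e.a not in allowed or e.b not in allowed):
            continue
        if g.has_edge(e.a, e.b) and g[e.a][e.b]["score"] >= e.score:
            continue
        g.add_edge(e.a, e.b, score=e.score, channels=",".join(sorted(e.channels)))
    unconnected = (allowed - set(g.nodes)) if allowed is not None else set()
    return g, unconnected


def main_component(g: nx.Graph) -> tuple[nx.Graph, set[str]]:
    """The largest connected component and the set of excluded nodes.

    Size ties are broken deterministically by the lexicographically smallest
    sorted node tuple.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no main component")
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    main = set(comps[0])
    excluded = set(g.nodes) - main
    return g.subgraph(main).copy(), excluded


@dataclass(frozen=True)
class TopologyStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    avg_neighbors: float
    transitivity: float


def topology_stats(g: nx.Graph) -> TopologyStats:
    """Whole-graph statistics: mean local clustering coefficient (nodes with
    degree < 2 contribute 0 — the network-analyzer convention) and the
    average neighbor count 2E/N.  Global transitivity is reported alongside
    because the two clustering conventions differ."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = g.number_of_edges()
    return TopologyStats(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=nx.average_clustering(g),
        avg_neighbors=2 * e / n,
        transitivity=nx.transitivity(g),
    )


def _mcc(g: nx.Graph, budget: int) -> dict[str, int]:
    """Maximal clique centrality via exact Bron-Kerbosch enumeration."""
    mcc = dict.fromkeys(g.nodes, 0)
    for i, clique in enumerate(nx.find_cliques(g)):
        if i >= budget:
            raise CliqueBudgetExceeded(
                f"more than {budget} maximal cliques; raise the budget explicitly"
            )
        w = factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    return mcc


def centralities(
    g: nx.Graph,
    clique_budget: int = DEFAULT_CLIQUE_BUDGET,
) -> pd.DataFrame:
    """Per-node degree, harmonic closeness, ordered-pair betweenness, and
    MCC, plus a dense rank per metric (1 = best)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(g.degree())
    closeness = nx.harmonic_centrality(g)
    # networkx sums over unordered pairs for undirected graphs; the ordered
    # convention doubles it.
    betweenness = {
        v: 2.0 * b
        for v, b in nx.betweenness_centrality(g, normalized=False).items()
    }
    mcc = _mcc(g, budget=clique_budget)
    df = pd.DataFrame(
        {
            "node": sorted(g.nodes),
        }
    )
    df["degree"] = df["node"].map(degree)
    df["closeness"] = df["node"].map(closeness)
    df["betweenness"] = df["node"].map(betweenness)
    df["mcc"] = df["node"].map(mcc)
    for m in METRICS:
        df[f"rank_{m}"] = df[m].rank(method="dense", ascending=False).astype(int)
    return df


@dataclass
class EssentialityReport:
    essential: set[str]
    top_per_metric: dict[str, list[tuple[str, float]]]
    rank_split: bool = False
    notes: list[str] = field(default_factory=list)


def rank_essential(records: pd.DataFrame, top_k: int = 3) -> EssentialityReport:
    """Identify essential nodes (dense-rank 1 on all four metrics at once)
    and report the top-k nodes per metric.

    Report ordering inside ties uses MCC, then degree, then symbol; this
    affects presentation only, never the essential set.
    """
    first = records
    for m in METRICS:
        first = first[first[f"rank_{m}"] == 1]
    essential = set(first["node"])
    top = {}
    for m in METRICS:
        best = records.sort_values(
            [m, "mcc", "degree", "node"], ascending=[False, False, False, True]
        ).head(top_k)
        top[m] = list(zip(best["node"], best[m]))
    report = EssentialityReport(essential=essential, top_per_metric=top)
    if not essential:
        report.rank_split = True
        report.notes.append(
            "no single node holds rank 1 on all four metrics; first ranks are split"
        )
    return report


def augment_network(
    g: nx.Graph,
    new_nodes: Iterable[str],
    edges: Iterable[ScoredEdge],
) -> tuple[nx.Graph, set[str]]:
    """Rebuild the graph after adding ``new_nodes``, keeping edges among the
    union of old and new symbols.  New symbols that gain no edge are reported
    as unconnected rather than added as isolates."""
    new_nodes = set(new_nodes)
    allowed = set(g.nodes) | new_nodes
    merged: list[ScoredEdge] = [
        ScoredEdge(
            a=a, b=b, score=d.get("score", 1.0),
            channels=frozenset(c for c in d.get("channels", "").split(",") if c),
        )
        for a, b, d in g.edges(data=True)
    ]
    merged.extend(edges)
    g2, _ = build_graph(merged, restrict_to=allowed)
    unconnected_new = new_nodes - set(g2.nodes)
    return g2, unconnected_new


#: Visual node-size rule used in graph exports: size = 10 x MCC.
MCC_SIZE_FACTOR = 10


def export_graph(
    g: nx.Graph,
    centrality_table: pd.DataFrame,
    path: str | Path,
    fmt: str = "graphml",
) -> None:
    """Export the graph with per-node centrality attributes and the visual
    size attribute (10 x MCC).  Formats: ``graphml`` or ``edgelist`` (a
    re-readable scored edge list)."""
    path = Path(path)
    g = g.copy()
    table = centrality_table.set_index("node")
    for v in g.nodes:
        if v in table.index:
            row = table.loc[v]
            g.nodes[v]["degree"] = int(row["degree"])
            g.nodes[v]["closeness"] = float(row["closeness"])
            g.nodes[v]["betweenness"] = float(row["betweenness"])
            g.nodes[v]["mcc"] = int(row["mcc"])
            g.nodes[v]["size"] = MCC_SIZE_FACTOR * int(row["mcc"])
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        rows = [
            (a, b, f"{d.get('score', 1.0):.3f}") for a, b, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["protein1", "protein2", "score"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def write_centralities(
    records: pd.DataFrame, essential: set[str], path: str | Path
) -> None:
    out = records.copy()
    out["essential"] = out["node"].isin(essential)
    out.to_csv(path, sep="\t", index=False)
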