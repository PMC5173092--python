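"""ceRNA network topology: degree, betweenness, power-law fits, hubs.

The network is an undirected bipartite graph whose edges are the
lncRNA-mRNA pairs that survived the shared-miRNA and co-expression
filters; edge correlations are kept as annotations and shortest paths
are unweighted.

Betweenness is reported twice, because the two textbook phrasings are not
identical: ``betweenness`` is the Brandes pair-fraction sum
sum_{s != t != v} sigma_st(v) / sigma_st over unordered pairs, and
``betweenness_global`` divides the raw count of shortest paths through v
by the total number of shortest paths in the network.  The two differ by
a positive factor per network, so the top-5% ranking used for bottleneck
selection is the same under either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Hub / bottleneck cut: top 5% of the node class, count rounded up.
DEFAULT_TOP_FRACTION = 0.05


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log least-squares fit of a degree distribution."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    fittable: bool = True


def build_network(coexpression_results: pd.DataFrame, passed_column: str = "passed_lmcn") -> nx.Graph:
    """Build the undirected bipartite graph from passing co-expression rows.

    Nodes carry ``gene_class``; edges carry the Pearson ``r`` of the pair.
    Isolated genes never enter; duplicate edges collapse with a warning.
    """
    edges = coexpression_results[coexpression_results[passed_column] == 1]
    if len(edges) == 0:
        raise ValueError("no passing pairs; cannot build an empty network")
    g = nx.Graph()
    seen = set()
    for lnc, mr, r in edges[["lncrna_id", "mrna_id", "r"]].itertuples(index=False):
        if lnc == mr:
            raise ValueError(f"self-loop edge {lnc!r}")
        if (lnc, mr) in seen:
            logger.warning("duplicate edge %s-%s collapsed", lnc, mr)
            continue
        seen.add((lnc, mr))
        g.add_node(lnc, gene_class="lncRNA")
        g.add_node(mr, gene_class="mRNA")
        g.add_edge(lnc, mr, r=float(r))
    logger.info(
        "network: %d lncRNAs, %d mRNAs, %d edges",
        sum(1 for _, c in g.nodes(data="gene_class") if c == "lncRNA"),
        sum(1 for _, c in g.nodes(data="gene_class") if c == "mRNA"),
        g.number_of_edges(),
    )
    return g


def shortest_path_counts(g: nx.Graph) -> dict:
    """sigma[(s, t)] = number of distinct shortest s-t paths, unordered pairs.

    BFS with path-count accumulation from every source; disconnected pairs
    are omitted.
    """
    sigma: dict = {}
    nodes = sorted(g.nodes)
    for s in nodes:
        dist = {s: 0}
        counts = {s: 1}
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in g[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        counts[v] = counts[u]
                        nxt.append(v)
                    elif dist[v] == dist[u] + 1:
                        counts[v] += counts[u]
            queue = nxt
        for t, c in counts.items():
            if s < t:
                sigma[(s, t)] = c
    return sigma


def betweenness(g: nx.Graph) -> pd.DataFrame:
    """Raw and globally normalized betweenness centrality per node.

    ``betweenness`` is the unnormalized Brandes sum over unordered pairs;
    ``betweenness_global`` counts shortest paths through the node and
    divides by the total number of shortest paths between all pairs.
    """
    raw = nx.betweenness_centrality(g, normalized=False)
    sigma = shortest_path_counts(g)
    total_paths = sum(sigma.values())
    # paths through v: sum over pairs of sigma_st(v), i.e. the Brandes sum
    # with sigma_st(v)/sigma_st replaced by the raw count.
    through = dict.fromkeys(g.nodes, 0.0)
    # sigma_st(v) = sigma_sv * sigma_vt when d(s,v)+d(v,t) = d(s,t)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    sig_from = {}
    for s in g.nodes:
        counts = {s: 1}
        order = sorted((d, n) for n, d in dist[s].items())
        for d, n in order:
            if n == s:
                continue
            counts[n] = sum(
                counts[p] for p in g[n] if dist[s].get(p, -1) == d - 1
            )
        sig_from[s] = counts
    for (s, t) in sigma:
        for v in g.nodes:
            if v == s or v == t:
                continue
            ds, dt = dist[s].get(v), dist[t].get(v)
            if ds is None or dt is None or ds + dt != dist[s][t]:
                continue
            through[v] += sig_from[s][v] * sig_from[t][v]
    rows = [
        (
            v,
            float(raw[v]),
            through[v] / total_paths if total_paths else 0.0,
        )
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows, columns=["id", "betweenness", "betweenness_global"]).set_index("id")


def annotate_topology(g: nx.Graph) -> pd.DataFrame:
    """Per-node table: gene_class, degree, both betweenness variants."""
    bc = betweenness(g)
    df = pd.DataFrame(
        {
            "gene_class": pd.Series(dict(g.nodes(data="gene_class"))),
            "degree": pd.Series(dict(g.degree())),
        }
    )
    df = df.join(bc).sort_index()
    df.index.name = "id"
    return df


def fit_power_law(degrees) -> PowerLawFit:
    """Least-squares line on (log10 degree, log10 frequency).

    One point per distinct observed degree >= 1, frequency = number of nodes
    with that degree.  Needs at least 3 distinct degrees; otherwise the fit
    is flagged not fittable.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    degrees = degrees[degrees >= 1]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        return PowerLawFit(float("nan"), float("nan"), float("nan"), len(values), False)
    lx = np.log10(values)
    ly = np.log10(counts)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(slope), float(intercept), float(r2), len(values))


def _top_nodes(table: pd.DataFrame, metric: str, tie_break: str, k: int) -> set:
    ordered = table.sort_values(
        [metric, tie_break, "id"], ascending=[False, False, True], kind="mergesort"
    )
    return set(ordered.head(k)["id"])


def select_hub_bottlenecks(
    topology: pd.DataFrame,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    node_class: str = "lncRNA",
) -> pd.DataFrame:
    """Nodes of a class in the top fraction by BOTH degree and betweenness.

    The cut keeps ceil(top_fraction * class size) nodes per metric; ties at
    the boundary break by the other metric, then lexicographic id, so the
    selection is deterministic.  Returns the class topology table with
    ``is_hub``, ``is_bottleneck`` flags; the hub-bottleneck set is the rows
    with both flags set.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    cls = topology[topology["gene_class"] == node_class].reset_index()
    if len(cls) == 0:
        raise ValueError(f"no nodes of class {node_class!r}")
    k = int(np.ceil(top_fraction * len(cls)))
    hubs = _top_nodes(cls, "degree", "betweenness", k)
    bottlenecks = _top_nodes(cls, "betweenness", "degree", k)
    cls["is_hub"] = cls["id"].isin(hubs).astype(int)
    cls["is_bottleneck"] = cls["id"].isin(bottlenecks).astype(int)
    logger.info(
        "%s: %d hubs, %d bottlenecks, %d hub-bottlenecks (top %.0f%% of %d)",
        node_class,
        len(hubs),
        len(bottlenecks),
        len(hubs & bottlenecks),
        100 * top_fraction,
        len(cls),
    )
    return cls.set_index("id")


def write_gml(g: nx.Graph, path) -> None:
    """GML export for external network viewers."""
    nx.write_gml(g, path)


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        (u, v, g.nodes[u]["gene_class"], g.nodes[v]["gene_class"], d["r"])
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "source_class", "target_class", "r"]
    ).to_csv(path, sep="\t", index=False)
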