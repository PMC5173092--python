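"""Synergistic competing modules: maximal biclique enumeration.

A competing module is a complete bipartite subgraph — every lncRNA in the
module co-expresses with, and shares miRNAs with, every mRNA in it — that
cannot be extended by any further vertex.  Enumeration runs on the
high-competition sub-network by default and is a consensus-style scheme:
seed bicliques from vertex stars, close each candidate mRNA set against the
lncRNA neighborhoods, and repeatedly intersect pairs of found mRNA sets
until no new maximal biclique appears.  Correctness is anchored to an
exhaustive subset-enumeration oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Default module size minima: at least 2 lncRNAs x 3 mRNAs.
DEFAULT_MIN_LNC = 2
DEFAULT_MIN_MRNA = 3


@dataclass(frozen=True)
class BicliqueModule:
    """A maximal complete bipartite module of the ceRNA network."""

    lncrnas: frozenset
    mrnas: frozenset
    mean_r: float = float("nan")

    @property
    def n_edges(self) -> int:
        return len(self.lncrnas) * len(self.mrnas)

    @property
    def size(self) -> int:
        return len(self.lncrnas) + len(self.mrnas)

    def sort_key(self):
        return (-self.size, sorted(self.lncrnas), sorted(self.mrnas))


def _bipartite_adjacency(g: nx.Graph) -> dict:
    adj = {}
    for u, v in g.edges:
        cu = g.nodes[u].get("gene_class")
        cv = g.nodes[v].get("gene_class")
        if {cu, cv} != {"lncRNA", "mRNA"}:
            raise ValueError(f"non-bipartite edge {u!r}-{v!r} ({cu!r}-{cv!r})")
        lnc, mr = (u, v) if cu == "lncRNA" else (v, u)
        adj.setdefault(lnc, set()).add(mr)
    return {l: frozenset(ms) for l, ms in adj.items()}


def enumerate_maximal_bicliques(
    g: nx.Graph, min_lnc: int = DEFAULT_MIN_LNC, min_mrna: int = DEFAULT_MIN_MRNA
) -> list[BicliqueModule]:
    """All maximal bicliques with at least ``min_lnc`` x ``min_mrna`` members.

    Each maximal biclique is reported exactly once, in a deterministic
    order (size descending, then lexicographic ids).
    """
    if min_lnc < 1 or min_mrna < 1:
        raise ValueError("size minima must be >= 1")
    adj = _bipartite_adjacency(g)
    if not adj:
        return []

    def close(mrna_seed: frozenset):
        """Largest biclique whose mRNA side contains the seed."""
        lncs = frozenset(l for l, ms in adj.items() if mrna_seed <= ms)
        if not lncs:
            return None
        mrnas = frozenset.intersection(*(adj[l] for l in lncs))
        return (lncs, mrnas)

    found: set = set()
    queue = []
    all_mrnas = frozenset.union(*adj.values())
    for seed in [adj[l] for l in adj] + [frozenset({m}) for m in all_mrnas]:
        bc = close(seed)
        if bc and bc not in found:
            found.add(bc)
            queue.append(bc)
    # consensus closure: intersections of known mRNA sides may reveal
    # maximal bicliques not generated by any single star
    while queue:
        _, b1 = queue.pop()
        for _, b2 in list(found):
            seed = b1 & b2
            if not seed:
                continue
            bc = close(seed)
            if bc and bc not in found:
                found.add(bc)
                queue.append(bc)
    modules = [
        BicliqueModule(lncs, mrnas)
        for lncs, mrnas in found
        if len(lncs) >= min_lnc and len(mrnas) >= min_mrna
    ]
    modules.sort(key=BicliqueModule.sort_key)
    logger.info(
        "enumerated %d maximal bicliques (minima %dx%d)", len(modules), min_lnc, min_mrna
    )
    return modules


def rank_modules(
    modules: list[BicliqueModule], coexpression_results: pd.DataFrame
) -> list[BicliqueModule]:
    """Attach mean edge correlation and order by (size desc, mean r desc)."""
    r_map = {
        (l, m): r
        for l, m, r in coexpression_results[["lncrna_id", "mrna_id", "r"]].itertuples(
            index=False
        )
    }
    ranked = []
    for mod in modules:
        rs = []
        for l in mod.lncrnas:
            for m in mod.mrnas:
                if (l, m) not in r_map:
                    raise ValueError(f"missing correlation for module edge {l!r}-{m!r}")
                rs.append(r_map[(l, m)])
        ranked.append(BicliqueModule(mod.lncrnas, mod.mrnas, float(sum(rs) / len(rs))))
    ranked.sort(key=lambda mod: (-mod.size, -mod.mean_r, sorted(mod.lncrnas), sorted(mod.mrnas)))
    return ranked


def modules_to_frame(modules: list[BicliqueModule]) -> pd.DataFrame:
    rows = [
        (
            f"module_{i + 1}",
            ",".join(sorted(m.lncrnas)),
            ",".join(sorted(m.mrnas)),
            m.n_edges,
            m.mean_r,
        )
        for i, m in enumerate(modules)
    ]
    return pd.DataFrame(
        rows, columns=["module_id", "lncrna_ids", "mrna_ids", "n_edges", "mean_r"]
    )
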