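"""Guilt-by-association characterization of a focal lncRNA.

An uncharacterized lncRNA is profiled through the mRNAs it competes with:
its network neighbors' expression is hierarchically clustered on both axes
(genes and patients, distance 1 - Pearson r, average linkage), and each
gene cluster is tested for gene-set enrichment with the same hypergeometric
machinery that scores shared miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pairs import bh_fdr, shared_mirna_pvalue

logger = logging.getLogger(__name__)

DEFAULT_N_GENE_CLUSTERS = 4
DEFAULT_N_SAMPLE_GROUPS = 3


def neighbors_of(g: nx.Graph, focal_gene: str) -> list[str]:
    """All network neighbors of the focal gene (its competing partners)."""
    if focal_gene not in g:
        raise ValueError(f"focal gene {focal_gene!r} not in network")
    neighbors = sorted(g[focal_gene])
    if not neighbors:
        logger.warning("focal gene %s is isolated; no neighbors", focal_gene)
    return neighbors


@dataclass(frozen=True)
class ClusterAssignment:
    """Two-axis hierarchical clustering of an expression submatrix."""

    gene_labels: pd.Series     # gene id -> cluster label (1..k)
    sample_labels: pd.Series   # sample id -> group label (1..g)
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances between rows; constant rows -> max."""
    sd = matrix.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant vectors fall back to maximum distance", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    return squareform(np.clip(dist, 0, 2), checks=False)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    n_gene_clusters: int = DEFAULT_N_GENE_CLUSTERS,
    n_sample_groups: int = DEFAULT_N_SAMPLE_GROUPS,
) -> ClusterAssignment:
    """Agglomerative clustering of genes (rows) and samples (columns).

    Average linkage on 1 - Pearson distances, trees cut to the requested
    cluster counts with scipy's maxclust criterion.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples to cluster")
    if not 1 <= n_gene_clusters <= matrix.shape[0]:
        raise ValueError("n_gene_clusters out of range")
    if not 1 <= n_sample_groups <= matrix.shape[1]:
        raise ValueError("n_sample_groups out of range")
    values = matrix.to_numpy(dtype=float)
    gene_link = hierarchy.average(_correlation_distance(values))
    sample_link = hierarchy.average(_correlation_distance(values.T))
    gene_labels = hierarchy.fcluster(gene_link, n_gene_clusters, criterion="maxclust")
    sample_labels = hierarchy.fcluster(sample_link, n_sample_groups, criterion="maxclust")
    return ClusterAssignment(
        pd.Series(gene_labels, index=matrix.index),
        pd.Series(sample_labels, index=matrix.columns),
        gene_link,
        sample_link,
    )


# ---------------------------------------------------------------------------
# Gene sets


def load_gmt(path) -> dict[str, frozenset]:
    """Read a GMT collection: set name, description, then member genes."""
    collection: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT rows need name, description, >=1 gene")
            name, genes = parts[0], frozenset(g for g in parts[2:] if g)
            if name in collection:
                raise ValueError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{line_no}: empty gene set {name!r}")
            collection[name] = genes
    if not collection:
        raise ValueError(f"no gene sets in {path}")
    return collection


def geneset_enrichment(
    cluster_genes, background_genes, collection: dict[str, frozenset]
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene cluster against a collection.

    For each set, p = P(X >= overlap) with universe = background; BH FDR
    across the sets of the collection.  Gene-set members outside the
    background are ignored.
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not cluster:
        raise ValueError("empty gene cluster")
    if not cluster <= background:
        raise ValueError("cluster genes must be a subset of the background")
    if not collection:
        raise ValueError("empty gene-set collection")
    N = len(background)
    K = len(cluster)
    rows = []
    for name in sorted(collection):
        members = collection[name] & background
        overlap = len(cluster & members)
        M = len(members)
        p = shared_mirna_pvalue(N, K, M, min(overlap, min(K, M)), tail="at_least") if M else 1.0
        rows.append((name, overlap, M, K, p))
    df = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "cluster_size", "p_value"]
    )
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "set_name"]).reset_index(drop=True)
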