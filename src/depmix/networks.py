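"""Intra-cluster connectivity graphs of co-dependent genes.

Genes in one consensus cluster need not all be mutually correlated —
membership only requires correlation with some cluster member.  The
connectivity graph makes that structure explicit: nodes are the cluster
genes, and an edge joins two genes whose dependency profiles have
Spearman correlation above a cutoff (0.1 by default, one-sided: strong
negative correlation never creates an edge).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import DependencyMatrix

__all__ = ["connectivity_graph", "export_graphml", "import_graphml",
           "edge_list"]


def _spearman(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(float)
    if np.isnan(arr).any():
        return values.T.corr(method="spearman").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(rankdata(arr, axis=1))


def connectivity_graph(cluster_genes: Iterable[str],
                       matrix: DependencyMatrix,
                       rho_min: float = 0.1,
                       membership: Mapping[str, str] | None = None,
                       ) -> nx.Graph:
    """Graph over ``cluster_genes`` with edges where Spearman rho > rho_min.

    Correlations are computed over pairwise-complete cell lines.  Edge
    weights carry rho; node attribute ``cluster`` carries the (small-)
    cluster membership when given.  Gene input order does not affect the
    result: nodes are sorted.
    """
    genes = sorted(dict.fromkeys(cluster_genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing[:5]}")
    sub = matrix.values.loc[genes]
    rho = _spearman(sub)

    g = nx.Graph(rho_min=float(rho_min))
    for gene in genes:
        attrs = {}
        if membership is not None and gene in membership:
            attrs["cluster"] = str(membership[gene])
        g.add_node(gene, **attrs)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = rho[i, j]
            if np.isfinite(r) and r > rho_min:
                g.add_edge(genes[i], genes[j], weight=float(r))
    return g


def export_graphml(graph: nx.Graph, path) -> None:
    """Write the graph as GraphML (weights and memberships preserved)."""
    nx.write_graphml(graph, path)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Edges as a TSV-ready frame sorted by descending weight."""
    rows = [(u, v, d.get("weight", np.nan))
            for u, v, d in graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "spearman_rho"])
    return df.sort_values("spearman_rho", ascending=False,
                          kind="stable").reset_index(drop=True)
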