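"""Weighted co-expression network over selected DEGs.

Every unordered pair of genes becomes an edge whose weight is the
Spearman rank correlation (SRCC) of the two genes' expression across all
samples, so a network over n genes is complete with n(n-1)/2 edges. A
high-confidence subnetwork keeps edges with |SRCC| strictly above a
threshold (0.8 in the published screen). Anti-correlation is co-expression
evidence too, so thresholding and voting use |SRCC| while the signed value
is kept on the edge; ``signed=True`` restricts to positive correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import NetworkError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


def spearman_matrix(matrix: ExpressionMatrix, gene_subset=None) -> pd.DataFrame:
    """Pairwise SRCC of the given genes across all samples.

    Mid-ranks (average ranks) are used for ties, i.e. each entry is the
    Pearson correlation of the two genes' rank vectors. A constant gene
    has undefined correlations; those entries are set to 0 with a warning
    so the matrix keeps its shape. Diagonal is 1.
    """
    genes = list(gene_subset) if gene_subset is not None else matrix.gene_ids
    sub = matrix.subset(genes)
    if sub.n_samples < 3:
        raise NetworkError("need at least 3 samples for rank correlations")
    x = sub.values.to_numpy(float)
    constant = np.ptp(x, axis=1) == 0
    if len(genes) == 1:
        corr = np.ones((1, 1))
    else:
        corr = np.asarray(stats.spearmanr(x, axis=1).statistic, float)
        if corr.ndim == 0:  # scipy collapses the 2-variable case to a scalar
            c = float(corr)
            corr = np.array([[1.0, c], [c, 1.0]])
    if constant.any():
        log.warning(
            "%d constant gene(s); their correlations are undefined and set to 0",
            int(constant.sum()),
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph over genes; thin wrapper around networkx.

    Edge attributes: ``weight`` (signed SRCC) and ``abs_weight``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def weight_matrix(self, nodes=None, absolute: bool = True) -> pd.DataFrame:
        """Dense weight matrix (zero diagonal), ordered by ``nodes``."""
        order = list(nodes) if nodes is not None else self.nodes
        attr = "abs_weight" if absolute else "weight"
        w = nx.to_numpy_array(self.graph, nodelist=order, weight=attr)
        return pd.DataFrame(w, index=order, columns=order)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (min(u, v), max(u, v), d["weight"], d["abs_weight"])
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "abs_weight"])

    def to_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(srcc: pd.DataFrame) -> CoexpressionNetwork:
    """Complete weighted network from a symmetric SRCC matrix.

    Every unordered gene pair becomes one edge, so n genes give exactly
    n(n-1)/2 edges; no self-edges.
    """
    genes = list(srcc.index)
    if len(genes) < 2:
        raise NetworkError("need at least 2 genes to build a network")
    vals = srcc.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise NetworkError("SRCC matrix is not symmetric")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = float(vals[i, j])
            g.add_edge(genes[i], genes[j], weight=w, abs_weight=abs(w))
    return CoexpressionNetwork(g)


def node_degrees(net: CoexpressionNetwork, top_k: int = 7) -> list[tuple[str, int]]:
    """Hub genes: nodes ranked by degree, descending.

    Ties break by gene id ascending so the ranking is deterministic.
    Returns at most ``top_k`` pairs (all nodes if top_k exceeds the count).
    """
    if net.n_nodes == 0:
        raise NetworkError("empty network")
    ranked = sorted(net.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return ranked[: min(top_k, len(ranked))]


def threshold_subnetwork(
    net: CoexpressionNetwork, min_weight: float = 0.8, signed: bool = False
) -> CoexpressionNetwork:
    """High-confidence subnetwork: edges with |weight| strictly above min_weight.

    ``signed=True`` keeps only positive correlations above the cut.
    Isolated nodes are dropped; the result may be empty (logged).
    """
    if not 0.0 <= min_weight <= 1.0:
        raise NetworkError("min_weight must lie in [0, 1]")
    sub = nx.Graph()
    for u, v, d in net.graph.edges(data=True):
        value = d["weight"] if signed else d["abs_weight"]
        if value > min_weight:
            sub.add_edge(u, v, **d)
    if sub.number_of_edges() == 0:
        log.warning("no edge exceeds |weight| > %g; subnetwork is empty", min_weight)
    return CoexpressionNetwork(sub)
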