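"""Gene networks: PPI edge-list ingest and mutual k-nearest-neighbor
co-expression graph construction.

Both sources yield the same object, an undirected simple :class:`GeneNetwork`
(no self-edges, no parallel edges, isolated nodes allowed), so downstream
feature construction treats them identically.

The co-expression graph connects two genes only if each ranks the other
among its top-k most correlated partners (mutual kNN). By default "most
co-expressed" means largest signed Pearson correlation; ranking by absolute
correlation is available via ``ranking="absolute"``. Correlation ties at the
k-th rank are broken deterministically by lexicographic gene id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


class GeneNetwork:
    """An undirected simple graph over gene ids.

    Thin wrapper around :class:`networkx.Graph` that enforces the simple-graph
    invariants on construction and carries provenance (how the network was
    built and with which parameters).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        provenance: Optional[dict] = None,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                continue  # self-edges carry no geneset information
            g.add_edge(a, b)
        self._graph = g
        self.provenance = dict(provenance or {})

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted id pairs (canonical unordered representation)."""
        return {tuple(sorted((a, b))) for a, b in self._graph.edges}

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def degree(self, gene: str) -> int:
        if gene not in self._graph:
            raise ValidationError(f"gene {gene!r} not in network")
        return int(self._graph.degree[gene])

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self._graph:
            raise ValidationError(f"gene {gene!r} not in network")
        return set(self._graph.neighbors(gene))

    def sorted_nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __repr__(self) -> str:  # pragma: no cover
        kind = self.provenance.get("kind", "network")
        return f"GeneNetwork({kind}: {self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class CoexpressionConfig:
    """Parameters of mutual-kNN co-expression graph construction.

    k is the neighbor count; ranking is "signed" (default, largest Pearson
    correlation) or "absolute"; if target_edges is set, k is chosen as the
    smallest value whose edge count reaches the target.
    """

    k: int = 84
    ranking: str = "signed"
    target_edges: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.ranking not in ("signed", "absolute"):
            raise ValidationError("ranking must be 'signed' or 'absolute'")
        if self.target_edges is not None and self.target_edges < 1:
            raise ValidationError("target_edges must be positive")


@dataclass
class KSelectionReport:
    """Result of searching k to match a target edge count."""

    k: int
    target_edges: int
    edges_at_k: int
    edges_below_k: int  # edge count at k-1 (0 for k=1)


@dataclass
class DegreeSummary:
    n_genes: int
    mean_degree: float
    median_degree: float


# -- PPI ingest -------------------------------------------------------------


def load_edge_list(path: str | Path, universe: Iterable[str]) -> GeneNetwork:
    """Load a two-column interaction edge list restricted to a gene universe.

    Self-edges are dropped, duplicate and reversed-duplicate pairs are
    collapsed, and edges with an endpoint outside the universe are removed.
    Every universe gene is a node, so isolated (degree-0) genes are retained.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValidationError("gene universe is empty")
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValidationError(f"edge list {path} needs two columns")
    pairs = [
        (str(a), str(b))
        for a, b in table.iloc[:, :2].itertuples(index=False)
        if str(a) != str(b) and str(a) in universe and str(b) in universe
    ]
    net = GeneNetwork(
        edges=pairs,
        nodes=universe,
        provenance={"kind": "ppi", "source": str(path)},
    )
    if net.n_edges == 0:
        warnings.warn(
            f"edge list {path} is empty after universe restriction; "
            "downstream genesets degenerate to single genes",
            UserWarning,
            stacklevel=2,
        )
    return net


# -- mutual kNN -------------------------------------------------------------


def _neighbor_ranks(dataset: ExpressionDataset, ranking: str) -> np.ndarray:
    """rank[i, j] = position (1-based) of gene j in gene i's co-expression
    ordering (self excluded, pushed to the last rank).

    Ties are broken by lexicographic gene id, so ranks are a deterministic
    permutation for every row.
    """
    vals = dataset.values.to_numpy(dtype=float)
    n = vals.shape[0]
    if vals.shape[1] < 3:
        raise ValidationError("mutual-kNN needs at least 3 patients")
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = dataset.values.index[np.argmax(sd == 0)]
        raise ValidationError(
            f"gene {bad!r} has zero variance; Pearson correlation undefined"
        )
    corr = np.corrcoef(vals)
    score = np.abs(corr) if ranking == "absolute" else corr
    np.fill_diagonal(score, -np.inf)
    # lexicographic tie-break: secondary key is gene-id order
    lex = np.argsort(np.argsort(np.asarray(dataset.values.index.astype(str))))
    ranks = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((lex, -score[i]))
        ranks[i, order] = np.arange(1, n + 1)
    return ranks


def build_mutual_knn(
    dataset: ExpressionDataset, config: CoexpressionConfig
) -> GeneNetwork:
    """Build the mutual-kNN co-expression graph.

    Edge {g, h} is present iff h is within g's top-k most co-expressed genes
    AND g is within h's top-k, by Pearson correlation over all patients
    pooled. Symmetric by construction; no self-edges; every gene is a node.
    """
    k = config.k
    if config.target_edges is not None:
        report = choose_k_for_edge_count(
            dataset, config.target_edges, ranking=config.ranking
        )
        k = report.k
        logger.info(
            "selected k=%d for target %d edges (count %d)",
            k,
            config.target_edges,
            report.edges_at_k,
        )
    ranks = _neighbor_ranks(dataset, config.ranking)
    mutual = np.maximum(ranks, ranks.T)
    ii, jj = np.nonzero(np.triu(mutual <= k, k=1))
    genes = list(dataset.values.index.astype(str))
    edges = [(genes[i], genes[j]) for i, j in zip(ii, jj)]
    return GeneNetwork(
        edges=edges,
        nodes=genes,
        provenance={"kind": "coexpression", "k": int(k), "ranking": config.ranking},
    )


def choose_k_for_edge_count(
    dataset: ExpressionDataset, target_edges: int, ranking: str = "signed"
) -> KSelectionReport:
    """Smallest k whose mutual-kNN edge count meets or exceeds the target.

    The mutual-kNN edge count is nondecreasing in k (an edge present at k
    stays present at k+1), so the answer is well defined whenever the target
    does not exceed the complete-graph edge count.
    """
    n = dataset.n_genes
    max_edges = n * (n - 1) // 2
    if target_edges < 1 or target_edges > max_edges:
        raise ValidationError(
            f"target {target_edges} not achievable: complete graph on "
            f"{n} genes has {max_edges} edges"
        )
    ranks = _neighbor_ranks(dataset, ranking)
    mutual = np.maximum(ranks, ranks.T)[np.triu_indices(n, k=1)]
    mutual.sort()
    k = int(mutual[target_edges - 1])
    edges_at_k = int(np.searchsorted(mutual, k, side="right"))
    edges_below = int(np.searchsorted(mutual, k - 1, side="right"))
    return KSelectionReport(
        k=k, target_edges=target_edges, edges_at_k=edges_at_k, edges_below_k=edges_below
    )


def degree_summary(
    network: GeneNetwork, gene_subset: Optional[Iterable[str]] = None
) -> DegreeSummary:
    """Mean and median degree over a gene subset (default all nodes).

    Degree counts edges incident in the full network, so a subset gene's
    degree includes neighbors outside the subset.
    """
    genes = network.sorted_nodes() if gene_subset is None else sorted(set(gene_subset))
    degrees = np.array([network.degree(g) for g in genes], dtype=float)
    if degrees.size == 0:
        raise ValidationError("empty gene subset")
    return DegreeSummary(
        n_genes=len(genes),
        mean_degree=float(degrees.mean()),
        median_degree=float(np.median(degrees)),
    )


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Serialize as a sorted two-column TSV (bit-reproducible)."""
    pd.DataFrame(network.sorted_edges(), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


__all__ = [
    "GeneNetwork",
    "CoexpressionConfig",
    "KSelectionReport",
    "DegreeSummary",
    "load_edge_list",
    "build_mutual_knn",
    "choose_k_for_edge_count",
    "degree_summary",
    "write_edge_list",
]
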