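"""Markov Clustering (MCL) and the enrichment-scored inflation sweep.

MCL simulates flow on the graph: a column-stochastic transition matrix is
alternately squared (expansion, spreading flow) and raised elementwise to
the inflation power with column renormalization (inflation, strengthening
strong flow).  Flow condenses onto attractors; clusters are read from the
attractor rows at convergence.  Larger inflation yields finer clusters.

The inflation parameter is tuned the way practitioners tune it for
co-expression networks: run a grid of inflations, score each clustering by
hypergeometric term enrichment against the whole-network background, and
keep the inflation producing the most enriched clusters (ties: most
enriched terms per enriched cluster, then the smallest inflation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .enrichment import hypergeom_enrichment

DEFAULT_INFLATION_GRID = np.round(np.arange(1.0, 5.0001, 0.1), 10)


@dataclass
class ClusterSet:
    """Disjoint gene clusters with provenance."""

    clusters: list[set]
    method: str
    parameter: float
    unassigned: set = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict:
        """gene → 1-based cluster index (largest cluster first), 0 = unassigned."""
        out = {g: 0 for g in self.unassigned}
        for k, cl in enumerate(sorted(self.clusters, key=len, reverse=True), start=1):
            for g in cl:
                out[g] = k
        return out

    def to_tsv(self, path) -> None:
        labels = self.labels()
        pd.DataFrame(sorted(labels.items()), columns=["gene", "cluster"]).to_csv(
            path, sep="\t", index=False
        )


class MarkovClustering(BaseEstimator, ClusterMixin):
    """MCL as an sklearn-style clusterer over a precomputed adjacency.

    ``fit(X)`` takes a symmetric non-negative adjacency matrix (self-loops
    of weight 1 are added before column normalization).  After convergence
    the attractor rows define the clusters; a node supported by several
    attractor systems is assigned to the one receiving its largest flow,
    ties going to the system containing the smallest attractor index.

    Attributes
    ----------
    labels_ : integer cluster label per node (0-based)
    n_iter_ : iterations run
    converged_ : whether the iteration reached ``conv_tol``
    """

    def __init__(
        self,
        inflation: float = 2.0,
        max_iter: int = 200,
        prune_eps: float = 1e-6,
        conv_tol: float = 1e-8,
        add_self_loops: bool = True,
    ):
        self.inflation = inflation
        self.max_iter = max_iter
        self.prune_eps = prune_eps
        self.conv_tol = conv_tol
        self.add_self_loops = add_self_loops

    @staticmethod
    def _normalize(M: np.ndarray) -> np.ndarray:
        colsum = M.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return M / colsum

    def fit(self, X, y=None):
        A = np.asarray(getattr(X, "values", X), dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("expected a square adjacency matrix")
        if (A < 0).any():
            raise ValueError("adjacency must be non-negative")
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")
        n = A.shape[0]
        A = A.copy()
        if self.add_self_loops:
            np.fill_diagonal(A, np.maximum(A.diagonal(), 1.0))
        M = self._normalize(A)
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = M
            M = M @ M                       # expansion
            M = M ** self.inflation         # inflation
            M[M < self.prune_eps] = 0.0
            M = self._normalize(M)
            if np.abs(M - prev).max() < self.conv_tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        if not self.converged_:
            warnings.warn(
                f"MCL did not converge in {self.max_iter} iterations; "
                "using the final iterate", RuntimeWarning,
            )
        self.flow_ = M
        self.labels_ = self._read_clusters(M)
        return self

    def _read_clusters(self, M: np.ndarray) -> np.ndarray:
        n = M.shape[0]
        eps = 1e-6
        attractors = np.nonzero(M.diagonal() > eps)[0]
        if attractors.size == 0:
            # pathological (non-converged) state: every node its own cluster
            return np.arange(n)
        # attractor systems: attractors sharing flow belong to one cluster
        parent = {int(a): int(a) for a in attractors}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        attractor_set = set(int(a) for a in attractors)
        for a in attractors:
            for b in np.nonzero(M[a] > eps)[0]:
                if int(b) in attractor_set:
                    ra, rb = find(int(a)), find(int(b))
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        systems: dict[int, list[int]] = {}
        for a in attractor_set:
            systems.setdefault(find(a), []).append(a)
        roots = sorted(systems)
        labels = np.full(n, -1, dtype=int)
        # flow received by node j from each attractor system
        # roots are ascending, so a strictly-greater test breaks ties toward
        # the system containing the smallest attractor index
        for j in range(n):
            best_root, best_flow = -1, 0.0
            for root in roots:
                flow = float(M[systems[root], j].sum())
                if flow > best_flow + 1e-15:
                    best_root, best_flow = root, flow
            if best_flow > eps:
                labels[j] = best_root
        # nodes with no flow anywhere become singletons
        for j in np.nonzero(labels < 0)[0]:
            labels[j] = n + j
        # relabel to consecutive 0..k-1 in order of smallest member
        order: dict[int, int] = {}
        for j in range(n):
            order.setdefault(labels[j], len(order))
        return np.array([order[l] for l in labels], dtype=int)


def _graph_adjacency(net: nx.Graph, weighted: bool) -> tuple[list, np.ndarray]:
    nodes = sorted(net.nodes())
    A = nx.to_numpy_array(net, nodelist=nodes, weight="score" if weighted else None)
    return nodes, A


def mcl(
    net: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune_eps: float = 1e-6,
    conv_tol: float = 1e-8,
    weighted: bool = False,
) -> ClusterSet:
    """Run MCL on a gene network and return named clusters."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    nodes, A = _graph_adjacency(net, weighted)
    est = MarkovClustering(
        inflation=inflation, max_iter=max_iter, prune_eps=prune_eps, conv_tol=conv_tol
    ).fit(A)
    clusters: dict[int, set] = {}
    for node, lab in zip(nodes, est.labels_):
        clusters.setdefault(int(lab), set()).add(node)
    return ClusterSet(
        clusters=sorted(clusters.values(), key=lambda s: (-len(s), sorted(s)[0])),
        method="mcl",
        parameter=float(inflation),
    )


@dataclass
class SweepRecord:
    inflation: float
    n_clusters: int
    n_enriched_clusters: int
    n_enriched_terms: int
    terms_per_enriched_cluster: float


def inflation_sweep(
    net: nx.Graph,
    annotation: Mapping[str, set],
    inflations: Sequence[float] | None = None,
    alpha_fdr: float = 0.05,
    min_cluster_size: int = 5,
    weighted: bool = False,
) -> tuple[float | None, list[SweepRecord], dict[float, ClusterSet]]:
    """Tune MCL inflation by term enrichment against the network background.

    Returns the optimal inflation (None when no clustering yields any
    enriched cluster), the per-inflation report, and the clusterings.
    """
    if inflations is None:
        inflations = DEFAULT_INFLATION_GRID
    inflations = list(inflations)
    if not inflations:
        raise ValueError("empty inflation grid")
    background = set(net.nodes())
    report: list[SweepRecord] = []
    clusterings: dict[float, ClusterSet] = {}
    for inf in inflations:
        cs = mcl(net, inflation=inf, weighted=weighted)
        clusterings[inf] = cs
        res = hypergeom_enrichment(
            cs, annotation, background, alpha_fdr=alpha_fdr,
            min_cluster_size=min_cluster_size,
        )
        sig = res[res["significant"]] if len(res) else res
        n_enriched_clusters = sig["cluster"].nunique() if len(sig) else 0
        n_terms = len(sig)
        report.append(SweepRecord(
            inflation=float(inf),
            n_clusters=cs.n_clusters,
            n_enriched_clusters=int(n_enriched_clusters),
            n_enriched_terms=int(n_terms),
            terms_per_enriched_cluster=(n_terms / n_enriched_clusters) if n_enriched_clusters else 0.0,
        ))
    enriched = [r for r in report if r.n_enriched_clusters > 0]
    if not enriched:
        return None, report, clusterings
    best = max(enriched, key=lambda r: (r.n_enriched_clusters, r.terms_per_enriched_cluster, -r.inflation))
    return best.inflation, report, clusterings
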