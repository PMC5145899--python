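"""Thresholded co-expression networks and their topology statistics.

A network is built by keeping gene pairs whose score passes a cutoff
(correlations: score >= cutoff; mutual rank: score <= cutoff).  The cutoff
itself is calibrated by scanning a grid and picking the cutoff that
minimizes network density over the surviving (degree >= 1) nodes, which
maximizes the clustering potential of the thresholded graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import MUTUAL_RANK, CorrelationMatrix

logger = logging.getLogger(__name__)

DEFAULT_PCC_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 10)
DEFAULT_MR_GRID = np.arange(5, 201, 5)


@dataclass
class DensityRecord:
    cutoff: float
    density: float | None
    n_nodes: int
    n_edges: int


def _edge_mask(corr: CorrelationMatrix, cutoff: float) -> np.ndarray:
    """Upper-triangular boolean mask of pairs passing the cutoff."""
    v = corr.values
    if corr.kind == MUTUAL_RANK:
        passing = v <= cutoff
    else:
        passing = v >= cutoff
    passing = passing & ~np.isnan(v)
    iu = np.triu_indices(corr.n, k=1)
    mask = np.zeros_like(passing)
    mask[iu] = passing[iu]
    return mask


def build_network(
    corr: CorrelationMatrix,
    cutoff: float,
    direction: str | None = None,
    exclude_same_gene: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected gene network.

    Only nodes with at least one surviving edge are included.  When a probe →
    gene map is given, edges between two probes of the same gene model are
    discarded.  ``direction`` may assert the comparison sense
    ('ge_for_pcc' / 'le_for_mr'); it must agree with the matrix kind.
    """
    expected = "le_for_mr" if corr.kind == MUTUAL_RANK else "ge_for_pcc"
    if direction is not None and direction != expected:
        raise ValueError(f"direction {direction!r} inconsistent with kind {corr.kind!r}")
    mask = _edge_mask(corr, cutoff)
    ii, jj = np.nonzero(mask)
    net = nx.Graph()
    ids = corr.ids
    v = corr.values
    n_same_gene = 0
    for i, j in zip(ii.tolist(), jj.tolist()):
        a, b = ids[i], ids[j]
        if exclude_same_gene is not None and exclude_same_gene.get(a) is not None \
                and exclude_same_gene.get(a) == exclude_same_gene.get(b):
            n_same_gene += 1
            continue
        net.add_edge(a, b, score=float(v[i, j]))
    if n_same_gene:
        logger.info("discarded %d edges between probes of the same gene model", n_same_gene)
    net.graph["kind"] = corr.kind
    net.graph["cutoff"] = float(cutoff)
    net.graph["universe"] = list(ids)
    return net


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """E / (N(N-1)/2): the edge count over all possible edges."""
    if n_nodes < 2:
        raise ValueError("density requires at least 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2.0)


def network_density(net: nx.Graph) -> float:
    """Density over the surviving (degree >= 1) nodes."""
    if net.number_of_nodes() < 2:
        raise ValueError("density requires at least 2 nodes")
    return density_from_counts(net.number_of_nodes(), net.number_of_edges())


def density_curve(corr: CorrelationMatrix, cutoffs: Sequence[float] | None = None) -> list[DensityRecord]:
    """Density, node and edge counts at each cutoff of a grid.

    Cutoffs where fewer than 2 nodes survive yield a null density record.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_MR_GRID if corr.kind == MUTUAL_RANK else DEFAULT_PCC_GRID
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff grid")
    records = []
    for c in cutoffs:
        mask = _edge_mask(corr, c)
        n_edges = int(mask.sum())
        deg = mask.sum(axis=0) + mask.sum(axis=1)
        n_nodes = int((deg > 0).sum())
        density = density_from_counts(n_nodes, n_edges) if n_nodes >= 2 else None
        records.append(DensityRecord(float(c), density, n_nodes, n_edges))
    return records


def select_pcc_cutoff(curve: Sequence[DensityRecord]) -> float:
    """Cutoff of minimum density; ties broken toward the smallest cutoff."""
    valid = [r for r in curve if r.density is not None]
    if not valid:
        raise ValueError("density curve contains no valid records")
    best = min(valid, key=lambda r: (r.density, r.cutoff))
    return best.cutoff


def clustering_coefficients(
    net: nx.Graph, require_degree2: bool = False
) -> tuple[dict, float]:
    """Per-node clustering coefficient C_n = 2 e_n / (k_n (k_n - 1)).

    e_n counts connected pairs among the neighbors of n.  Degree-0/1 nodes
    get C_n = 0; the network value is the mean over all nodes, or over
    degree >= 2 nodes when ``require_degree2``.
    """
    per_node = nx.clustering(net)
    if not per_node:
        return {}, 0.0
    if require_degree2:
        eligible = [c for node, c in per_node.items() if net.degree(node) >= 2]
        mean = float(np.mean(eligible)) if eligible else 0.0
    else:
        mean = float(np.mean(list(per_node.values())))
    return per_node, mean


def components(net: nx.Graph) -> list[set]:
    """Connected components, largest first."""
    return sorted(nx.connected_components(net), key=len, reverse=True)


def path_stats(net: nx.Graph) -> tuple[float, int]:
    """Characteristic path length and shortest-path count.

    The length is the mean breadth-first distance over all ordered reachable
    pairs; the count is the number of such pairs.  Multi-component graphs
    simply contribute no cross-component pairs.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("path statistics of an empty network are undefined")
    total = 0
    n_pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            if target != source:
                total += d
                n_pairs += 1
    mean = total / n_pairs if n_pairs else 0.0
    return mean, n_pairs


def degree_powerlaw_fit(net: nx.Graph) -> tuple[float, float]:
    """Least-squares slope and R² of log10(frequency) on log10(degree).

    Zero-frequency degree bins are excluded; a graph with fewer than three
    distinct positive degrees has no meaningful fit and raises.
    """
    degrees = np.array([d for _, d in net.degree() if d > 0])
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValueError("power-law fit requires at least 3 distinct degrees")
    x = np.log10(values.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def mr_disconnected_fraction(
    corr: CorrelationMatrix, cutoffs: Sequence[float] | None = None
) -> list[tuple[float, float]]:
    """Fraction of genes with no partner at MR <= cutoff, per grid cutoff."""
    if corr.kind != MUTUAL_RANK:
        raise ValueError("mr_disconnected_fraction requires a mutual_rank matrix")
    if cutoffs is None:
        cutoffs = DEFAULT_MR_GRID
    v = corr.values.copy()
    np.fill_diagonal(v, np.inf)
    v[np.isnan(v)] = np.inf
    best = v.min(axis=1)
    return [(float(c), float((best > c).mean())) for c in cutoffs]


def direct_neighbors(net: nx.Graph, genes: Iterable[str]) -> pd.DataFrame:
    """Adjacent nodes and edge scores for each query gene.

    Queries absent from the network simply contribute no rows.
    """
    rows = []
    for g in genes:
        if g not in net:
            continue
        for nb in net.neighbors(g):
            rows.append((g, nb, net.edges[g, nb].get("score", np.nan)))
    return pd.DataFrame(rows, columns=["query", "neighbor", "score"])


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [(a, b, d.get("score", 1.0)) for a, b, d in net.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(path, sep="\t", index=False)
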