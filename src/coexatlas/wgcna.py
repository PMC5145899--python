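"""Soft-threshold weighted co-expression network.

Instead of a hard correlation cutoff, the absolute correlation is raised to
a power β chosen as the smallest exponent whose connectivity distribution
approximates a power law (scale-free topology).  The resulting adjacency
a_ij = |corr|^β is converted to a topological overlap matrix (TOM), which
scores neighborhood sharing; modules are cut from an average-linkage tree
of the TOM dissimilarity 1 − TOM, and each module is summarized by its
eigengene (the first principal component of the module's standardized
expression), against which per-gene module membership is correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .atlas import ExpressionAtlas
from .correlation import CorrelationMatrix
from .mcl import ClusterSet

DEFAULT_BETAS = tuple(range(1, 21))
DEFAULT_R2_MIN = 0.8
DEFAULT_N_BINS = 10


@dataclass
class SoftNetwork:
    """Soft-thresholded adjacency a_ij = |corr_ij|^β (diagonal zeroed)."""

    ids: list[str]
    adjacency: np.ndarray
    beta: int

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class PowerFitRecord:
    beta: int
    r2_signed: float | None
    slope: float | None


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = DEFAULT_N_BINS):
    """Signed R² of the binned log-log connectivity/frequency regression.

    Connectivities are binned into ``n_bins`` equal-width bins; zero-frequency
    and non-positive-mean bins are excluded.  The signed R² is
    -sign(slope) · R², so a passing fit requires a decreasing frequency.
    Returns (signed R², slope) or (None, None) when the fit is undefined.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.allclose(k, k[0]):
        return None, None
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        means.append(members.mean())
        freqs.append(members.size)
    if len(means) < 3:
        return None, None
    x = np.log10(np.array(means))
    y = np.log10(np.array(freqs, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return None, None
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot
    return -np.sign(slope) * r2, float(slope)


def select_soft_power(
    corr: CorrelationMatrix,
    betas: Sequence[int] = DEFAULT_BETAS,
    r2_min: float = DEFAULT_R2_MIN,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[int | None, list[PowerFitRecord]]:
    """Lowest β whose soft adjacency meets the scale-free fit threshold."""
    betas = sorted(int(b) for b in betas)
    table: list[PowerFitRecord] = []
    chosen = None
    base = np.abs(corr.values).copy()
    np.fill_diagonal(base, 0.0)
    for beta in betas:
        k = (base ** beta).sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins=n_bins)
        table.append(PowerFitRecord(beta, r2, slope))
        if chosen is None and r2 is not None and r2 >= r2_min:
            chosen = beta
    return chosen, table


def soft_adjacency(corr: CorrelationMatrix, beta: int) -> SoftNetwork:
    """Raise |correlation| to the power β; diagonal excluded from connectivity."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = np.abs(corr.values) ** beta
    np.fill_diagonal(A, 0.0)
    return SoftNetwork(ids=list(corr.ids), adjacency=A, beta=int(beta))


def topological_overlap(net: SoftNetwork) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), TOM_ii = 1.

    l_ij sums shared-neighbor adjacency products; the zero diagonal of the
    adjacency keeps i and j themselves out of the sum.
    """
    A = net.adjacency
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.asarray(tom)
    tom[~np.isfinite(tom)] = 0.0
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return tom


class TreeCutModules(BaseEstimator, ClusterMixin):
    """Static-height branch cut of an average-linkage TOM dendrogram.

    ``fit(X)`` takes a TOM similarity matrix; clustering runs on the
    dissimilarity 1 − TOM.  ``cut_height`` is relative to the tallest merge
    (default 0.99 of the tree maximum); branches below it with at least
    ``min_module_size`` leaves become modules, everything else is labeled 0
    (unassigned).
    """

    def __init__(self, min_module_size: int = 30, cut_height: float = 0.99):
        self.min_module_size = min_module_size
        self.cut_height = cut_height

    def fit(self, X, y=None):
        tom = np.asarray(getattr(X, "values", X), dtype=float)
        n = tom.shape[0]
        if n < 2:
            self.labels_ = np.zeros(n, dtype=int)
            return self
        dis = 1.0 - tom
        np.fill_diagonal(dis, 0.0)
        dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
        Z = linkage(squareform(dis, checks=False), method="average")
        self.linkage_ = Z
        max_h = Z[:, 2].max()
        height = self.cut_height * max_h if max_h > 0 else 0.0
        raw = fcluster(Z, t=height, criterion="distance")
        labels = np.zeros(n, dtype=int)
        next_label = 1
        for lab in np.unique(raw):
            members = np.nonzero(raw == lab)[0]
            if members.size >= self.min_module_size:
                labels[members] = next_label
                next_label += 1
        self.labels_ = labels
        return self


def detect_modules_tree_cut(
    tom: np.ndarray,
    ids: Sequence[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ClusterSet:
    """Cut the TOM dendrogram into modules; small branches stay unassigned."""
    ids = list(ids)
    if min_module_size > len(ids):
        import warnings

        warnings.warn("min_module_size exceeds gene count; everything unassigned")
    est = TreeCutModules(min_module_size=min_module_size, cut_height=cut_height).fit(tom)
    clusters: dict[int, set] = {}
    unassigned = set()
    for gid, lab in zip(ids, est.labels_):
        if lab == 0:
            unassigned.add(gid)
        else:
            clusters.setdefault(int(lab), set()).add(gid)
    return ClusterSet(
        clusters=sorted(clusters.values(), key=lambda s: (-len(s), sorted(s)[0])),
        method="tree_cut",
        parameter=float(cut_height),
        unassigned=unassigned,
    )


def module_eigengene_membership(
    atlas: ExpressionAtlas, modules: ClusterSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes and per-gene module membership.

    The eigengene of a module is the first principal component of its
    standardized (per-gene z-scored) expression across samples, oriented to
    correlate non-negatively with the module's mean profile.  Membership is
    the Pearson correlation of every atlas gene with each eigengene.
    """
    if not modules.clusters:
        raise ValueError("no modules to summarize")
    X = atlas.data
    eigengenes = {}
    for mi, cluster in enumerate(
        sorted(modules.clusters, key=len, reverse=True), start=1
    ):
        genes = [g for g in cluster if g in X.index]
        if not genes:
            raise ValueError("module genes missing from the atlas")
        sub = X.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if z.shape[0] == 1:
            eig = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        eigengenes[f"M{mi}"] = eig
    eig_df = pd.DataFrame(eigengenes, index=X.columns).T
    genes_z = X.to_numpy(dtype=float)
    gsd = genes_z.std(axis=1, ddof=0)
    gsd[gsd == 0] = 1.0
    gz = (genes_z - genes_z.mean(axis=1, keepdims=True)) / gsd[:, None]
    mm = {}
    for name, eig in eigengenes.items():
        esd = eig.std()
        ez = (eig - eig.mean()) / (esd if esd > 0 else 1.0)
        mm[name] = gz @ ez / gz.shape[1]
    membership = pd.DataFrame(mm, index=X.index)
    return eig_df, membership
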