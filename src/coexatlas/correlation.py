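"""Pairwise gene correlation: plain PCC, sample-redundancy-weighted PCC,
and Mutual Rank.

Expression compendia often contain blocks of near-duplicate arrays (probe
replicates, repeated conditions).  Plain Pearson correlation implicitly
weights every array equally, so redundant blocks dominate.  The weighted
variant first scores sample-to-sample similarity J (Pearson between sample
columns), rescales similarities above a threshold C to
J' = (J - C)/(1 - C) and zeroes the rest, sums each sample's J' row
(its redundancy, self term included), and weights each sample by
1/sqrt(redundancy).  Mutual Rank then replaces correlation magnitudes by
the geometric mean of the two reciprocal ranks, which rescues genes whose
correlations are systematically low but consistently ordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import LOG10, AtlasError, ExpressionAtlas

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.4

PCC = "pcc"
WEIGHTED_PCC = "weighted_pcc"
MUTUAL_RANK = "mutual_rank"


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise gene scores.

    ``kind`` is one of ``pcc``, ``weighted_pcc`` (both in [-1, 1], diagonal
    1) or ``mutual_rank`` (>= 1 off-diagonal; the diagonal is undefined and
    stored as NaN).
    """

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class SampleWeightVector:
    """Per-sample redundancy weights W = redundancy^(-1/2).

    ``J`` is the sample × sample Pearson similarity, ``J_adj`` the
    thresholded and rescaled similarity, ``redundancy`` its row sum
    (including the self term, so redundancy >= 1 and 0 < W <= 1).
    """

    sample_ids: list[str]
    J: np.ndarray
    J_adj: np.ndarray
    redundancy: np.ndarray
    weights: np.ndarray


def _row_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows, constant rows mapped to 0."""
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows in correlation input; their PCC set to 0",
                       int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.asarray(corr, dtype=float)
    corr[np.isnan(corr)] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def pearson_all_pairs(atlas: ExpressionAtlas) -> CorrelationMatrix:
    """All-pairs Pearson correlation of log10-scale gene profiles."""
    if atlas.scale_state != LOG10:
        raise AtlasError("pearson_all_pairs expects a log10-transformed atlas")
    if atlas.n_samples < 3:
        raise AtlasError("at least 3 samples are required for correlation")
    return CorrelationMatrix(ids=atlas.row_ids, values=_row_correlations(atlas.values), kind=PCC)


def sample_similarity(atlas: ExpressionAtlas) -> pd.DataFrame:
    """Pearson similarity J between sample columns (diagonal 1)."""
    if atlas.n_genes < 3:
        raise AtlasError("at least 3 genes are required for sample similarity")
    J = _row_correlations(atlas.values.T)
    return pd.DataFrame(J, index=atlas.sample_ids, columns=atlas.sample_ids)


def adjusted_similarity_and_weights(
    J: pd.DataFrame | np.ndarray,
    C: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> SampleWeightVector:
    """Threshold/rescale sample similarities and derive redundancy weights.

    J' = 0 where J < C, else (J - C)/(1 - C); a sample's redundancy is the
    row sum of J' (self term included), and its weight is the inverse square
    root of that redundancy.  Negative similarities fall below C and are
    zeroed without special casing.
    """
    if not (0.0 <= C < 1.0):
        raise ValueError(f"similarity threshold C must be in [0, 1), got {C}")
    if isinstance(J, pd.DataFrame):
        sample_ids = list(J.columns)
        Jv = J.to_numpy(dtype=float)
    else:
        Jv = np.asarray(J, dtype=float)
        sample_ids = [f"S{i}" for i in range(Jv.shape[0])]
    if Jv.shape[0] != Jv.shape[1] or not np.allclose(Jv, Jv.T, atol=1e-12):
        raise ValueError("J must be a symmetric sample similarity matrix")
    J_adj = np.where(Jv < C, 0.0, (Jv - C) / (1.0 - C))
    redundancy = J_adj.sum(axis=1)
    weights = redundancy ** -0.5
    return SampleWeightVector(sample_ids, Jv, J_adj, redundancy, weights)


def weighted_pcc(
    atlas: ExpressionAtlas,
    weights: SampleWeightVector | np.ndarray,
) -> CorrelationMatrix:
    """Sample-weighted Pearson correlation between all gene pairs.

    Uses weighted means RE_g = sum(W_s RE_g,s) / sum(W_s) and the weighted
    covariance/variance ratio; a zero-weight sample contributes nothing,
    which is equivalent to deleting it.
    """
    w = weights.weights if isinstance(weights, SampleWeightVector) else np.asarray(weights, float)
    if w.shape[0] != atlas.n_samples:
        raise AtlasError("weight vector length does not match sample count")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    X = atlas.values
    wsum = w.sum()
    wmean = (X * w).sum(axis=1) / wsum
    Xc = X - wmean[:, None]
    cov = (Xc * w) @ Xc.T
    var = np.diag(cov).copy()
    constant = var <= 0
    if constant.any():
        logger.warning("%d rows constant under the given weights; PCC set to 0",
                       int(constant.sum()))
        var[constant] = 1.0
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(ids=atlas.row_ids, values=corr, kind=WEIGHTED_PCC)


def mutual_rank(corr: CorrelationMatrix, geometric: bool = True) -> CorrelationMatrix:
    """Mutual Rank: geometric mean of the two reciprocal correlation ranks.

    For each gene, partners are ranked 1..n-1 by descending correlation
    (self excluded, ties averaged); MR(A, B) = sqrt(Rank_A→B × Rank_B→A).
    ``geometric=False`` returns the bare rank product instead of its square
    root (the alternative reading of the defining equation).
    """
    if corr.kind not in (PCC, WEIGHTED_PCC):
        raise ValueError("mutual_rank requires a pcc or weighted_pcc matrix")
    n = corr.n
    if n < 3:
        raise ValueError("mutual_rank requires at least 3 genes")
    values = corr.values
    ranks = np.zeros((n, n), dtype=float)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        ranks[i, others] = rankdata(-values[i, others], method="average")
    prod = ranks * ranks.T
    mr = np.sqrt(prod) if geometric else prod
    np.fill_diagonal(mr, np.nan)
    return CorrelationMatrix(ids=list(corr.ids), values=mr, kind=MUTUAL_RANK)


class PairwiseCorrelation(BaseEstimator, TransformerMixin):
    """sklearn-style transformer over the correlation routines.

    ``transform`` maps a genes × samples matrix to the requested pairwise
    score matrix: ``method`` ∈ {"pcc", "weighted_pcc", "mutual_rank"}.  The
    weighted variants derive sample weights from the matrix itself via the
    redundancy scheme with threshold ``C``; mutual rank is computed from the
    weighted correlation.
    """

    def __init__(self, method: str = PCC, C: float = DEFAULT_SIMILARITY_THRESHOLD,
                 geometric: bool = True):
        self.method = method
        self.C = C
        self.geometric = geometric

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        values = np.asarray(getattr(X, "values", X), dtype=float)
        if self.method == PCC:
            return _row_correlations(values)
        ids = [str(i) for i in range(values.shape[0])]
        atlas = ExpressionAtlas(
            data=pd.DataFrame(values, index=ids), scale_state=LOG10
        )
        J = sample_similarity(atlas)
        sw = adjusted_similarity_and_weights(J, C=self.C)
        wc = weighted_pcc(atlas, sw)
        if self.method == WEIGHTED_PCC:
            return wc.values
        if self.method == MUTUAL_RANK:
            return mutual_rank(wc, geometric=self.geometric).values
        raise ValueError(f"unknown correlation method: {self.method!r}")
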