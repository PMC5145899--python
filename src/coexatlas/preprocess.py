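"""Gene filtering and log transformation of raw expression atlases.

Two filters remove genes whose expression barely varies across the atlas
(such genes would otherwise flood the network with spuriously high
correlations): a coefficient-of-variation filter (sample sd / mean >= 0.5)
and an expression-range filter (max - min > 32 raw units).  Values are then
log10-transformed with negative transforms clamped to 0.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import LOG10, RAW, AtlasError, ExpressionAtlas

logger = logging.getLogger(__name__)

DEFAULT_CV_MIN = 0.5
DEFAULT_RANGE_MIN = 32.0


class VariableGeneFilter(BaseEstimator, TransformerMixin):
    """Keep genes with sd/mean >= ``cv_min`` and range > ``range_min``.

    Operates on a genes × samples array or DataFrame of raw expression.
    The standard deviation is the sample (n-1) formula; rows with zero mean
    fail the CV criterion rather than raising.

    Attributes
    ----------
    keep_mask_ : boolean array marking surviving rows
    n_kept_, n_dropped_ : surviving / removed row counts
    """

    def __init__(self, cv_min: float = DEFAULT_CV_MIN, range_min: float = DEFAULT_RANGE_MIN):
        self.cv_min = cv_min
        self.range_min = range_min

    def fit(self, X, y=None):
        values = np.asarray(getattr(X, "values", X), dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-d genes × samples matrix")
        sd = values.std(axis=1, ddof=1)
        mean = values.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / np.where(mean == 0, 1.0, mean), 0.0)
        rng = values.max(axis=1) - values.min(axis=1)
        self.keep_mask_ = (cv >= self.cv_min) & (rng > self.range_min)
        self.n_kept_ = int(self.keep_mask_.sum())
        self.n_dropped_ = int(values.shape[0] - self.n_kept_)
        return self

    def transform(self, X):
        values = getattr(X, "values", X)
        if values.shape[0] != self.keep_mask_.shape[0]:
            # allow transform on fresh data by refitting the mask
            self.fit(X)
        if hasattr(X, "loc"):
            return X.loc[self.keep_mask_]
        return np.asarray(X)[self.keep_mask_]


class Log10Transform(BaseEstimator, TransformerMixin):
    """Elementwise ``max(0, log10(v))`` with 0 mapped to 0.

    Negative transforms (raw values below 1) are clamped to 0, and the
    limit point v = 0 is clamped the same way.  Negative raw values are an
    upstream error.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        values = np.asarray(getattr(X, "values", X), dtype=float)
        if (values < 0).any():
            raise ValueError("raw expression values must be non-negative")
        with np.errstate(divide="ignore"):
            out = np.log10(np.where(values > 0, values, 1.0))
        out = np.maximum(out, 0.0)
        if hasattr(X, "loc"):
            import pandas as pd

            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def filter_variable_genes(
    atlas: ExpressionAtlas,
    cv_min: float = DEFAULT_CV_MIN,
    range_min: float = DEFAULT_RANGE_MIN,
) -> ExpressionAtlas:
    """Apply the CV and range filters to a raw-scale atlas."""
    if atlas.scale_state != RAW:
        raise AtlasError("gene filters are defined on raw-scale expression")
    est = VariableGeneFilter(cv_min=cv_min, range_min=range_min).fit(atlas.data)
    logger.info("variable-gene filter: kept %d, dropped %d", est.n_kept_, est.n_dropped_)
    return atlas.with_data(atlas.data.loc[est.keep_mask_])


def log_transform(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Log10-transform a raw atlas, clamping negative transforms to 0."""
    if atlas.scale_state != RAW:
        raise AtlasError("atlas is already log-transformed")
    transformed = Log10Transform().fit_transform(atlas.data)
    return atlas.with_data(transformed, scale_state=LOG10)
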