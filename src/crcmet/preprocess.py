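"""Transformation chain for concentration data.

Three transformers, applied in this order: median fold-change normalization
on the raw concentration scale (removes per-sample dilution-like analytical
bias), natural-log transform with autoscaling (unit-variance scaling and
centering, the convention of chemometrics software), and block scaling for
multi-platform fusion (each block down-weighted by 1/sqrt(width) so blocks
contribute equal total variance). All transformers follow the scikit-learn
fit/transform contract: statistics are frozen on the training set and reused
verbatim for validation samples — validation data are never refit.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class MedianFoldChangeNormalizer(BaseEstimator, TransformerMixin):
    """Median fold-change (probabilistic quotient) normalization.

    ``fit`` stores the per-metabolite median over training samples as the
    reference profile. ``transform`` divides each sample by its dilution
    factor, the median over metabolites of (value / reference). The median
    makes the factor robust: a single aberrant metabolite does not move it.

    Attributes
    ----------
    reference_profile_ : pd.Series
        Per-metabolite reference concentration (uM).
    dilution_factors_ : pd.Series
        Factors of the most recently transformed data.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        self._check_positive(X)
        self.reference_profile_ = X.median(axis=0)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        X = _as_frame(X)
        self._check_positive(X)
        ratios = X / self.reference_profile_.reindex(X.columns)
        factors = ratios.median(axis=1)
        self.dilution_factors_ = factors
        return X.div(factors, axis=0)

    @staticmethod
    def _check_positive(X: pd.DataFrame) -> None:
        arr = X.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("missing values present; impute before normalization")
        if (arr <= 0).any():
            raise ValueError("non-positive concentrations: fold-change ratios undefined")


class LogAutoscaler(BaseEstimator, TransformerMixin):
    """Natural-log transform followed by autoscaling (unit-variance, centered).

    Column means and sds (sample sd, ddof=1) of the log values are estimated
    on the training set only; ``transform`` on new data reuses them, so a new
    sample sitting at every training geometric mean maps to the zero vector.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        logx = self._log(X)
        self.column_means_ = logx.mean(axis=0)
        self.column_sds_ = logx.std(axis=0, ddof=1)
        zero = self.column_sds_ <= 0
        if zero.any():
            bad = list(logx.columns[zero])
            raise ValueError(f"zero-variance metabolites at fit time: {bad}")
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        X = _as_frame(X)
        logx = self._log(X)
        return (logx - self.column_means_.reindex(logx.columns)) / self.column_sds_.reindex(logx.columns)

    def inverse_transform(self, Z):
        Z = _as_frame(Z)
        return np.exp(Z * self.column_sds_.reindex(Z.columns) + self.column_means_.reindex(Z.columns))

    @staticmethod
    def _log(X: pd.DataFrame) -> pd.DataFrame:
        arr = X.to_numpy()
        if np.isnan(arr).any() or (arr <= 0).any():
            raise ValueError("log transform requires strictly positive, complete values")
        return np.log(X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "column_means": self.column_means_.to_dict(),
                "column_sds": self.column_sds_.to_dict(),
            },
            sort_keys=True,
        )


def block_scale(blocks: list[pd.DataFrame], block_names: list[str] | None = None) -> pd.DataFrame:
    """Fuse autoscaled blocks, weighting each column by 1/sqrt(block width).

    With autoscaled columns (variance 1 each), a block of p columns carries
    total variance p; the 1/sqrt(p) weight equalizes the blocks' total
    variance so no platform dominates the fused model. Column provenance is
    retained by prefixing each column with its block name.
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    frames = [_as_frame(b) for b in blocks]
    index = frames[0].index
    for i, f in enumerate(frames[1:], start=1):
        if len(f.index) != len(index) or list(f.index) != list(index):
            extra = sorted(map(str, set(f.index) ^ set(index)))
            raise ValueError(f"sample mismatch between blocks 0 and {i}: {extra}")
    if block_names is None:
        block_names = [f"block{i}" for i in range(len(frames))]
    scaled = []
    for name, f in zip(block_names, frames):
        w = 1.0 / np.sqrt(f.shape[1])
        g = f * w
        g.columns = [f"{name}::{c}" for c in f.columns]
        scaled.append(g)
    return pd.concat(scaled, axis=1)


class BlockScaler(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`block_scale` for pipeline use.

    ``fit`` records block boundaries from a list of column-name lists;
    ``transform`` takes the horizontally concatenated frame and applies the
    per-block 1/sqrt(width) weights.
    """

    def __init__(self, block_columns=None, block_names=None):
        self.block_columns = block_columns
        self.block_names = block_names

    def fit(self, X, y=None):
        X = _as_frame(X)
        cols = self.block_columns or [list(X.columns)]
        self.block_columns_ = [list(c) for c in cols]
        self.block_weights_ = [1.0 / np.sqrt(len(c)) for c in self.block_columns_]
        return self

    def transform(self, X):
        X = _as_frame(X)
        names = self.block_names or [f"block{i}" for i in range(len(self.block_columns_))]
        return block_scale([X.loc[:, c] for c in self.block_columns_], names)


def preprocess_state_to_json(normalizer: MedianFoldChangeNormalizer, scaler: LogAutoscaler) -> str:
    """Serialize the frozen training-set preprocessing state."""
    return json.dumps(
        {
            "reference_profile": normalizer.reference_profile_.to_dict(),
            "column_means": scaler.column_means_.to_dict(),
            "column_sds": scaler.column_sds_.to_dict(),
        },
        sort_keys=True,
    )
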