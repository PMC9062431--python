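"""Metabolite preprocessing: detection-limit censoring and rank-based
inverse normal transformation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["censor_lod", "inverse_rank_transform", "InverseRankTransformer"]


def censor_lod(
    values: pd.DataFrame, lod: dict[str, float] | pd.Series | float
) -> tuple[pd.DataFrame, pd.Series]:
    """Set values below each measure's detection limit to missing.

    ``lod`` may be a scalar (applied to every column) or a per-column
    mapping; columns without an entry are left unchanged. Returns the
    censored frame and the per-column count of newly censored values.
    """
    out = values.copy()
    counts = {}
    for col in out.columns:
        if np.isscalar(lod):
            limit = float(lod)
        else:
            limit = lod.get(col, None) if hasattr(lod, "get") else None
        if limit is None or not np.isfinite(limit):
            counts[col] = 0
            continue
        mask = out[col] < limit
        counts[col] = int(mask.sum())
        out.loc[mask, col] = np.nan
    return out, pd.Series(counts, name="n_censored")


def inverse_rank_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform of one vector.

    Non-missing values are replaced by ``Phi^-1((r - c) / (m - 2c + 1))``
    with r the average-tie rank among the m non-missing values and
    c = 3/8 the Blom offset (for c = 3/8 the denominator equals m + 1/4);
    missing values stay missing. Strictly monotone in the input.
    """
    arr = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(arr)
    m = int(obs.sum())
    if m == 0:
        raise ValueError("all values missing; cannot rank-transform")
    if m < 3:
        raise ValueError(f"need at least 3 non-missing values, got {m}")
    ranks = rankdata(arr[obs], method="average")
    arr[obs] = norm.ppf((ranks - offset) / (m - 2.0 * offset + 1.0))
    return arr


class InverseRankTransformer(TransformerMixin, BaseEstimator):
    """Column-wise rank-based inverse normal transformation.

    Ranks are computed within the data being transformed (the transform is
    a within-cohort normalisation, not an out-of-sample mapping), so
    :meth:`fit` only validates; use :meth:`fit_transform` in pipelines.
    """

    def __init__(self, offset: float = 3.0 / 8.0):
        self.offset = offset

    def fit(self, X, y=None) -> "InverseRankTransformer":
        X = pd.DataFrame(X)
        n_obs = X.notna().sum(axis=0)
        bad = n_obs[n_obs < 3]
        if len(bad):
            raise ValueError(
                f"columns with <3 non-missing values cannot be transformed: "
                f"{list(bad.index)}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        out = X.copy()
        for col in out.columns:
            out[col] = inverse_rank_transform(out[col].to_numpy(float), self.offset)
        return out
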