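"""Effective number of independent tests among correlated metabolites.

The Li & Ji estimator eigendecomposes the Pearson correlation matrix of
the measures and counts each eigenvalue's contribution as
``f(|lambda|) = 1{|lambda| >= 1} + (|lambda| - floor(|lambda|))``:
an eigenvalue of M (all measures perfectly correlated) contributes one
test, M unit eigenvalues contribute M. The family-wise significance
threshold is ``alpha / m_eff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "MeffResult",
    "LiJiCorrection",
    "liji_meff",
    "meff_from_corr",
    "bonferroni_threshold",
]


@dataclass
class MeffResult:
    n_measures: int
    eigenvalues: np.ndarray
    m_eff: int
    m_eff_raw: float
    alpha: float = 0.05
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = bonferroni_threshold(self.alpha, self.m_eff)


def _liji_f(eigenvalues: np.ndarray) -> float:
    x = np.abs(np.asarray(eigenvalues, float))
    # snap to 9 decimals so floating error near integer eigenvalues cannot
    # flip floor(x) (e.g. 2.9999999999999996 must count as exactly one test)
    x = np.round(x, 9)
    return float(np.sum((x >= 1.0) + (x - np.floor(x))))


def bonferroni_threshold(alpha: float, m_eff: float) -> float:
    """Family-wise significance threshold alpha / m_eff."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if m_eff < 1:
        raise ValueError(f"m_eff must be >= 1, got {m_eff}")
    return alpha / m_eff


class LiJiCorrection(BaseEstimator):
    """Estimate the effective number of independent tests from a measure
    matrix (individuals x measures, missing allowed).

    Parameters
    ----------
    alpha : float, default 0.05
        Family-wise error level for the derived threshold.
    rounding : {"nearest", "none"}, default "nearest"
        Whether the threshold uses ``round(m_eff)`` (integer counts of
        independent measures) or the raw eigenvalue sum.
    pairwise : bool, default True
        Pairwise-complete correlations (uses detection-limit censored data
        maximally); set False for complete-case rows only.

    Attributes
    ----------
    eigenvalues_ : descending eigenvalues of the correlation matrix.
    m_eff_ : effective number of tests used for the threshold.
    threshold_ : alpha / m_eff_.
    """

    def __init__(self, alpha: float = 0.05, rounding: str = "nearest", pairwise: bool = True):
        self.alpha = alpha
        self.rounding = rounding
        self.pairwise = pairwise

    def fit(self, X, y=None) -> "LiJiCorrection":
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 measures")
        stds = X.std(axis=0, skipna=True)
        constant = stds[(stds == 0) | stds.isna()]
        if len(constant):
            raise ValueError(
                f"constant measures have undefined correlations: {list(constant.index)}"
            )
        if self.pairwise:
            corr = X.corr(method="pearson", min_periods=2).to_numpy()
        else:
            corr = X.dropna(axis=0).corr(method="pearson").to_numpy()
        if not np.isfinite(corr).all():
            bad = [X.columns[i] for i in np.unique(np.nonzero(~np.isfinite(corr))[0])]
            raise ValueError(f"correlations not computable for measures: {bad}")
        eig = np.linalg.eigvalsh(corr)[::-1]
        if eig[-1] < -1e-8:
            warnings.warn(
                "pairwise-complete correlation matrix is not positive "
                "semi-definite; clipping negative eigenvalues at 0",
                RuntimeWarning,
            )
            eig = np.clip(eig, 0.0, None)
        m_raw = _liji_f(eig)
        m_eff = int(round(m_raw)) if self.rounding == "nearest" else m_raw
        m_eff = max(m_eff, 1)
        self.eigenvalues_ = eig
        self.m_eff_raw_ = m_raw
        self.m_eff_ = m_eff
        self.threshold_ = bonferroni_threshold(self.alpha, m_eff)
        self.n_measures_ = X.shape[1]
        return self

    def result_(self) -> MeffResult:
        return MeffResult(
            n_measures=self.n_measures_,
            eigenvalues=self.eigenvalues_,
            m_eff=self.m_eff_,
            m_eff_raw=self.m_eff_raw_,
            alpha=self.alpha,
        )


def meff_from_corr(corr, alpha: float = 0.05, rounding: str = "nearest") -> MeffResult:
    """Li & Ji count from an explicit correlation matrix."""
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1] or corr.shape[0] < 2:
        raise ValueError("corr must be a square matrix of at least 2 measures")
    eig = np.linalg.eigvalsh(corr)[::-1]
    m_raw = _liji_f(eig)
    m_eff = int(round(m_raw)) if rounding == "nearest" else m_raw
    return MeffResult(
        n_measures=corr.shape[0],
        eigenvalues=eig,
        m_eff=max(m_eff, 1),
        m_eff_raw=m_raw,
        alpha=alpha,
    )


def liji_meff(measures, alpha: float = 0.05, pairwise: bool = True) -> MeffResult:
    """Li & Ji effective-test count and threshold for a measure matrix."""
    est = LiJiCorrection(alpha=alpha, pairwise=pairwise).fit(measures)
    return est.result_()
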