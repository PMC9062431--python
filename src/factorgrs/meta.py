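"""Inverse-variance fixed-effect meta-analysis of per-cohort results.

Cohorts are analyzed separately (covariate scales differ across studies)
and pooled with weights ``w_i = 1/SE_i^2``:
pooled estimate ``sum(w b)/sum(w)``, pooled SE ``1/sqrt(sum w)``, Cochran's
``Q = sum w (b - pooled)^2`` and ``I^2 = max(0, (Q - df)/Q)`` as
heterogeneity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaResult", "fixed_effect_meta", "meta_analyze_tables"]


@dataclass(frozen=True)
class MetaResult:
    outcome_id: str
    term: str
    estimate: float
    se: float
    p: float
    n: int
    k_cohorts: int
    cochran_q: float
    i_squared: float
    cohort_estimates: tuple
    cohort_ses: tuple

    def to_row(self) -> dict:
        return {
            "outcome_id": self.outcome_id,
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "n": self.n,
            "k_cohorts": self.k_cohorts,
            "cochran_q": self.cochran_q,
            "i_squared": self.i_squared,
        }


def fixed_effect_meta(results: pd.DataFrame) -> MetaResult:
    """Pool rows of one (outcome_id, term) pair across cohorts."""
    if results["outcome_id"].nunique() != 1 or results["term"].nunique() != 1:
        pairs = sorted(set(zip(results["outcome_id"], results["term"])))
        raise ValueError(f"results mix outcome/term pairs: {pairs}")
    beta = results["estimate"].to_numpy(float)
    se = results["se"].to_numpy(float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    if len(beta) == 1:
        warnings.warn("single cohort supplied; returning it unchanged", RuntimeWarning)
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    # exact zero when all inputs agree (pooled may differ by rounding)
    q = 0.0 if np.all(beta == beta[0]) else float(np.sum(w * (beta - pooled) ** 2))
    df = len(beta) - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 and df > 0 else 0.0
    return MetaResult(
        outcome_id=str(results["outcome_id"].iloc[0]),
        term=str(results["term"].iloc[0]),
        estimate=pooled,
        se=pooled_se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n=int(results["n"].sum()) if "n" in results else 0,
        k_cohorts=len(beta),
        cochran_q=q,
        i_squared=i2,
        cohort_estimates=tuple(beta),
        cohort_ses=tuple(se),
    )


def meta_analyze_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    """Pool several long-format result tables over (outcome_id, term).

    Every pair must appear in every table; unmatched pairs raise.
    """
    combined = pd.concat(tables, ignore_index=True)
    counts = combined.groupby(["outcome_id", "term"]).size()
    if counts.nunique() > 1:
        bad = counts[counts != len(tables)]
        raise ValueError(
            f"outcome/term pairs missing from some cohorts: {list(bad.index)[:5]}"
        )
    rows = [
        fixed_effect_meta(grp).to_row()
        for _, grp in combined.groupby(["outcome_id", "term"], sort=False)
    ]
    return pd.DataFrame(rows)
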