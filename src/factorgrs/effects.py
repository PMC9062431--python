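"""Odds-ratio summaries and additivity assessment for factorial CAD
analyses.

Log-odds estimates are exponentiated to odds ratios with Wald 95%
confidence intervals. Under the rare-outcome approximation an odds ratio
is read as a risk ratio, so risk reduction is ``100*(1 - OR)`` percent;
when the outcome is not rare the Zhang-Yu correction
``RR = OR / ((1 - p0) + p0*OR)`` converts the OR at baseline risk p0.
Two factorial exposures combine additively on the multiplicative scale
when the joint OR is close to the product of the single-exposure ORs, and
on the risk-difference scale when the summed individual risk reductions
match the joint reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationResult
from .scores import FactorialAssignment

__all__ = [
    "OrSummary",
    "or_from_logistic",
    "rr_from_or",
    "additivity_assessment",
    "summarize_factorial_cad",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class OrSummary:
    group: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    risk_reduction_pct: float
    rr_adjusted: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None


def rr_from_or(odds_ratio: float, baseline_risk: float) -> float:
    """Zhang-Yu incidence-corrected risk ratio from an odds ratio."""
    if not (0.0 < baseline_risk < 1.0):
        raise ValueError(f"baseline_risk must lie in (0,1), got {baseline_risk}")
    return odds_ratio / ((1.0 - baseline_risk) + baseline_risk * odds_ratio)


def or_from_logistic(
    result: AssociationResult | pd.Series,
    baseline_risk: float | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> OrSummary:
    """OR = exp(beta), 95% CI = exp(beta +/- 1.96*SE) for one logistic term."""
    est = float(result["estimate"]) if isinstance(result, (pd.Series, dict)) else result.estimate
    se = float(result["se"]) if isinstance(result, (pd.Series, dict)) else result.se
    term = result["term"] if isinstance(result, (pd.Series, dict)) else result.term
    if not (se > 0):
        raise ValueError(f"standard error must be positive, got {se}")
    odds = float(np.exp(est))
    return OrSummary(
        group=str(term),
        odds_ratio=odds,
        ci_low=float(np.exp(est - Z95 * se)),
        ci_high=float(np.exp(est + Z95 * se)),
        risk_reduction_pct=100.0 * (1.0 - odds),
        rr_adjusted=None if baseline_risk is None else rr_from_or(odds, baseline_risk),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def additivity_assessment(
    or_a: float,
    or_b: float,
    or_ab: float,
    baseline_risk: float | None = None,
    tolerance: float = 0.02,
) -> dict:
    """Compare single-exposure ORs with the joint-exposure OR.

    Reports the multiplicative prediction ``or_a * or_b`` against the
    observed joint OR, and the summed risk reductions against the joint
    reduction under both the rare-outcome (risk ratio ~ OR) and, when a
    baseline risk is supplied, the incidence-corrected conversion. The
    ``additive`` flag is |predicted - observed| <= tolerance on the OR
    scale.
    """
    for name, v in (("or_a", or_a), ("or_b", or_b), ("or_ab", or_ab)):
        if not (v > 0 and np.isfinite(v)):
            raise ValueError(f"{name} must be a positive finite odds ratio")
    predicted = or_a * or_b
    out = {
        "multiplicative_prediction": predicted,
        "observed_joint_or": or_ab,
        "additive": bool(abs(predicted - or_ab) <= tolerance),
        "rare_outcome": {
            "risk_reduction_a_pct": 100.0 * (1.0 - or_a),
            "risk_reduction_b_pct": 100.0 * (1.0 - or_b),
            "summed_reduction_pct": 100.0 * ((1.0 - or_a) + (1.0 - or_b)),
            "joint_reduction_pct": 100.0 * (1.0 - or_ab),
        },
    }
    if baseline_risk is not None:
        rr = {k: rr_from_or(v, baseline_risk) for k, v in
              (("a", or_a), ("b", or_b), ("ab", or_ab))}
        out["incidence_corrected"] = {
            "risk_reduction_a_pct": 100.0 * (1.0 - rr["a"]),
            "risk_reduction_b_pct": 100.0 * (1.0 - rr["b"]),
            "summed_reduction_pct": 100.0 * ((1.0 - rr["a"]) + (1.0 - rr["b"])),
            "joint_reduction_pct": 100.0 * (1.0 - rr["ab"]),
            "baseline_risk": baseline_risk,
        }
    return out


def summarize_factorial_cad(
    assignment: FactorialAssignment,
    results: pd.DataFrame,
    outcome,
    baseline_risk: float | None = None,
) -> pd.DataFrame:
    """Per-group OR table (all 2^k - 1 contrasts vs the reference arm).

    ``results`` is the logistic fit table whose terms are the group
    indicator columns ``group_<label>``; ``outcome`` the binary CAD vector
    used for per-group case/control counts. Groups with zero cases are
    flagged and their OR omitted.
    """
    y = np.asarray(outcome, int)
    labels = assignment.labels
    rows = []
    terms = {str(r["term"]): r for _, r in results.iterrows()}
    k = assignment.indicators.shape[1]
    for g in sorted(labels.unique()):
        mask = (labels == g).to_numpy()
        n_cases = int(y[mask].sum())
        n_controls = int(mask.sum() - n_cases)
        row = {
            "group": g,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "reference": g == assignment.reference_label,
        }
        term = f"group_{g}"
        if g == assignment.reference_label:
            row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan,
                       risk_reduction_pct=0.0, rr_adjusted=np.nan, flagged=False)
        elif n_cases == 0:
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       risk_reduction_pct=np.nan, rr_adjusted=np.nan, flagged=True)
        elif term in terms:
            s = or_from_logistic(terms[term], baseline_risk=baseline_risk,
                                 n_cases=n_cases, n_controls=n_controls)
            row.update(odds_ratio=s.odds_ratio, ci_low=s.ci_low, ci_high=s.ci_high,
                       risk_reduction_pct=s.risk_reduction_pct,
                       rr_adjusted=np.nan if s.rr_adjusted is None else s.rr_adjusted,
                       flagged=False)
        else:
            raise KeyError(f"no fitted term {term!r} for group {g}")
        rows.append(row)
    table = pd.DataFrame(rows)
    expected = 2**k
    if len(table) < expected:
        # groups can be empty in tiny cohorts; keep whatever exists
        pass
    return table
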