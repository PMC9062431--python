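"""End-to-end factorial analyses on a cohort table.

These helpers wire the stages together the way the full study runs them:
scores -> median-split groups -> covariate-adjusted regression, with the
metabolome branch adding detection-limit censoring, rank-based inverse
normal transformation, an effective-number-of-tests threshold and
cross-cohort pooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import fit_linear, fit_logistic, interaction_test
from .multiplicity import liji_meff
from .preprocess import InverseRankTransformer
from .scores import FactorialAssignment, assign_factorial_groups

__all__ = [
    "group_design",
    "factorial_cad_analysis",
    "metabolome_analysis",
]

CAD_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
METABOLOME_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 5)]


def group_design(
    cohort: pd.DataFrame, score_columns: list[str], rule: str = ">="
) -> tuple[FactorialAssignment, pd.DataFrame]:
    """Median-split the given score columns; return indicator design with
    one ``group_<label>`` dummy per non-reference group."""
    assignment = assign_factorial_groups(cohort[score_columns], rule=rule)
    dummies = pd.get_dummies(assignment.labels, prefix="group", prefix_sep="_")
    ref = f"group_{assignment.reference_label}"
    design = dummies.drop(columns=[ref]).astype(float)
    return assignment, design


def factorial_cad_analysis(
    cohort: pd.DataFrame,
    score_columns: list[str],
    covariates: list[str] = CAD_COVARIATES,
    outcome: str = "cad",
    weights: str | None = None,
    cohort_id: str = "cohort",
) -> tuple[FactorialAssignment, pd.DataFrame]:
    """2^k factorial logistic analysis of CAD vs the reference arm."""
    assignment, design = group_design(cohort, score_columns)
    design = pd.concat(
        [design.reset_index(drop=True), cohort[covariates].reset_index(drop=True)],
        axis=1,
    )
    results = fit_logistic(
        cohort[outcome].to_numpy(),
        design,
        weights=None if weights is None else cohort[weights].to_numpy(),
        outcome_id=outcome,
        cohort_id=cohort_id,
        terms=[c for c in design.columns if c.startswith("group_")],
    )
    return assignment, results


def metabolome_analysis(
    cohort: pd.DataFrame,
    score_columns: list[str],
    metabolite_columns: list[str],
    covariates: list[str] = METABOLOME_COVARIATES,
    weights: str | None = None,
    cohort_id: str = "cohort",
    alpha: float = 0.05,
    interaction: bool = False,
    rank_transform: bool = True,
) -> dict:
    """2x2 factorial linear analysis of each metabolite, plus the Li-Ji
    multiplicity threshold (and optionally the score-product interaction
    test per measure).

    Metabolites are inverse-rank transformed before fitting and before the
    correlation matrix that feeds the effective-test count; missing values
    (e.g. below detection limit) simply reduce each fit's n.
    """
    mets = cohort[metabolite_columns]
    if rank_transform:
        mets = InverseRankTransformer().fit_transform(mets)
    meff = liji_meff(mets, alpha=alpha)
    assignment, gdesign = group_design(cohort, score_columns)
    base = pd.concat(
        [gdesign.reset_index(drop=True), cohort[covariates].reset_index(drop=True)],
        axis=1,
    )
    w = None if weights is None else cohort[weights].to_numpy()
    group_terms = [c for c in base.columns if c.startswith("group_")]
    tables = []
    inter_tables = []
    for m in metabolite_columns:
        tables.append(
            fit_linear(
                mets[m].to_numpy(), base, weights=w, outcome_id=m,
                cohort_id=cohort_id, terms=group_terms,
            )
        )
        if interaction:
            inter_tables.append(
                interaction_test(
                    mets[m].to_numpy(),
                    cohort[score_columns[0]].to_numpy(),
                    cohort[score_columns[1]].to_numpy(),
                    covariates=cohort[covariates],
                    weights=w,
                    outcome_id=m,
                    cohort_id=cohort_id,
                    names=tuple(score_columns[:2]),
                )
            )
    results = pd.concat(tables, ignore_index=True)
    results["significant"] = results["p"] < meff.threshold
    out = {"assignment": assignment, "results": results, "meff": meff}
    if interaction:
        out["interaction"] = pd.concat(inter_tables, ignore_index=True)
    return out
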