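"""Covariate-adjusted association of factorial genotype groups with CAD
(logistic) and with metabolomic measures (linear).

Estimates are Wald: each result row carries the term's point estimate
(log-odds for logistic outcomes, SD units for rank-transformed
metabolites), its standard error from the observed information (or a
weight-consistent sandwich when probability weights are supplied), the
two-sided normal p-value and the number of individuals actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "AssociationResult",
    "SeparationError",
    "RankDeficiencyError",
    "fit_logistic",
    "fit_linear",
    "interaction_test",
    "effect_concordance",
]

RESULT_COLUMNS = ["cohort_id", "outcome_id", "term", "estimate", "se", "p", "n"]


class SeparationError(RuntimeError):
    """Logistic likelihood has no finite maximizer (perfect separation)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class AssociationResult:
    """One fitted term: estimate, Wald SE and p, sample size, identifiers."""

    outcome_id: str
    term: str
    estimate: float
    se: float
    p: float
    n: int
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"standard_error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    def to_row(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "outcome_id": self.outcome_id,
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "n": self.n,
        }


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the culprits
        _, r, piv = linalg.qr(mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [X.columns[p] for p in piv[len(diag):]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
            f"collinear terms: {sorted(map(str, bad))}"
        )


def _prepare(outcome, design: pd.DataFrame, weights):
    design = pd.DataFrame(design).copy()
    y = np.asarray(outcome, float)
    if len(y) != len(design):
        raise ValueError("outcome and design lengths differ")
    w = None if weights is None else np.asarray(weights, float)
    keep = np.isfinite(y) & np.isfinite(design.to_numpy(float)).all(axis=1)
    if w is not None:
        keep &= np.isfinite(w)
    y = y[keep]
    design = pd.DataFrame(design.to_numpy(float)[keep], columns=design.columns)
    w = None if w is None else w[keep]
    X = sm.add_constant(design, prepend=True, has_constant="add")
    _check_rank(X)
    return y, X, w


def _collect(fit, X, n, terms, outcome_id, cohort_id) -> pd.DataFrame:
    report = [t for t in X.columns if t != "const"] if terms is None else list(terms)
    rows = []
    for t in report:
        if t not in X.columns:
            raise KeyError(f"term {t!r} not in design")
        est = float(fit.params[t])
        se = float(fit.bse[t])
        p = float(2.0 * stats.norm.sf(abs(est / se)))
        rows.append(
            AssociationResult(
                outcome_id=outcome_id, term=str(t), estimate=est, se=se,
                p=max(p, np.nextafter(0, 1)), n=int(n), cohort_id=cohort_id,
            ).to_row()
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def fit_logistic(
    outcome,
    design: pd.DataFrame,
    weights=None,
    weight_kind: str = "probability",
    outcome_id: str = "cad",
    cohort_id: str = "cohort",
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression (IRLS) of a binary outcome.

    ``design`` holds the group indicators and covariates (an intercept is
    added). ``weights`` may be frequency weights (``weight_kind='frequency'``)
    or sampling/probability weights, in which case the SEs come from a
    sandwich estimator. Raises :class:`SeparationError` when the MLE
    diverges and :class:`RankDeficiencyError` on collinear designs rather
    than silently dropping terms.
    """
    y, X, w = _prepare(outcome, design, weights)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    kwargs = {}
    cov_kwargs = {}
    if w is not None:
        if weight_kind == "frequency":
            kwargs["freq_weights"] = w
        else:
            kwargs["freq_weights"] = w
            cov_kwargs = {"cov_type": "HC0"}
    model = sm.GLM(y, X, family=sm.families.Binomial(), **kwargs)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        fit = model.fit(maxiter=50, tol=1e-10, **cov_kwargs)
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise SeparationError(
            "perfect separation detected: the logistic MLE does not exist"
        )
    grad = model.score(np.asarray(fit.params))
    if np.max(np.abs(np.asarray(fit.params))) > 30.0 or not np.all(
        np.isfinite(fit.bse)
    ):
        raise SeparationError(
            "logistic estimates diverged; the outcome is (quasi-)separated "
            "by the design"
        )
    if np.linalg.norm(grad) > 1e-6 * max(1.0, len(y)):
        raise SeparationError("IRLS failed to converge within 50 iterations")
    return _collect(fit, X, len(y), terms, outcome_id, cohort_id)


def fit_linear(
    outcome,
    design: pd.DataFrame,
    weights=None,
    weight_kind: str = "probability",
    outcome_id: str = "metabolite",
    cohort_id: str = "cohort",
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """(Weighted) least-squares association of a continuous outcome.

    With probability weights the covariance is the HC0 sandwich, so SEs
    remain consistent under designed oversampling; with ``weights=None``
    this is ordinary least squares with model-based SEs.
    """
    y, X, w = _prepare(outcome, design, weights)
    if w is None:
        fit = sm.OLS(y, X).fit()
    else:
        model = sm.WLS(y, X, weights=w)
        fit = model.fit(cov_type="HC0") if weight_kind == "probability" else model.fit()
    return _collect(fit, X, len(y), terms, outcome_id, cohort_id)


def interaction_test(
    outcome,
    score_a,
    score_b,
    covariates: pd.DataFrame | None = None,
    weights=None,
    outcome_id: str = "outcome",
    cohort_id: str = "cohort",
    names: tuple[str, str] = ("score_a", "score_b"),
) -> pd.DataFrame:
    """Product-term test of additivity between two continuous scores.

    Fits ``outcome ~ A + B + A*B + covariates`` and reports the product
    term; a null product term means the two genetic exposures combine
    additively on the outcome scale.
    """
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    design = pd.DataFrame({names[0]: a, names[1]: b, f"{names[0]}:{names[1]}": a * b})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        design = pd.concat([design, cov], axis=1)
    return fit_linear(
        outcome,
        design,
        weights=weights,
        outcome_id=outcome_id,
        cohort_id=cohort_id,
        terms=[f"{names[0]}:{names[1]}"],
    )


def effect_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame) -> dict:
    """R^2 and slope of one score's metabolite effects on the other's.

    Both inputs are result tables over the same outcome ids (one row per
    outcome); returns the OLS of A's estimates on B's across outcomes.
    """
    a = results_a.set_index("outcome_id")["estimate"]
    b = results_b.set_index("outcome_id")["estimate"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared outcomes, got {len(shared)}"
        )
    av = a.loc[shared].to_numpy(float)
    bv = b.loc[shared].to_numpy(float)
    fit = sm.OLS(av, sm.add_constant(bv)).fit()
    return {
        "r_squared": float(fit.rsquared),
        "slope": float(fit.params[1]),
        "n": int(len(shared)),
    }
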