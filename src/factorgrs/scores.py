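"""Weighted genetic risk scores and factorial genotype groups.

A weighted genetic risk score (GRS) is the per-individual sum of
trait-associated allele dosages times their published per-allele effect
weights, oriented so a higher score means a genetically *lower* lipid
level (lipid-lowering alleles coded as effect alleles, positive weights).
Dichotomizing each of k scores at its within-cohort median yields a
2^k-arm factorial design mimicking a randomized trial of combined
lipid-lowering exposures; the reference arm is below the median on every
score (genetically higher lipid levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScoreVariant",
    "ScoreDefinition",
    "FactorialAssignment",
    "GeneticRiskScorer",
    "FactorialGrouper",
    "compute_grs",
    "assign_factorial_groups",
    "derive_cad_status",
    "read_score_definitions",
    "read_dosages",
]

CAD_ICD10_ROOTS = frozenset({"I20", "I21", "I22", "I24", "I25"})


@dataclass(frozen=True)
class ScoreVariant:
    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight == 0.0:
            raise ValueError(
                f"weight for {self.variant_id} must be finite and non-zero"
            )


@dataclass
class ScoreDefinition:
    """A named set of variants with effect alleles and per-allele weights.

    On construction the score is oriented: any variant with a negative
    weight has its effect/other alleles swapped and the weight negated, so
    stored weights are all positive and a higher score always corresponds
    to a genetically lower lipid level.
    """

    label: str
    variants: list[ScoreVariant]
    oriented: bool = field(default=False)

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids in score {self.label}: {dupes}")
        if not self.oriented:
            self.variants = [
                v
                if v.weight > 0
                else ScoreVariant(v.variant_id, v.other_allele, v.effect_allele, -v.weight)
                for v in self.variants
            ]
            self.oriented = True

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants])


@dataclass
class FactorialAssignment:
    """Per-individual membership in the 2^k median-split groups.

    ``indicators`` holds one binary column per score (1 = at or above the
    cohort median, i.e. the genetically lower-lipid arm). The reference
    group is all-zero: below the median on every score.
    """

    indicators: pd.DataFrame
    medians: dict[str, float]
    labels: pd.Series

    @property
    def n_groups(self) -> int:
        return 2 ** self.indicators.shape[1]

    @property
    def reference_label(self) -> str:
        return _group_label(np.zeros(self.indicators.shape[1], int))

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _group_label(bits: np.ndarray) -> str:
    return "".join(str(int(b)) for b in bits)


class GeneticRiskScorer(TransformerMixin, BaseEstimator):
    """Compute raw and SD-standardized weighted genetic risk scores.

    Parameters
    ----------
    score_definitions : list of ScoreDefinition
        Scores to compute; each variant must exist as a ``dosage_<id>`` or
        plain ``<id>`` column of the dosage frame passed to :meth:`fit`.
    standardize : bool, default True
        Also emit ``<label>_std`` columns, centred and scaled within the
        fitted cohort (score units reported "in SD").
    coded_alleles : dict, optional
        Allele counted by each dosage column (variant id -> allele). Where
        it equals the score's *other* allele the dosage is flipped to
        ``2 - d`` so every score counts its effect allele; omitted variants
        are assumed coded on the effect allele already.

    Attributes
    ----------
    allele_freqs_ : dict
        Effect-allele frequency per variant, estimated from non-missing
        dosages; missing dosages are imputed as twice this frequency.
    means_, sds_ : dict
        Per-score raw-score mean and SD used for standardization.
    """

    def __init__(
        self,
        score_definitions: list[ScoreDefinition],
        standardize: bool = True,
        coded_alleles: dict[str, str] | None = None,
    ):
        self.score_definitions = score_definitions
        self.standardize = standardize
        self.coded_alleles = coded_alleles

    def _dosage_matrix(self, X: pd.DataFrame, sdef: ScoreDefinition) -> np.ndarray:
        cols = []
        missing = []
        for vid in sdef.variant_ids:
            for cand in (f"dosage_{vid}", vid):
                if cand in X.columns:
                    cols.append(cand)
                    break
            else:
                missing.append(vid)
        if missing:
            raise KeyError(
                f"score {sdef.label}: variants absent from dosage table: {missing}"
            )
        mat = X[cols].to_numpy(float)
        bad = (mat < -1e-9) | (mat > 2 + 1e-9)
        if np.any(bad & np.isfinite(mat)):
            raise ValueError(f"score {sdef.label}: dosages outside [0, 2]")
        if self.coded_alleles:
            for j, v in enumerate(sdef.variants):
                coded = self.coded_alleles.get(v.variant_id)
                if coded is None or coded == v.effect_allele:
                    continue
                if coded != v.other_allele:
                    raise ValueError(
                        f"variant {v.variant_id}: coded allele {coded!r} matches "
                        f"neither {v.effect_allele!r} nor {v.other_allele!r}"
                    )
                mat[:, j] = 2.0 - mat[:, j]
        return mat

    def fit(self, X: pd.DataFrame, y=None) -> "GeneticRiskScorer":
        X = pd.DataFrame(X)
        self.allele_freqs_ = {}
        self.means_ = {}
        self.sds_ = {}
        for sdef in self.score_definitions:
            mat = self._dosage_matrix(X, sdef)
            with np.errstate(invalid="ignore"):
                freqs = np.nanmean(mat, axis=0) / 2.0
            if np.any(~np.isfinite(freqs)):
                bad = [v for v, f in zip(sdef.variant_ids, freqs) if not np.isfinite(f)]
                raise ValueError(
                    f"score {sdef.label}: variants with no observed dosages: {bad}"
                )
            for vid, f in zip(sdef.variant_ids, freqs):
                self.allele_freqs_[vid] = float(f)
            raw = self._raw(mat, sdef)
            sd = float(np.std(raw, ddof=1)) if raw.size > 1 else 0.0
            if sd == 0.0 and self.standardize:
                raise ValueError(
                    f"score {sdef.label} has zero variance in this cohort "
                    "(all contributing variants monomorphic); cannot standardize"
                )
            self.means_[sdef.label] = float(np.mean(raw))
            self.sds_[sdef.label] = sd
        return self

    def _raw(self, mat: np.ndarray, sdef: ScoreDefinition) -> np.ndarray:
        mat = mat.copy()
        for j, vid in enumerate(sdef.variant_ids):
            col = mat[:, j]
            if np.any(~np.isfinite(col)):
                freq = self.allele_freqs_.get(vid)
                if freq is None:  # during fit, before freqs stored
                    freq = np.nanmean(col) / 2.0
                col[~np.isfinite(col)] = 2.0 * freq
        return mat @ sdef.weights

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "means_"):
            raise RuntimeError("GeneticRiskScorer is not fitted")
        X = pd.DataFrame(X)
        out = {}
        for sdef in self.score_definitions:
            raw = self._raw(self._dosage_matrix(X, sdef), sdef)
            out[sdef.label] = raw
            if self.standardize:
                out[f"{sdef.label}_std"] = (
                    raw - self.means_[sdef.label]
                ) / self.sds_[sdef.label]
        return pd.DataFrame(out, index=X.index)


class FactorialGrouper(TransformerMixin, BaseEstimator):
    """Dichotomize each score at its within-cohort median into 2^k groups.

    Parameters
    ----------
    rule : {">=", ">"}, default ">="
        Tie rule at the median. With ``>=`` individuals exactly at the
        median join the lower-lipid arm, so the reference arm is strictly
        below the median; discrete scores can mass many ties there.
    thresholds : dict, optional
        Explicit per-score thresholds overriding the fitted medians.

    Attributes
    ----------
    medians_ : dict of score label -> dichotomization threshold.
    """

    def __init__(self, rule: str = ">=", thresholds: dict[str, float] | None = None):
        self.rule = rule
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y=None) -> "FactorialGrouper":
        X = pd.DataFrame(X)
        if self.rule not in (">=", ">"):
            raise ValueError(f"rule must be '>=' or '>', got {self.rule!r}")
        if X.shape[1] < 1:
            raise ValueError("at least one score vector is required")
        self.medians_ = {}
        for col in X.columns:
            vals = X[col].to_numpy(float)
            if self.thresholds and col in self.thresholds:
                self.medians_[col] = float(self.thresholds[col])
                continue
            if np.nanmin(vals) == np.nanmax(vals):
                raise ValueError(
                    f"score {col!r} is constant; the median split is undefined — "
                    "pass an explicit threshold via `thresholds`"
                )
            self.medians_[col] = float(np.nanmedian(vals))
        return self

    def transform(self, X: pd.DataFrame) -> FactorialAssignment:
        if not hasattr(self, "medians_"):
            raise RuntimeError("FactorialGrouper is not fitted")
        X = pd.DataFrame(X)
        ind = {}
        for col in X.columns:
            thr = self.medians_[col]
            vals = X[col].to_numpy(float)
            ind[col] = (vals >= thr if self.rule == ">=" else vals > thr).astype(int)
        indicators = pd.DataFrame(ind, index=X.index)
        labels = pd.Series(
            [_group_label(row) for row in indicators.to_numpy()],
            index=X.index,
            name="group",
        )
        return FactorialAssignment(indicators=indicators, medians=dict(self.medians_), labels=labels)


def compute_grs(
    dosages: pd.DataFrame,
    score_def: ScoreDefinition,
    standardize: bool = True,
    coded_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Raw (and SD-standardized) weighted score for one definition."""
    scorer = GeneticRiskScorer(
        [score_def], standardize=standardize, coded_alleles=coded_alleles
    )
    return scorer.fit(dosages).transform(dosages)


def assign_factorial_groups(
    scores: pd.DataFrame, rule: str = ">=", thresholds: dict[str, float] | None = None
) -> FactorialAssignment:
    """Median-split one or more score vectors into 2^k factorial groups."""
    return FactorialGrouper(rule=rule, thresholds=thresholds).fit(scores).transform(scores)


def derive_cad_status(icd10_codes) -> np.ndarray:
    """Binary CAD status from per-individual ICD-10 code lists.

    Case iff any code's 3-character root is one of I20 (angina pectoris),
    I21/I22 (myocardial infarction) or I24/I25 (acute and chronic ischemic
    heart disease). Sub-codes such as I21.4 match by root; unrecognized
    codes are ignored.
    """
    out = np.zeros(len(icd10_codes), dtype=int)
    for i, codes in enumerate(icd10_codes):
        if codes is None:
            continue
        if isinstance(codes, str):
            codes = [codes]
        for code in codes:
            if str(code).strip().upper()[:3] in CAD_ICD10_ROOTS:
                out[i] = 1
                break
    return out


def read_score_definitions(path: str) -> list[ScoreDefinition]:
    """Read score definitions from TSV (label, variant_id, effect_allele,
    other_allele, weight), one row per variant."""
    tab = pd.read_csv(path, sep="\t", dtype={"label": str, "variant_id": str})
    required = {"label", "variant_id", "effect_allele", "other_allele", "weight"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    defs = []
    for label, grp in tab.groupby("label", sort=False):
        variants = [
            ScoreVariant(r.variant_id, r.effect_allele, r.other_allele, float(r.weight))
            for r in grp.itertuples()
        ]
        defs.append(ScoreDefinition(label=str(label), variants=variants))
    return defs


def read_dosages(path: str) -> pd.DataFrame:
    """Read genotype dosages from TSV (individuals x variants) or VCF.

    VCF files must carry a per-sample ``DS`` FORMAT field; the effect of
    the ALT allele is counted, one column per variant (ID or chrom:pos).
    """
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        from cyvcf2 import VCF

        vcf = VCF(path)
        samples = list(vcf.samples)
        cols: dict[str, np.ndarray] = {}
        for rec in vcf:
            name = rec.ID or f"{rec.CHROM}:{rec.POS}"
            ds = rec.format("DS")
            if ds is None:
                raise ValueError(f"variant {name}: VCF has no DS format field")
            cols[name] = np.asarray(ds, float).reshape(-1)
        return pd.DataFrame(cols, index=pd.Index(samples, name="id"))
    df = pd.read_csv(path, sep="\t")
    if "id" in df.columns:
        df = df.set_index("id")
    return df
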