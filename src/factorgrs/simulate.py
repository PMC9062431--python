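"""Synthetic cohort generation.

Genotypes are drawn under Hardy-Weinberg equilibrium with linkage
equilibrium across variants (the real scores use variants selected to be
independent), lipids and a block-correlated metabolite panel are linear in
the standardized genetic scores, and CAD status is Bernoulli with a logit
whose intercept is solved numerically to hit the target marginal incidence.
Optional BMI-stratified oversampling reproduces the design of cohorts that
deliberately over-recruit high-BMI participants, returning the sampling
weights needed to recover population parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimConfig, BmiStratum
from .scores import GeneticRiskScorer, ScoreDefinition, ScoreVariant

__all__ = [
    "generate_genotypes",
    "generate_phenotypes",
    "apply_bmi_oversampling",
    "simulate_cohort",
    "write_cohort",
]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def generate_genotypes(config: SimConfig) -> pd.DataFrame:
    """Draw dosages binomial(2, allele_freq) per variant, independently.

    Columns are ``dosage_<variant id>``; optional missingness (MCAR at
    ``config.missing_rate``) is applied afterwards as NaN.
    """
    rng = _rng(config, 1)
    n = config.n_individuals
    data = {}
    for v in config.variants:
        col = rng.binomial(2, v.allele_freq, size=n).astype(float)
        data[f"dosage_{v.id}"] = col
    df = pd.DataFrame(data, index=pd.RangeIndex(n, name="row"))
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        arr = df.to_numpy()
        arr[mask] = np.nan
        df.iloc[:, :] = arr
    return df


def _score_definitions(config: SimConfig) -> list[ScoreDefinition]:
    defs = []
    for label in config.score_labels:
        variants = [
            ScoreVariant(v.id, "A", "B", v.weight)
            for v in config.variants
            if v.score_label == label
        ]
        defs.append(ScoreDefinition(label=label, variants=variants))
    return defs


def _block_noise(rng: np.random.Generator, n: int, blocks) -> np.ndarray:
    """Unit-variance Gaussian noise with compound-symmetric blocks."""
    cols = []
    for size, rho in blocks:
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, size))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep)
    return np.concatenate(cols, axis=1)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    def gap(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target incidence {target} unreachable: achievable range is "
            f"[{np.mean(expit(lo + eta)):.3g}, {np.mean(expit(hi + eta)):.3g}]"
        )
    return brentq(gap, lo, hi, xtol=1e-10)


def generate_phenotypes(dosages: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Build the full cohort table from dosages.

    TG and LDL-C (SD units) are linear in the standardized scores plus
    Gaussian noise; the metabolite panel is score effects plus
    block-correlated noise with the lowest ``lod_quantile`` fraction of
    each measure censored to missing (below detection limit); CAD is
    Bernoulli on a logistic scale including score and covariate effects.
    The true generating parameters are stored in ``df.attrs['truth']``.
    """
    rng = _rng(config, 2)
    n = len(dosages)

    scorer = GeneticRiskScorer(_score_definitions(config)).fit(dosages)
    scores = scorer.transform(dosages)
    labels = config.score_labels
    Z = scores[[f"{lab}_std" for lab in labels]].to_numpy()

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 38.0, 75.0)
    sex = rng.binomial(1, config.sex_male_prob, n)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 60.0)
    pcs = rng.standard_normal((n, 10))

    # stratum-specific TG effect modifiers (identity when no strata given)
    tg_mult = np.ones(n)
    if config.bmi_strata:
        for s in config.bmi_strata:
            tg_mult[s.contains(bmi)] = s.tg_effect_multiplier

    tg_eff = np.array([config.tg_effects.get(lab, 0.0) for lab in labels])
    ldl_eff = np.array([config.ldlc_effects.get(lab, 0.0) for lab in labels])
    tg_sig = np.sqrt(max(0.25, 1.0 - float(tg_eff @ tg_eff)))
    ldl_sig = np.sqrt(max(0.25, 1.0 - float(ldl_eff @ ldl_eff)))
    tg = (Z * tg_mult[:, None]) @ tg_eff + rng.normal(0.0, tg_sig, n)
    ldlc = Z @ ldl_eff + rng.normal(0.0, ldl_sig, n)

    eff = config.effect_matrix()
    E = np.column_stack([eff.get(lab, np.zeros(config.n_metabolites)) for lab in labels])
    mets = Z @ E.T + _block_noise(rng, n, config.metabolite_blocks)

    if config.lod_quantile > 0:
        k = int(np.floor(config.lod_quantile * n))
        if k > 0:
            order = np.argsort(mets, axis=0, kind="stable")
            rows = order[:k, :]
            mets[rows, np.arange(mets.shape[1])[None, :]] = np.nan

    cov = config.cad_covariate_log_or
    beta = np.array([config.cad_log_or_per_score.get(lab, 0.0) for lab in labels])
    eta = (
        Z @ beta
        + cov.get("age", 0.0) * (age - config.age_mean)
        + cov.get("sex", 0.0) * (sex - config.sex_male_prob)
        + cov.get("bmi", 0.0) * (bmi - config.bmi_mean)
    )
    intercept = _solve_intercept(eta, config.cad_incidence)
    cad = rng.binomial(1, expit(intercept + eta))

    cols: dict[str, np.ndarray] = {"id": np.array([f"ind{i:07d}" for i in range(n)])}
    for c in dosages.columns:
        cols[c] = dosages[c].to_numpy()
    for lab in labels:
        cols[f"grs_{lab.lower()}"] = scores[lab].to_numpy()
        cols[f"grs_{lab.lower()}_std"] = scores[f"{lab}_std"].to_numpy()
    cols.update(age=age, sex=sex, bmi=bmi)
    for j in range(10):
        cols[f"pc{j + 1}"] = pcs[:, j]
    cols.update(tg=tg, ldlc=ldlc, cad=cad, weight=np.ones(n))
    for m in range(config.n_metabolites):
        cols[f"m{m + 1}"] = mets[:, m]
    df = pd.DataFrame(cols, index=dosages.index)

    df.attrs["truth"] = {
        "score_labels": labels,
        "tg_effects": {lab: float(config.tg_effects.get(lab, 0.0)) for lab in labels},
        "ldlc_effects": {lab: float(config.ldlc_effects.get(lab, 0.0)) for lab in labels},
        "cad_log_or_per_score": {
            lab: float(config.cad_log_or_per_score.get(lab, 0.0)) for lab in labels
        },
        "cad_intercept": float(intercept),
        "metabolite_effects": {lab: eff.get(lab, np.zeros(config.n_metabolites)).tolist() for lab in labels},
        "cad_incidence": float(config.cad_incidence),
    }
    return df


def apply_bmi_oversampling(
    cohort: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, dict]:
    """Resample the cohort with BMI-stratum sampling multipliers.

    Each individual is drawn into the biased sample with expected
    multiplicity equal to their stratum's ``sampling_multiplier`` (floor
    copies plus a Bernoulli on the fractional part), emulating designed
    oversampling of high-BMI participants. The returned sample carries
    Horvitz-Thompson weights ``1 / multiplier``; the second return value
    records the generating population parameters (stratum fractions,
    population TG mean, marginal score->TG effects averaged over strata)
    so weighted analyses can be validated by recovery.
    """
    if not config.bmi_strata:
        raise ValueError("config.bmi_strata is not set; nothing to oversample")
    rng = _rng(config, 3)
    bmi = cohort["bmi"].to_numpy(float)
    copies = np.zeros(len(cohort), dtype=int)
    assigned = np.zeros(len(cohort), dtype=bool)
    mult = np.ones(len(cohort))
    fractions = {}
    for s in config.bmi_strata:
        mask = s.contains(bmi) & ~assigned
        if not mask.any():
            raise ValueError(
                f"BMI stratum [{s.lower}, {s.upper}) contains no individuals"
            )
        assigned |= mask
        mult[mask] = s.sampling_multiplier
        fractions[f"[{s.lower},{s.upper})"] = float(mask.mean())
        base = int(np.floor(s.sampling_multiplier))
        frac = s.sampling_multiplier - base
        copies[mask] = base + (rng.random(mask.sum()) < frac)
    if not assigned.all():
        raise ValueError("bmi_strata do not cover all individuals")

    idx = np.repeat(np.arange(len(cohort)), copies)
    sampled = cohort.iloc[idx].copy()
    sampled["weight"] = 1.0 / mult[idx]
    sampled = sampled.reset_index(drop=True)

    labels = config.score_labels
    pop_tg_effect = {}
    for j, lab in enumerate(labels):
        base = config.tg_effects.get(lab, 0.0)
        mods = np.ones(len(cohort))
        for s in config.bmi_strata:
            mods[s.contains(bmi)] = s.tg_effect_multiplier
        pop_tg_effect[lab] = float(base * mods.mean())
    truth = {
        "population_n": int(len(cohort)),
        "stratum_fractions": fractions,
        "population_tg_mean": float(cohort["tg"].mean()),
        "population_tg_effects": pop_tg_effect,
    }
    return sampled, truth


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Genotypes + phenotypes in one call (deterministic in config.seed)."""
    return generate_phenotypes(generate_genotypes(config), config)


def write_cohort(cohort: pd.DataFrame, out_dir: str | Path, name: str = "cohort") -> Path:
    """Write the cohort TSV and a JSON sidecar of true generating parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}.tsv"
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")
    truth = cohort.attrs.get("truth")
    if truth is not None:
        with open(out / f"{name}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return path
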