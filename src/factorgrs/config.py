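"""Simulation configuration for synthetic lipid-genetics cohorts.

The generator emulates the statistical structure a factorial genetic
association analysis assumes: Hardy-Weinberg genotypes in linkage
equilibrium, lipid phenotypes driven linearly by weighted allele scores,
a block-correlated NMR-style metabolite panel with detection-limit
censoring, a logistic coronary-artery-disease (CAD) outcome, and optional
BMI-stratified oversampling with known sampling multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import math

import numpy as np
import yaml

#: upper-half minus lower-half conditional mean of a standard normal score,
#: E[Z | Z >= 0] - E[Z | Z < 0] = 2*sqrt(2/pi); converts a per-SD effect into
#: the expected median-split group contrast for an approximately normal score.
NORMAL_HALF_GAP = 2.0 * math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class Variant:
    """One biallelic variant contributing to a weighted genetic score.

    ``weight`` is the per-allele effect of the coded (lipid-lowering) allele
    in SD units of the lipid; scores are oriented so that a higher score
    means a genetically lower lipid level, hence weights are positive.
    """

    id: str
    allele_freq: float
    weight: float
    score_label: str

    def __post_init__(self) -> None:
        if not (0.0 < self.allele_freq < 1.0) or not np.isfinite(self.allele_freq):
            raise ValueError(
                f"allele_freq for {self.id} must lie strictly in (0,1), "
                f"got {self.allele_freq!r}"
            )
        if not np.isfinite(self.weight) or self.weight == 0.0:
            raise ValueError(f"weight for {self.id} must be finite and non-zero")


@dataclass(frozen=True)
class BmiStratum:
    """BMI stratum with a sampling multiplier (and optional effect modifier).

    ``sampling_multiplier`` is the expected number of copies of each stratum
    member drawn into the biased sample (NEO-style oversampling of high BMI).
    ``tg_effect_multiplier`` scales the score->TG effects inside the stratum,
    which lets tests create effect heterogeneity that only a weighted
    analysis averages correctly.
    """

    lower: float
    upper: float
    sampling_multiplier: float = 1.0
    tg_effect_multiplier: float = 1.0

    def contains(self, bmi: np.ndarray) -> np.ndarray:
        return (bmi >= self.lower) & (bmi < self.upper)


@dataclass
class SimConfig:
    """Full description of one synthetic cohort.

    Defaults mirror the study conditions of a large population biobank:
    ~11.7% CAD incidence, 43% male, a 145-measure correlated metabolite
    panel, and three lipid scores (APOA5 and LPL for triglycerides, a
    15-variant LDL-C score).
    """

    n_individuals: int = 10_000
    variants: list[Variant] = field(default_factory=lambda: default_variants())
    n_metabolites: int = 145
    metabolite_blocks: list[tuple[int, float]] = field(
        default_factory=lambda: list(DEFAULT_BLOCKS)
    )
    score_effect_matrix: dict[str, np.ndarray] | None = None
    tg_effects: dict[str, float] = field(
        default_factory=lambda: {"APOA5": -0.25, "LPL": -0.15}
    )
    ldlc_effects: dict[str, float] = field(default_factory=lambda: {"LDLC": -0.30})
    cad_incidence: float = 0.117
    cad_log_or_per_score: dict[str, float] = field(
        default_factory=lambda: {
            # per-SD log-odds chosen so median-split group contrasts land at
            # odds ratios ~0.95 (APOA5), ~0.94 (LPL) and ~0.87 (LDL-C arm)
            "APOA5": math.log(0.95) / NORMAL_HALF_GAP,
            "LPL": math.log(0.94) / NORMAL_HALF_GAP,
            "LDLC": math.log(0.87) / NORMAL_HALF_GAP,
        }
    )
    cad_covariate_log_or: dict[str, float] = field(
        default_factory=lambda: {"age": 0.055, "sex": 0.95, "bmi": 0.04}
    )
    lod_quantile: float = 0.0
    missing_rate: float = 0.0
    bmi_strata: list[BmiStratum] | None = None
    sex_male_prob: float = 0.43
    age_mean: float = 56.8
    age_sd: float = 8.0
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        for p, name in (
            (self.cad_incidence, "cad_incidence"),
            (self.lod_quantile, "lod_quantile"),
            (self.missing_rate, "missing_rate"),
            (self.sex_male_prob, "sex_male_prob"),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {p!r}")
        sizes = [b[0] for b in self.metabolite_blocks]
        if sum(sizes) != self.n_metabolites:
            raise ValueError(
                f"metabolite block sizes sum to {sum(sizes)}, "
                f"expected n_metabolites={self.n_metabolites}"
            )
        for _, rho in self.metabolite_blocks:
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"within-block correlation must be in [0,1), got {rho}")
        if self.score_effect_matrix is not None:
            for label, eff in self.score_effect_matrix.items():
                arr = np.asarray(eff, dtype=float)
                if arr.shape != (self.n_metabolites,):
                    raise ValueError(
                        f"score_effect_matrix[{label!r}] has shape {arr.shape}, "
                        f"expected ({self.n_metabolites},)"
                    )

    @property
    def score_labels(self) -> list[str]:
        seen: list[str] = []
        for v in self.variants:
            if v.score_label not in seen:
                seen.append(v.score_label)
        return seen

    def effect_matrix(self) -> dict[str, np.ndarray]:
        """Per-score metabolite effect vectors (SD units per SD of score)."""
        if self.score_effect_matrix is not None:
            return {k: np.asarray(v, float) for k, v in self.score_effect_matrix.items()}
        return default_effect_matrix(self.n_metabolites, self.metabolite_blocks)


#: (block size, within-block correlation); blocks stand in for lipoprotein
#: subclass families (VLDL, LDL, HDL, fatty acids, other lipids, low-MW
#: metabolites) and sum to the 145-measure panel.
DEFAULT_BLOCKS: tuple[tuple[int, float], ...] = (
    (20, 0.90),
    (15, 0.85),
    (20, 0.85),
    (20, 0.75),
    (30, 0.70),
    (40, 0.65),
)


def default_variants() -> list[Variant]:
    """Default variant set: 2 APOA5 + 5 LPL triglyceride variants, 15 LDL-C.

    Frequencies and weights are configuration stand-ins of realistic
    magnitude (per-SD score-on-lipid associations around 0.1-0.3 SD);
    real analyses supply their own weight tables.
    """
    tg = [
        Variant("rs662799", 0.92, 0.40, "APOA5"),
        Variant("rs3135506", 0.94, 0.25, "APOA5"),
        Variant("rs268", 0.98, 0.15, "LPL"),
        Variant("rs301", 0.74, 0.08, "LPL"),
        Variant("rs326", 0.70, 0.09, "LPL"),
        Variant("rs328", 0.10, 0.17, "LPL"),
        Variant("rs10096633", 0.12, 0.10, "LPL"),
    ]
    ldl = [
        Variant(f"rsLDL{i + 1:02d}", f, w, "LDLC")
        for i, (f, w) in enumerate(
            [
                (0.12, 0.12), (0.22, 0.09), (0.31, 0.07), (0.38, 0.06),
                (0.45, 0.05), (0.52, 0.05), (0.58, 0.04), (0.63, 0.04),
                (0.68, 0.04), (0.73, 0.03), (0.78, 0.03), (0.82, 0.03),
                (0.86, 0.02), (0.89, 0.02), (0.92, 0.02),
            ]
        )
    ]
    return tg + ldl


def default_effect_matrix(
    n_metabolites: int, blocks: list[tuple[int, float]] | tuple = DEFAULT_BLOCKS
) -> dict[str, np.ndarray]:
    """Deterministic per-score metabolite effect vectors.

    Both TG scores act through a shared lipoprotein pattern (lower VLDL/LDL,
    higher HDL) with the APOA5 effects larger in magnitude and the LPL score
    carrying an extra HDL-raising component, so the two effect profiles are
    strongly but not perfectly concordant.
    """
    base_by_block = [-1.0, -0.5, 0.5, -0.6, -0.3, 0.0]
    shared = np.empty(n_metabolites)
    hdl_mask = np.zeros(n_metabolites, bool)
    start = 0
    for j, (size, _) in enumerate(blocks):
        scale = np.linspace(0.8, 1.2, size)
        shared[start : start + size] = base_by_block[j % len(base_by_block)] * scale
        if j == 2:  # HDL-like block
            hdl_mask[start : start + size] = True
        start += size
    idx = np.arange(n_metabolites)
    wiggle_a = 0.02 * np.sin(0.7 * idx)
    wiggle_l = 0.02 * np.cos(1.3 * idx)
    apoa5 = 0.11 * shared + wiggle_a
    lpl = 0.05 * shared + wiggle_l + 0.05 * hdl_mask
    return {"APOA5": apoa5, "LPL": lpl, "LDLC": np.zeros(n_metabolites)}


def load_config(path: str) -> SimConfig:
    """Read a :class:`SimConfig` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "variants" in raw:
        raw["variants"] = [Variant(**v) for v in raw["variants"]]
    if "bmi_strata" in raw and raw["bmi_strata"] is not None:
        raw["bmi_strata"] = [BmiStratum(**s) for s in raw["bmi_strata"]]
    if "metabolite_blocks" in raw:
        raw["metabolite_blocks"] = [tuple(b) for b in raw["metabolite_blocks"]]
    return SimConfig(**raw)


def dump_config(config: SimConfig, path: str) -> None:
    data = asdict(config)
    if data.get("score_effect_matrix"):
        data["score_effect_matrix"] = {
            k: np.asarray(v, float).tolist()
            for k, v in data["score_effect_matrix"].items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
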