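import numpy as np
import pandas as pd
import pytest

import factorgrs as fg


@pytest.fixture(scope="session")
def small_config():
    """Tiny metabolite panel so per-test simulation stays cheap."""
    return fg.SimConfig(
        n_individuals=3000,
        n_metabolites=6,
        metabolite_blocks=[(3, 0.6), (3, 0.2)],
        seed=42,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return fg.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def null_cohort_big():
    """n=50,000 cohort with every genetic effect switched off; shared by the
    incidence, null-correlation and block-correlation checks."""
    cfg = fg.SimConfig(
        n_individuals=50_000,
        tg_effects={},
        ldlc_effects={},
        cad_log_or_per_score={},
        score_effect_matrix={
            "APOA5": np.zeros(145),
            "LPL": np.zeros(145),
            "LDLC": np.zeros(145),
        },
        cad_incidence=0.117,
        seed=7,
    )
    return cfg, fg.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_score_frame(rng):
    return pd.DataFrame(
        {"A": rng.standard_normal(400), "B": rng.standard_normal(400)}
    )
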