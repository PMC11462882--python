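import numpy as np
import pandas as pd
import pytest

from rmstprofile.simulate import SimConfig, generate_population


@pytest.fixture(scope="session")
def toy_episodes() -> pd.DataFrame:
    """Five-patient cohort small enough to hand-compute every estimator:
    product-limit survival 4/5 on [2,6), 8/15 on [6,8), 4/15 on [8, inf)."""
    return pd.DataFrame({
        "patient_id": np.arange(5),
        "time_days": [2.0, 4.0, 6.0, 8.0, 12.0],
        "status": ["noncompliance", "censored", "competing", "noncompliance", "censored"],
        "entity": [0] * 5,
    })


@pytest.fixture(scope="session")
def small_bundle():
    """A small confounded cohort (m=3, n=600) shared across tests."""
    cfg = SimConfig(n_patients=600, n_entities=3, seed=42,
                    entity_effect_vector=(0.0, 0.3, -0.3))
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def small_frame(small_bundle):
    """Episode table joined with covariates for the small cohort."""
    from rmstprofile.episodes import EpisodeParams, build_cohort_episodes

    cfg, bundle = small_bundle
    eps = build_cohort_episodes(bundle, EpisodeParams())
    return cfg, eps.merge(bundle.patients.drop(columns=["discharge_day"]),
                          on="patient_id", validate="1:1")
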