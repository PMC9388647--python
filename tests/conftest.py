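import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import xwasmeta as xm

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_collection():
    """A small but structurally complete survey collection.

    3 countries x 2 waves x 2 sexes = 12 surveys, one planted binary
    effect (OR 2.5 in both sexes), duplicate groups, label conflicts.
    """
    cfg = xm.SyntheticConfig(
        n_countries=3, waves_per_country=2, n_per_survey=800,
        n_variables=24, n_clusters_per_survey=40, n_duplicate_groups=2,
        planted_effects=[xm.PlantedEffect.symmetric("v001", np.log(2.5))],
        label_conflict_rate=0.5, seed=42)
    datasets, truth = xm.generate_multisurvey(cfg)
    datasets = xm.inject_label_conflicts(datasets, cfg.label_conflict_rate,
                                         seed=43)
    return cfg, datasets, truth
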