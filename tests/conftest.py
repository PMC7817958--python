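import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import resq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size default-configuration cohort shared across read-only tests."""
    cfg = resq.default_config(n_participants=3000, seed=1)
    cohort, truth = resq.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    """Complete participants with exposure, symptom and resilience columns."""
    _, cohort, _ = default_cohort
    participants, _ = resq.clean(cohort)
    complete = participants[participants["complete"]].reset_index(drop=True)
    return resq.compute_all(resq.score_cohort(complete))


def orthogonal_config(**overrides):
    """Generator config with independent factors and no structural paths,
    used where a test needs marginal regressions to recover the weights."""
    base = dict(
        factor_correlation=np.eye(len(resq.FACTORS)),
        mediation_paths={"a1": 0.0, "a2": 0.0},
        missingness=0.0,
    )
    base.update(overrides)
    return resq.default_config(**base)


def pipeline_frame(cfg) -> pd.DataFrame:
    """Run generation -> cleaning -> scoring -> resilience for a config."""
    cohort, _ = resq.generate_cohort(cfg)
    participants, _ = resq.clean(cohort)
    complete = participants[participants["complete"]].reset_index(drop=True)
    return resq.compute_all(resq.score_cohort(complete))
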