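import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from oridisc.cohort import CohortSpec, generate_study_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic study (6 subjects, 4 reps/cell)."""
    spec = CohortSpec(n_subjects=6)
    trials, truth = generate_study_dataset(
        spec, np.random.default_rng(777), design_kwargs={"reps_per_cell": 4}
    )
    return {"spec": spec, "trials": trials, "truth": truth}


@pytest.fixture(scope="session")
def small_threshold_table(small_cohort):
    from oridisc.psychometric import fit_threshold_table

    return fit_threshold_table(small_cohort["trials"])


def make_balanced_threshold_table(rng, n_subjects=8, effects=(0.0, 0.5, 1.0),
                                  subject_sd=0.5, noise_sd=0.3):
    """Synthetic subject x level threshold table with known structure."""
    rows = []
    intercepts = rng.normal(0, subject_sd, n_subjects)
    for i in range(n_subjects):
        for j, eff in enumerate(effects):
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "noise_scale": float(j),
                    "threshold_sigma_deg": 2.0 + eff + intercepts[i]
                    + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
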