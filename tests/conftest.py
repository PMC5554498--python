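import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import movemetrics as mm
from movemetrics.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort (3 controls, 1 patient/stage) with all 12 trials."""
    config = GeneratorConfig(n_controls=3, n_patients_per_stage=(1, 1, 1), seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def one_session(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def one_patient_session(small_cohort):
    return next(s for s in small_cohort if s.group == "patient")


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return mm.build_cohort_table(small_cohort)


def make_laterality_table(n_controls=10, n_per_stage=8, asymmetry=(0.85, 0.7, 0.55),
                          level=(0.7, 0.55, 0.4), control_asymmetry=1.0,
                          noise=0.02, seed=0):
    """Constructed cohort table with a single controllable asymmetric MPI.

    Builds only the two hand columns of one MPI base plus labels -- a cheap
    deterministic stand-in for a generated cohort in predicate unit tests.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    idx = []
    for i in range(n_controls):
        base = np.exp(rng.normal(0, 0.2))
        rows.append({
            "emg-mav_GPP-EL_R": base * control_asymmetry * (1 + rng.normal(0, noise)),
            "emg-mav_GPP-EL_L": base * (1 + rng.normal(0, noise)),
            "group": "control", "hy_stage": None, "affected_side": None,
        })
        idx.append(f"C{i}")
    k = 0
    for stage in (1, 2, 3):
        for i in range(n_per_stage):
            side = "R" if k % 2 == 0 else "L"
            base = np.exp(rng.normal(0, 0.2)) * level[stage - 1]
            aff = base * asymmetry[stage - 1] * (1 + rng.normal(0, noise))
            unaff = base * (1 + rng.normal(0, noise))
            rows.append({
                "emg-mav_GPP-EL_R": aff if side == "R" else unaff,
                "emg-mav_GPP-EL_L": unaff if side == "R" else aff,
                "group": "patient", "hy_stage": stage, "affected_side": side,
            })
            idx.append(f"P{k}")
            k += 1
    import pandas as pd
    return pd.DataFrame(rows, index=idx)
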