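import numpy as np
import pytest

from kin2emg.synthetic_data import (
    ArmModel,
    StudyConfig,
    base_emg_model,
    default_task_catalog,
    generate_study,
)


@pytest.fixture(scope="session")
def arm():
    return ArmModel()


@pytest.fixture(scope="session")
def catalog():
    return default_task_catalog()


@pytest.fixture(scope="session")
def gt_model():
    return base_emg_model()


@pytest.fixture(scope="session")
def mini_manifest(catalog):
    """Small study shared across tests: 2 subjects x 4 tasks x 6 repetitions."""
    names = {t.name: t for t in catalog}
    tasks = [
        names["shoulder flexion (90)"],
        names["elbow flexion"],
        names["reading a watch"],
        names["drawing a line"],
    ]
    cfg = StudyConfig(n_subjects=2, n_reps=6, tasks=tasks, rest_pad=0.3)
    return generate_study(cfg, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
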