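import numpy as np
import pytest

from fogvision.modeling import ModelConfig
from fogvision.pipeline import extract_cohort
from fogvision.synthetic import SimParams, simulate_cohort, simulate_recording


def tiny_sim_params(**overrides) -> SimParams:
    """A small, fast cohort: short recordings, one test per subject."""
    defaults = dict(
        n_subjects=6,
        tests=("TUG",),
        walk_s=(6.0, 8.0),
        turn_s=(2.0, 2.5),
        fog_duration_s=(1.5, 5.0),
        seed=0,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def tiny_model_config(seed: int = 0) -> ModelConfig:
    cfg = ModelConfig.fast(seed=seed)
    cfg.grid = {
        "learning_rate": [0.1],
        "n_estimators": [25],
        "max_depth": [3],
        "subsample": [1.0],
        "colsample_bytree": [1.0],
    }
    cfg.selection_sizes = (1, 3, 8, 15)
    return cfg


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six short synthetic recordings with ground truth."""
    return simulate_cohort(tiny_sim_params())


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    """(feature matrix, annotation map) for the tiny cohort."""
    return extract_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def fog_recording():
    """One recording with two injected FOG episodes."""
    params = tiny_sim_params(walk_s=(8.0, 10.0))
    return simulate_recording(params, subject_seed=3, subject_id="S04",
                              test_id="TUG", n_fog_episodes=2)


@pytest.fixture(scope="session")
def tiny_loso(tiny_dataset):
    """Staged LOSO evaluation of the tiny cohort."""
    from fogvision.inference_eval import loso_evaluate

    matrix, annotations = tiny_dataset
    return loso_evaluate(matrix, annotations, tiny_model_config(), staged=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
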