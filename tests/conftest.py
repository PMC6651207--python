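import numpy as np
import pytest

from leansense import (
    build_image_dataset,
    make_cohort,
    make_regime_config,
    simulate_recording,
)
from leansense.preprocess import preprocess
from leansense.task import script_for


@pytest.fixture(scope="session")
def regime_windows():
    """One preprocessed 250-s analysis window per regime (seed fixed)."""
    out = {}
    for regime, subtask in (("KATA", "KATA-III"), ("CPDnA", "Plan")):
        model = make_regime_config(regime, seed=1)
        rec = simulate_recording(model, script_for(regime), fs=128, seed=1)
        out[regime] = (model, preprocess(rec).subtask_window(subtask))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Four preprocessed subjects (8 recordings) for dataset-level tests."""
    return [preprocess(r) for r in make_cohort(4, 128, seed=5)]


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_image_dataset(small_cohort)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """The full study-scale image dataset: 24 subjects x 2 tasks x 250-s
    analysis windows at 1-s segmentation."""
    cohort = [preprocess(r) for r in make_cohort(24, 128, seed=7)]
    return build_image_dataset(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
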