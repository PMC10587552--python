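import numpy as np
import pytest

from acnegrade.datasets import DatasetConfig, generate_subjects
from acnegrade.grader import GraderConfig, train_grader
from acnegrade.rule import DEFAULT_RULE, counts_to_interval


@pytest.fixture(scope="session")
def cohort64():
    """40 synthetic subjects at 64 px (desk scale), fixed seed."""
    return generate_subjects(40, 123, DatasetConfig(side_px=64))


@pytest.fixture(scope="session")
def cohort256():
    """12 synthetic subjects at the 256 px default resolution, fixed seed."""
    return generate_subjects(12, 7, DatasetConfig(side_px=256))


@pytest.fixture(scope="session")
def tiny_grader(cohort64):
    """A quickly trained grader on the 64 px cohort (for fusion/eval tests)."""
    cfg = GraderConfig(epochs=6, resize_side=64, input_side=56, seed=3)
    imgs = [s.image for s in cohort64]
    grades = [s.true_grade for s in cohort64]
    return train_grader(imgs, grades, cfg)


@pytest.fixture(scope="session")
def cohort64_intervals(cohort64):
    return [counts_to_interval(s.true_counts, DEFAULT_RULE) for s in cohort64]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
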