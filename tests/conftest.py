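"""Shared fixtures: small deterministic two-level datasets."""

import numpy as np
import pytest

from groupslope import GroupedData, ScenarioSpec, generate_dataset


@pytest.fixture
def tiny_exact_data():
    """J=3, n=2, zero within-group variation; group x-means (-1, 0, 1) and
    y-means exactly 0.5 * x-means."""
    x = np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.0])
    y = 0.5 * x
    group = np.array(["a", "a", "b", "b", "c", "c"])
    return GroupedData(x=x, y=y, group=group)


@pytest.fixture
def small_random_data():
    """Seeded J=5, n=5 dataset from the generator."""
    spec = ScenarioSpec(icc_x=0.3, J=5, n=5, beta_b=0.5, beta_w=0.5, seed=123)
    return generate_dataset(spec, 0)


def make_dataset(icc_x=0.3, J=10, n=5, beta_b=0.5, beta_w=0.5, seed=0,
                 rep=0, icc_y=0.2):
    spec = ScenarioSpec(icc_x=icc_x, J=J, n=n, beta_b=beta_b, beta_w=beta_w,
                        icc_y=icc_y, seed=seed)
    return generate_dataset(spec, rep)
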