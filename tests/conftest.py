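"""Shared fixtures: synthetic femurs are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

from femplan import axes as A
from femplan.cortex import extract_ridge_profile
from femplan.implant import generate_generic_family
from femplan.synthetic import FemurParams, generate_femur, sample_params

COHORT_SEEDS = list(range(1, 21))


@pytest.fixture(scope="session")
def default_femur():
    """Canonical right femur with its ground truth."""
    return generate_femur(FemurParams())


@pytest.fixture(scope="session")
def default_axes(default_femur):
    mesh, _ = default_femur
    return A.build_axis_set(mesh)


@pytest.fixture(scope="session")
def default_profile(default_femur, default_axes):
    mesh, _ = default_femur
    return extract_ridge_profile(mesh, default_axes.frame, default_axes.landmarks)


@pytest.fixture(scope="session")
def family():
    return generate_generic_family()


@pytest.fixture(scope="session")
def cohort():
    """Twenty jittered femurs with ground truth and detected axes."""
    out = []
    for seed in COHORT_SEEDS:
        mesh, truth = generate_femur(sample_params(seed))
        axes = A.build_axis_set(mesh)
        out.append((seed, mesh, truth, axes))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
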