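"""Shared fixtures: simulated spheroids are expensive, so the common ones
are session-scoped and reused across test modules."""

import warnings

import numpy as np
import pytest

from spheromet.segmentation import SegmentationParams, segment_spheroid
from spheromet.synthetic import MarkerModel, SyntheticSpec, simulate


@pytest.fixture(scope="session")
def default_sphere():
    """Default-noise 100 µm sphere with a 50% uniform marker."""
    spec = SyntheticSpec(
        shape_family="sphere", radius_um=50, rng_seed=11,
        marker_models=(MarkerModel(name="oct4", polarisation="uniform",
                                   p_positive_inside=0.5),))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_sphere():
    spec = SyntheticSpec(shape_family="sphere", radius_um=50, rng_seed=12,
                         noise_poisson_scale=0.0, noise_gaussian_sd=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def sphere_mask3d(default_sphere):
    _, stack, _ = default_sphere
    return segment_spheroid(stack, "dapi", SegmentationParams(mode="3d"))


@pytest.fixture(scope="session")
def counting_spheroid():
    """300 well-separated nuclei for spot-count accuracy checks."""
    spec = SyntheticSpec(shape_family="sphere", radius_um=50, n_nuclei=300,
                         min_spacing_um=8.0, rng_seed=13)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate(spec)
    return spec, stack, truth


def dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
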