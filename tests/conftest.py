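import numpy as np
import pytest

from smlsize import (
    EmitterSpec,
    GaussianKernel,
    LineProfile,
    ModelProfile,
    SimConfig,
    StructuralModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_model():
    return StructuralModel(shape="sphere_surface", radius=50.0)


@pytest.fixture
def kernel20():
    return GaussianKernel(sigma=20.0)


def make_noiseless_profile(
    shape="sphere_surface",
    radius=100.0,
    sigma=20.0,
    amplitude=5000.0,
    background=2.0,
    center=13.0,
    bin_width=5.0,
    half_span=300.0,
):
    """Exact model-generated profile (midpoint convention, no noise)."""
    mp = ModelProfile(
        model=StructuralModel(shape=shape, radius=radius),
        kernel=GaussianKernel(sigma=sigma),
        amplitude=amplitude,
        background=background,
        center=center,
    )
    x = np.arange(-half_span, half_span, bin_width) + bin_width / 2.0 + center
    return LineProfile(
        bin_centers=x, counts=mp.predict(x, bin_width), bin_width=bin_width
    )


@pytest.fixture
def noiseless_profile():
    return make_noiseless_profile()


@pytest.fixture
def bead_spec():
    return EmitterSpec(geometry="sphere_surface", diameter=100.0, n_fluorophores=334)


@pytest.fixture
def bead_cfg():
    return SimConfig(sigma_loc=20.0, blinks_per_fluorophore=3.0, seed=7)
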