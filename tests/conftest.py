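import numpy as np
import pytest

from tvphantom import ExperimentConfig, Image, PhantomSpec, RoiSpec


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A scaled-down phantom (64 px, 4 mm pixels) that renders quickly."""
    return PhantomSpec(
        grid_size=64,
        pixel_mm=4.0,
        cylinder_radius_mm=100.0,
        rod_sectors=((9.5, 2.0), (11.1, 2.0), (12.7, 2.0)),
        center_clear_radius_mm=32.0,
    )


@pytest.fixture(scope="session")
def small_config(small_phantom_spec) -> ExperimentConfig:
    """A reduced study configuration for fast end-to-end tests."""
    return ExperimentConfig(
        phantom=small_phantom_spec,
        roi_a=RoiSpec(center_row=31.5, center_col=31.5, radius_px=4.0, label="A"),
        roi_b=RoiSpec(center_row=5.0, center_col=5.0, radius_px=4.0, label="B"),
        n_replicates=2,
        base_seed=11,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def noisy_small_image(rng) -> Image:
    """A flat 32x32 field with mild Gaussian noise, for solver tests."""
    return Image(0.5 + rng.normal(0.0, 0.03, size=(32, 32)))
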