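import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import implantfem as ifm
from implantfem.synthetic_ct import MandiblePhantomParams, ToothSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_params() -> MandiblePhantomParams:
    """A compact phantom tall enough for a 9 mm implant with default crown."""
    return MandiblePhantomParams(
        extents=(20, 20, 58),
        bone_height_mm=12.48,
        teeth=[
            ToothSpec(
                center_x_mm=3.9,
                center_y_mm=3.9,
                radius_mm=3.0,
                root_depth_mm=8.0,
                crown_height_mm=8.0,
            )
        ],
        seed=7,
    )


@pytest.fixture
def small_volume(small_params) -> ifm.VoxelVolume:
    return ifm.generate_mandible_volume(small_params)


@pytest.fixture
def small_segmented(small_volume) -> ifm.VoxelVolume:
    return ifm.segment_roi(small_volume, 300.0, 10300.0)


def tiny_run_config(outdir: str) -> "ifm.RunConfig":
    """A one-design configuration small enough for repeated end-to-end runs."""
    params = MandiblePhantomParams(
        extents=(20, 20, 28),
        bone_height_mm=7.8,
        teeth=[
            ToothSpec(
                center_x_mm=3.9,
                center_y_mm=3.9,
                radius_mm=2.0,
                root_depth_mm=5.0,
                crown_height_mm=3.0,
            )
        ],
        seed=11,
    )
    return ifm.RunConfig(
        phantom=params,
        diameters_mm=[3.0],
        lengths_mm=[4.5],
        supracrestal_height_mm=3.0,
        crown_radius_mm=2.0,
        cusp_offset_mm=1.0,
        seed=11,
        outdir=outdir,
    )


@pytest.fixture(scope="session")
def default_sweep(tmp_path_factory):
    """The full 12-design sweep at default study conditions (run once)."""
    outdir = tmp_path_factory.mktemp("default_sweep")
    config = ifm.RunConfig(outdir=str(outdir))
    manifest = ifm.run_all(config)
    return manifest
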