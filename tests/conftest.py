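"""Shared fixtures: small synthetic inputs with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from cralekit import ct as ctmod
from cralekit import synthetic as syn


@pytest.fixture(scope="session")
def small_phantom_params() -> syn.PhantomCTParams:
    """A modest gradient phantom used across CT tests."""
    return syn.PhantomCTParams(
        shape=(48, 40, 40),
        spacing_mm=(3.0, 2.5, 2.5),
        lung_centers_mm=((0.0, 0.0, -26.0), (0.0, 0.0, 26.0)),
        semi_axes_mm=((60.0, 35.0, 18.0), (60.0, 35.0, 18.0)),
        base_mean_hu=-549.0,
        vd_slope_hu=150.0,
        noise_sd_hu=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_params):
    return syn.gen_ct_phantom(small_phantom_params)


@pytest.fixture()
def uniform_volume():
    """Factory for a uniform-HU box volume with a box mask."""

    def make(hu: float, shape=(10, 12, 14), spacing=(1.0, 1.0, 1.0)):
        data = np.full(shape, hu, dtype=float)
        mask = np.ones(shape, dtype=bool)
        return (
            ctmod.CTVolume(data=data, spacing_mm=spacing),
            ctmod.LungMask(data=mask),
        )

    return make


@pytest.fixture(scope="session")
def occlusion_trace():
    """Noisy occlusion-pair trace with CL=50, Ccw=100 (Crs=100/3)."""
    params = syn.WaveformParams(
        duration_s=18.0,
        comp_amplitude_cmh2o=0.0,
        occlusions=(
            syn.OcclusionSpec(start_s=3.0, duration_s=5.5, kind="insp"),
            syn.OcclusionSpec(start_s=11.0, duration_s=5.5, kind="exp"),
        ),
        cl_ml_cmh2o=50.0,
        ccw_ml_cmh2o=100.0,
        noise_sd_cmh2o=0.05,
        seed=2,
    )
    return syn.gen_pressure_traces(params)


@pytest.fixture(scope="session")
def cc_trace():
    """60-s compression trace at 102/min with ventilation superimposed."""
    params = syn.WaveformParams(
        duration_s=60.0,
        comp_amplitude_cmh2o=15.0,
        noise_sd_cmh2o=0.2,
        seed=3,
    )
    return syn.gen_pressure_traces(params)
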