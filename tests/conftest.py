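import dataclasses

import numpy as np
import pytest

from holorbc.config import PipelineConfig, SimulationConfig
from holorbc.morphometry import thickness_to_phase
from holorbc.simulate import (
    PhantomCell,
    make_biconcave_phantom,
    make_reference_hologram,
    simulate_off_axis_hologram,
)


@pytest.fixture
def roi_sim() -> SimulationConfig:
    """Region-of-interest scale simulation: 256 px grid, aberrations on."""
    return SimulationConfig(
        grid_shape=(256, 256),
        noise_sigma=0.0,
        aberration_rad=(0.8, -0.5, 1.5, 0.3, -0.2),
        rng_seed=7,
    )


@pytest.fixture
def normal_cell() -> PhantomCell:
    return PhantomCell(diameter_um=7.0, edge_thickness_um=2.0, dimple_depth_frac=0.6)


@pytest.fixture
def phantom_scene(roi_sim, normal_cell):
    """Ground-truth thickness, its phase, and the simulated hologram pair."""
    truth = make_biconcave_phantom(normal_cell, roi_sim.grid_shape, roi_sim.sampling_um_per_px)
    phase = thickness_to_phase(truth, roi_sim)
    holo = simulate_off_axis_hologram(phase, roi_sim)
    ref = make_reference_hologram(roi_sim, roi_sim.grid_shape)
    return {"sim": roi_sim, "truth": truth, "phase": phase, "hologram": holo, "reference": ref}


def recovery_error_pct(result_thickness, truth, mask):
    """RMS thickness error inside the mask, % of the phantom's maximum."""
    err = result_thickness.values - truth.values
    return 100.0 * np.sqrt(np.mean(err[mask] ** 2)) / truth.values.max()


@pytest.fixture
def pipeline_config(roi_sim) -> PipelineConfig:
    return PipelineConfig(simulation=roi_sim)


@pytest.fixture
def noisy_pipeline_config(roi_sim) -> PipelineConfig:
    return PipelineConfig(simulation=dataclasses.replace(roi_sim, noise_sigma=2.0))
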