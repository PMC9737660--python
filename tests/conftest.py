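import numpy as np
import pytest

from ionquench.beam_model import (
    BEAM_PRESETS,
    DepthGrid,
    DepthDoseCurve,
    SpeciesDepthProfile,
    range_energy,
    stopping_power,
)
from ionquench.workflow import ExperimentConfig, synth_experiment


@pytest.fixture(scope="session")
def proton_bundle():
    """Zero-noise single-proton-beam bundle."""
    cfg = ExperimentConfig(beams=["H160"], noise_sigma=0.0, seed=7)
    return synth_experiment(cfg)


@pytest.fixture(scope="session")
def tri_bundle():
    """Zero-noise bundle with one beam per primary species."""
    cfg = ExperimentConfig(beams=["H160", "He150", "C290"], noise_sigma=0.0, seed=7)
    return synth_experiment(cfg)


@pytest.fixture(scope="session")
def carbon_bundle():
    cfg = ExperimentConfig(beams=["C290"], noise_sigma=0.0, seed=7)
    return synth_experiment(cfg)


@pytest.fixture(scope="session")
def pure_proton_profile():
    """Single-species (H-1 only) profile with its matching reference curve."""
    beam = BEAM_PRESETS["H160"]
    remap = range_energy(beam)
    grid = DepthGrid.covering(1.15 * remap.csda_range_mm)
    depths = grid.depths
    let = stopping_power(remap.residual_energy(depths), beam.species)
    frac = np.ones((grid.n_bins, 1))
    profile = SpeciesDepthProfile(
        grid, ["H-1"], frac, let[:, None], absolute_fluence=np.ones(grid.n_bins)
    )
    inside = remap.in_range(depths)
    dose = np.where(inside, let, 0.0)
    dose[0] = let[0]
    reference = DepthDoseCurve(grid, dose, source="reference")
    return profile, reference
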