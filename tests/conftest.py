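import numpy as np
import pytest

from dsrt import screen_sim as ss


@pytest.fixture
def cell_lines():
    return [f"CL{i:02d}" for i in range(4)]


@pytest.fixture
def small_library():
    return ss.make_library(12, seed=11)


@pytest.fixture
def truth(cell_lines, small_library):
    return ss.make_truth(cell_lines, small_library, seed=11)


@pytest.fixture
def zero_noise():
    return ss.NoiseModel(cv_mult=0.0, sd_add=0.0, seed=0)


@pytest.fixture
def noisy():
    return ss.NoiseModel(cv_mult=0.05, sd_add=0.0, seed=0)


@pytest.fixture
def small_screen(cell_lines, small_library, truth, zero_noise):
    return ss.simulate_screen(cell_lines, small_library, truth, zero_noise)


def make_flat_truth(cells, library, top_viab=80.0, top_tox=60.0, slope=1.0,
                    archetype="cytotoxic"):
    """Hand-built truth with identical, fully controlled parameters."""
    truth = ss.SyntheticTruth()
    for spec in library:
        truth.compound_class[spec.compound_id] = spec.drug_class
        mid = float(np.log10(spec.concentrations).mean())
        for cell in cells:
            truth.responses[(cell, spec.compound_id)] = ss.TrueResponseModel(
                top_viab=top_viab, top_tox=top_tox,
                log_ec50_viab=mid, log_ec50_tox=mid,
                slope=slope, archetype=archetype)
    return truth
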