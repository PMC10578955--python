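import numpy as np
import pytest

from qustex.core import AcquisitionSpec
from qustex.maps import SlidingWindowConfig, average_phantom_spectrum
from qustex.synthdata import (
    CohortSpec,
    DEFAULT_CLASS_EFFECT,
    ScattererSpec,
    generate_synthetic_cohort,
    simulate_reference_phantom,
    simulate_rf_frame,
)

#: Small acquisition used by simulation-backed tests (keeps RF synthesis fast).
SMALL_ACQ = AcquisitionSpec(max_depth=2.5, num_lines=160, lateral_fov=2.4)
PHANTOM_ACQ = AcquisitionSpec(max_depth=2.5, num_lines=400, lateral_fov=6.0)


@pytest.fixture(scope="session")
def sim_frame():
    scat = ScattererSpec(effective_diameter=80.0, number_density=16.0,
                         amplitude_variance=1.0, attenuation_coefficient=0.5)
    return simulate_rf_frame(SMALL_ACQ, scat, seed=1)


@pytest.fixture(scope="session")
def phantom_bundle():
    frame, freqs, bsc = simulate_reference_phantom(PHANTOM_ACQ, seed=1001)
    return {"frame": frame, "bsc": (freqs, bsc)}


@pytest.fixture(scope="session")
def phantom_spectrum_2mm(phantom_bundle):
    return average_phantom_spectrum(phantom_bundle["frame"], SlidingWindowConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """10 patients x 2 frames with the default class effect (fast)."""
    spec = CohortSpec(n_patients=10, frames_per_patient=2,
                      class_fraction_cr=0.4, seed=5,
                      class_effect=dict(DEFAULT_CLASS_EFFECT),
                      map_shape=(24, 24), roi_axes_mm=(10.0, 16.0))
    return generate_synthetic_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
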