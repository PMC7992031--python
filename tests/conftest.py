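import numpy as np
import pytest

from ictonet.config import StudyConfig
from ictonet.synth import GroundTruthSpec


@pytest.fixture(scope="session")
def pair_spec():
    """Two-region generator spec used by connectivity-level tests."""
    return GroundTruthSpec(n_regions=2, duration=40.0, base_density=1.0,
                           base_strength=0.8, leakage_strength=0.0,
                           sensor_noise=0.2, seed=0)


@pytest.fixture(scope="session")
def small_network():
    """A fixed 16-node weighted graph for dynamics tests."""
    rng = np.random.default_rng(0)
    n = 16
    a = (rng.random((n, n)) < 0.3).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return a * 0.3


def scaled_study_config(seed: int, patient_effect: float = 1.5,
                        fast: bool = False) -> StudyConfig:
    """Desk-scale study conditions: 16 regions, 2 segments, reduced durations.

    Region count and coupling density are chosen so the thresholded
    networks keep an expected degree comparable to full-scale runs (few
    isolated nodes), which the coupling-interval calibration requires.
    """
    doc = {
        "seed": seed,
        "synth": {"n_controls": 10, "n_patients": 10, "n_regions": 16,
                  "duration": 60.0, "base_density": 0.45, "base_strength": 0.6,
                  "patient_effect": patient_effect},
        "preprocess": {"total_s": 40.0, "segment_s": 20.0},
        "network": {"n_surrogates": 19},
        "dynamics": {"t_total": 1000.0, "t_transient": 100.0},
        "bni": {"n_grid": 10, "n_realizations": 1, "n_reference": 3},
    }
    if fast:
        doc["synth"].update(n_regions=12, base_density=0.55)
        doc["dynamics"].update(t_total=400.0, t_transient=50.0)
        doc["bni"].update(n_grid=6, n_reference=2)
    return StudyConfig.from_dict(doc)
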