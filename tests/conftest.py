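import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imputesim.demography import HaplotypePanel, simulate_panel
from imputesim.runner import DESK_PROFILE, simulate_profile_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_panel() -> HaplotypePanel:
    """One shared desk-profile panel of the four-population demography."""
    return simulate_profile_panel(DESK_PROFILE, 20240101)


@pytest.fixture(scope="session")
def small_one_deme_panel() -> HaplotypePanel:
    """A single-deme panel: 60 diploids, 100 kb, N = 1000."""
    from .helpers import one_deme_model

    return simulate_panel(one_deme_model(), {"P1": 60}, 777)


@pytest.fixture()
def tiny_panel() -> HaplotypePanel:
    """Hand-built panel: 4 diploids x 6 sites with known frequencies."""
    matrix = np.array(
        [
            [1, 0, 0, 1, 0, 1],
            [0, 0, 1, 1, 0, 0],
            [0, 1, 0, 1, 0, 1],
            [0, 0, 0, 1, 0, 0],
            [1, 0, 0, 0, 1, 1],
            [0, 0, 1, 1, 0, 0],
            [0, 1, 0, 1, 0, 1],
            [1, 0, 0, 1, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel(
        matrix=matrix,
        positions=np.array([5, 10, 40, 77, 120, 199]),
        sample_populations=np.array(["P1"] * 4 + ["P2"] * 4),
        sequence_length=250.0,
    )
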