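import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnacleave as rc
from rnacleave.simulate import CleavagePropensityModel, NoiseModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Printed reference masses of the twelve fixture RNAs, Da (3 decimals).
REFERENCE_MASSES = {
    1: 5764.869,
    2: 5763.874,
    3: 5763.874,
    4: 5749.858,
    5: 5719.836,
    6: 8612.152,
    7: 8626.168,
    8: 8626.168,
    9: 8640.183,
    10: 2523.388,
    11: 2522.393,
    12: 2522.393,
}


@pytest.fixture(scope="session")
def rna1():
    return rc.reference_rna(1)


@pytest.fixture(scope="session")
def rna6():
    return rc.reference_rna(6)


@pytest.fixture(scope="session")
def rna10():
    return rc.reference_rna(10)


@pytest.fixture
def clean_model():
    """Propensity model without base-loss or a/w channels."""
    return CleavagePropensityModel(
        base_loss_fraction=0.0, ay_channel_fraction=0.0
    )


@pytest.fixture
def no_noise():
    return NoiseModel.none()


@pytest.fixture(scope="session")
def noiseless_run(rna1):
    """A noiseless c/y-only CAD simulation of the 18-mer at n = 7, with
    its matched assignments — shared by assignment and statistics tests."""
    model = CleavagePropensityModel(base_loss_fraction=0.0, ay_channel_fraction=0.0)
    peaks, truth = rc.simulate_cad_spectrum(
        rna1, 7, model, n_ions=20_000, noise=NoiseModel.none(), seed=3
    )
    candidates = rc.enumerate_fragments(rna1, "cy", max_charge=7)
    assignments = rc.match_fragments(peaks, candidates, tol_ppm=3.0)
    return peaks, truth, candidates, assignments
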