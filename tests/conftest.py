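import numpy as np
import pytest

from oligoscope import ChainGeometry, LabelingScheme, OligomerComposition


@pytest.fixture
def arc_geometry():
    return ChainGeometry(repeat_spacing_nm=9.0, turn_angle_deg=22.0)


@pytest.fixture
def straight_geometry():
    return ChainGeometry(repeat_spacing_nm=9.0, turn_angle_deg=0.0)


@pytest.fixture
def internal_scheme():
    return LabelingScheme("internal_1to1", p_label=0.2)


@pytest.fixture
def end_scheme():
    return LabelingScheme("end_2Nto2")


@pytest.fixture
def four_species():
    return OligomerComposition([0.60, 0.25, 0.10, 0.05])


def rice_sample(rng, nu, sigma, n=1):
    """Draw observed distances by construction: two 2-D Gaussian-perturbed
    points at true separation nu with combined scale sigma."""
    a = rng.normal(0.0, sigma / np.sqrt(2), (n, 2))
    b = np.column_stack([np.full(n, nu), np.zeros(n)]) + rng.normal(
        0.0, sigma / np.sqrt(2), (n, 2)
    )
    return np.hypot(*(a - b).T)
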