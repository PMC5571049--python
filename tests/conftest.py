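import numpy as np
import pytest

from spntex import ImageVolume, NoduleConfig, VOIMask, make_nodule


@pytest.fixture(scope="session")
def small_study():
    """One deterministic mid-size nodule used across tests."""
    return make_nodule(
        NoduleConfig(diameter_mm=24.0, seed=11, target_ri_percent=20.0),
        lesion_id="fixture",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def cube_volume(values, spacing=(1.0, 1.0, 1.0), modality="PET", units="SUV"):
    """Helper: wrap an array as an ImageVolume."""
    return ImageVolume(np.asarray(values, dtype=float), np.asarray(spacing), modality, "early", units)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return VOIMask(np.ones(shape, dtype=np.uint8), np.asarray(spacing))
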