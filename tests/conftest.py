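import numpy as np
import pytest

from mammodelta.data_model_io import Mammogram, Round, View


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mammogram(pixels, view=View.CC, rnd=Round.CURRENT, pid="p0", **kw):
    return Mammogram(
        pixels=np.asarray(pixels, dtype=float),
        view=view,
        round=rnd,
        patient_id=pid,
        **kw,
    )


@pytest.fixture
def textured_image(rng):
    """Smooth textured phantom in [0, 1], 128x128."""
    from scipy import ndimage

    base = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 3)
    base = (base - base.min()) / np.ptp(base)
    return make_mammogram(base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """8-patient synthetic cohort shared across tests (in memory)."""
    from mammodelta.synthetic_cohort import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_patients=8, seed=7)
    manifest, truth = generate_cohort(cfg)
    return cfg, manifest, truth
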