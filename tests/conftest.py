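import numpy as np
import pytest

from neurofuse.phantom import (
    EffectRegion,
    PhantomConfig,
    generate_cohort,
    study_config,
)

#: small but window-compatible volume geometry used across unit tests: the
#: in-plane size is reduced while the slicing axis keeps >= 69 planes so the
#: default (37, 68) window applies unchanged
SMALL_SHAPE = (16, 16, 80)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten small, low-noise subjects (5 EMCI / 5 NC) for pipeline smoke tests."""
    config = study_config(
        n_emci=5,
        n_nc=5,
        shape=SMALL_SHAPE,
        effect_scale=4.0,
        noise_sd=0.5,
        region_noise=0.0,
        anatomy_seed=11,
        subject_noise_seed=11,
    )
    subjects, manifest = generate_cohort(config)
    return subjects, manifest, config


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic zero-noise configuration: volumes equal the template."""
    return PhantomConfig(
        n_emci=2,
        n_nc=2,
        shape=SMALL_SHAPE,
        effect_regions=(EffectRegion((8, 8, 50), 4.0, {"FA": -0.1, "MD": 0.2, "sMRI": -20.0}),),
        noise_sd=0.0,
        scale_jitter=0.0,
        anatomy_seed=3,
        subject_noise_seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
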