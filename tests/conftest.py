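"""Shared fixtures: small rendered phantoms reused across test modules."""

import numpy as np
import pytest

from respcine import phantom, pipeline
from respcine.volumetry import SubjectRecord

#: One-slice miniature with the full default acquisition duration
#: (900 frames x 33 ms); volumes scaled so a single slice holds them.
MINI_KWARGS = dict(
    n_slices=1,
    frames_per_slice=900,
    edv0_rv=20.0,
    esv0_rv=8.0,
    edv0_lv=16.0,
    esv0_lv=7.0,
    preload_gain_rv=0.008,
    preload_gain_lv=-0.004,
)


@pytest.fixture(scope="session")
def mini_config():
    return phantom.PhantomConfig(seed=0, **MINI_KWARGS)


@pytest.fixture(scope="session")
def mini_subject(mini_config):
    return phantom.simulate_subject(mini_config, render=True)


@pytest.fixture(scope="session")
def mini_subject_noiseless():
    cfg = phantom.PhantomConfig(seed=0, noise_sd=0.0, **MINI_KWARGS)
    return phantom.simulate_subject(cfg, render=True)


@pytest.fixture(scope="session")
def demo_record():
    return SubjectRecord(
        id="demo", age_years=10, sex="F", weight_kg=35.0, height_cm=140.0,
        group="rv_overload",
    )


@pytest.fixture(scope="session")
def demo_result(demo_record):
    """Full image-mode run of one subject at desk scale, planted RV slope 0.75."""
    pcfg = phantom.PhantomConfig(
        n_slices=6, frames_per_slice=600, starling_slope_rv=0.75, seed=3
    )
    cfg = pipeline.RunConfig(n_slices=6, frames_per_slice=600)
    return pipeline.run_phantom_subject(pcfg, demo_record, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
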