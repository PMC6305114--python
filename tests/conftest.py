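import logging

import numpy as np
import pytest

import lesionvario as lv


@pytest.fixture(autouse=True)
def _quiet_fit_warnings(caplog):
    # descriptor extraction logs low-r2 warnings on tiny test masks; keep
    # test output readable without hiding errors
    logging.getLogger("lesionvario").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (10+5 subjects per gender, 4 timepoints)."""
    spec = lv.default_cohort_spec(master_seed=7)
    return lv.generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_descriptors(default_cohort):
    """Descriptor table for the default cohort (shared: ~2 s to build)."""
    masks, records, labels = default_cohort
    frame = lv.PatternDescriptorExtractor().fit().transform(masks)
    return frame, records, labels


@pytest.fixture
def single_ball_mask():
    # large margin pins the ball at the domain centre, away from the
    # asymmetric pair loss a pattern near a grid face would suffer
    spec = lv.PatternSpec(
        domain_shape=(64, 64, 64),
        n_blobs=1,
        radius_mean=8.0,
        radius_sd=0.0,
        anisotropy=(1.0, 1.0),
        seed=11,
        margin_mm=25.0,
    )
    return lv.generate_pattern(spec)


@pytest.fixture
def bernoulli_mask():
    rng = np.random.default_rng(5)
    grid = (rng.random((24, 24, 24)) < 0.1).astype(np.uint8)
    return lv.LesionMask(grid=grid, spacing=(1.0, 1.0, 1.0))
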