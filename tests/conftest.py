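import numpy as np
import pytest

import dermgfr as d


#: compact texture settings for unit tests: small patches, line counts
#: scaled to the smaller area, same monotone structure as the defaults.
SMALL_TEXTURE = d.TextureConfig(
    image_size=(64, 64),
    lines_per_level={1: 2, 2: 4, 3: 7, 4: 11, 5: 16},
    line_depth_per_level={1: 0.22, 2: 0.30, 3: 0.38, 4: 0.46, 5: 0.54},
)


@pytest.fixture(scope="session")
def small_texture_cfg() -> d.TextureConfig:
    return SMALL_TEXTURE


@pytest.fixture(scope="session")
def cohort() -> list[d.SubjectRecord]:
    """Default 75-subject cohort without texture features."""
    return d.generate_cohort(d.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def labelled_cohort() -> list[d.SubjectRecord]:
    """A 75-subject cohort with texture features from small patches.

    Small images keep the session fast; statistics-sensitive checks use the
    default configuration in the acceptance suite instead.
    """
    recs = d.generate_cohort(d.CohortConfig(seed=11))
    return d.attach_texture_features(recs, SMALL_TEXTURE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
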