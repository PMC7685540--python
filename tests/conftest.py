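import numpy as np
import pytest

import motionshare as ms


@pytest.fixture(scope="session")
def default_profile():
    return ms.TableProfile()


@pytest.fixture(scope="session")
def short_profile():
    # 10 deg outward-only motion: 41 frames at 15 Hz, fast enough for tracking tests
    return ms.TableProfile(max_angle=10.0, include_return=False)


@pytest.fixture(scope="session")
def short_subject(short_profile):
    sharing = ms.SharingProfile(
        base_shares=(0.4, 0.3, 0.2, 0.1), share_drift=(0.02,) * 4, noise_sd=0.0
    )
    return ms.generate_subject(short_profile, sharing, seed=2)


@pytest.fixture(scope="session")
def short_render(short_subject):
    return ms.render_frames(short_subject)


@pytest.fixture(scope="session")
def short_templates(short_render):
    fixture = ms.corner_fixture(short_render.geometry)
    return ms.register_first_image(short_render.frames[0], fixture)


@pytest.fixture(scope="session")
def short_tracked(short_render, short_templates):
    return ms.track_sequence(short_render.frames, short_templates)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
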