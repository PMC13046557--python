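import numpy as np
import pytest

from glossography import LandmarkTrack, Session

LANDMARKS = {
    "forehead": (320.0, 100.0),
    "nose": (320.0, 220.0),
    "tongue_tip": (320.0, 300.0),
    "chin": (320.0, 360.0),
}


def make_session(coords, fps=25.0, label="test", likelihood=None):
    """Build a Session from {name: (x_array, y_array)} mappings."""
    tracks = {}
    for name, (x, y) in coords.items():
        x = np.asarray(x, dtype=float)
        lk = np.ones(len(x)) if likelihood is None else np.asarray(likelihood[name])
        tracks[name] = LandmarkTrack(name=name, x=x, y=np.asarray(y, dtype=float),
                                     likelihood=lk)
    return Session(label=label, fps=fps, tracks=tracks)


@pytest.fixture
def static_session():
    """A perfectly still 100-frame face."""
    n = 100
    return make_session(
        {name: (np.full(n, rx), np.full(n, ry))
         for name, (rx, ry) in LANDMARKS.items()}
    )


@pytest.fixture
def grid_session():
    """A jittering face with coordinates on a 1/64-px grid.

    Grid coordinates stay exactly representable under integer pixel
    shifts, so translation-invariance checks can assert bit equality.
    """
    rng = np.random.default_rng(7)
    n = 200
    coords = {}
    for name, (rx, ry) in LANDMARKS.items():
        x = rx + rng.integers(-640, 640, n) / 64.0
        y = ry + rng.integers(-640, 640, n) / 64.0
        coords[name] = (x, y)
    return make_session(coords)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
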