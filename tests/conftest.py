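import numpy as np
import pytest

from fvrf.simulate import gen_dot_stimulus, gen_eye_trace, gen_motion_dot_stimulus


@pytest.fixture(scope="session")
def short_trace():
    trace, saccades = gen_eye_trace(20.0, rate=1000.0, saccade_rate=2.0, seed=7)
    return trace, saccades


@pytest.fixture(scope="session")
def small_dots():
    return gen_dot_stimulus(500, dots_per_frame=8, dot_size=0.5,
                            frame_rate=60.0, seed=3)


@pytest.fixture(scope="session")
def small_motion():
    return gen_motion_dot_stimulus(800, seed=4)


@pytest.fixture(scope="session")
def sparse_movie():
    """Sparse-dot pixel movie (T, 16, 16) resembling a reconstructed ROI."""
    rng = np.random.default_rng(11)
    T, h = 20000, 16
    movie = np.zeros((T, h, h), dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:h]
    cx = rng.uniform(0, h - 1, size=(T, 2))
    cy = rng.uniform(0, h - 1, size=(T, 2))
    pol = rng.choice([-1.0, 1.0], size=(T, 2))
    for d in range(2):
        movie += (
            pol[:, d, None, None]
            * np.exp(
                -(
                    (xx[None] - cx[:, d, None, None]) ** 2
                    + (yy[None] - cy[:, d, None, None]) ** 2
                )
                / (2 * 1.5**2)
            )
        ).astype(np.float32)
    return movie
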