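import numpy as np
import pytest

from icband import synthetic
from icband.core import MovieStack


@pytest.fixture(scope="session")
def coupled_session():
    """A 2-min fully coupled spontaneous session with default artifacts."""
    cfg = synthetic.SyntheticSpontConfig(duration=120.0, coupling=1.0, seed=11)
    movie, masks, truth = synthetic.generate_spontaneous_movie(cfg)
    return cfg, movie, masks, truth


@pytest.fixture(scope="session")
def preprocessed_session(coupled_session):
    from icband import preprocess

    cfg, movie, masks, _ = coupled_session
    dff, masks_ds, motion, fit = preprocess.preprocess_movie(movie, masks)
    return cfg, dff, masks_ds, motion


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def textured_static():
    """A static textured movie (no activity) for registration tests."""
    rng = np.random.default_rng(7)
    tex = synthetic.baseline_texture((48, 64), 0.1, rng)
    return MovieStack(np.repeat((100.0 * tex)[None], 40, axis=0))
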