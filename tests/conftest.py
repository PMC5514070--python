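import numpy as np
import pytest

from penrhythm.synthetic import SyntheticConfig, simulate_word
from penrhythm.trace_io import Trace, TraceMeta


@pytest.fixture
def meta():
    return TraceMeta(participant_id="P0", group="G1", script="cursive",
                     condition="Spontaneous", trial_id="P0-cursive-Spontaneous")


@pytest.fixture
def noisefree_config():
    """Generator config with every stochastic ingredient switched off."""
    return SyntheticConfig(sigma_T=0.0, pos_jitter=0.0, rho_jitter=0.0,
                           participant_size_sigma=0.0,
                           participant_tempo_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(t, x, y, pressure, meta=None, **meta_kw):
    if meta is None:
        kw = dict(participant_id="P0", group="G1", script="cursive",
                  condition="Spontaneous", trial_id="t0")
        kw.update(meta_kw)
        meta = TraceMeta(**kw)
    return Trace(meta=meta, t=np.asarray(t, float), x=np.asarray(x, float),
                 y=np.asarray(y, float), pressure=np.asarray(pressure, float))


@pytest.fixture
def noisefree_word(noisefree_config, rng):
    """One noise-free cursive trace plus its ground truth."""
    return simulate_word(noisefree_config, "Spontaneous", "cursive", rng)
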