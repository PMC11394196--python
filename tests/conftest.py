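import numpy as np
import pytest

from ecgpaperkit import RenderConfig, generate_signal, render_paper


@pytest.fixture(scope="session")
def short_render():
    """A clean 3-second single-strip page at 8 px/mm with its truth."""
    sig = generate_signal(3.0, 500.0, heart_rate_bpm=66, seed=5)
    page, gt = render_paper(sig, RenderConfig(px_per_mm=8), fs=500.0)
    return sig, page, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
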