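import numpy as np
import pytest

from episignal import SynthConfig, TimeSeriesPanel, generate_panel


def make_panel(years=2, P=12, n_sites=1, start_year=2000, values=None,
               site_names=None):
    """Small well-formed panel; values default to 1..n per site."""
    n = years * P
    yy = start_year + np.arange(n) // P
    ss = np.arange(n) % P + 1
    if values is None:
        values = np.tile(np.arange(1.0, n + 1)[:, None], (1, n_sites))
    names = site_names or [chr(ord("A") + i) for i in range(n_sites)]
    return TimeSeriesPanel(years=yy, subunits=ss, periodicity=P,
                           site_names=names, values=values)


@pytest.fixture
def tiny_panel():
    return make_panel()


@pytest.fixture
def noisefree_panel():
    cfg = SynthConfig(seed=11, n_sites=3, years=10, noise_sd=0.0)
    return generate_panel(cfg)


@pytest.fixture
def noisy_panel():
    cfg = SynthConfig(seed=7, n_sites=3, years=20)
    return generate_panel(cfg)
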