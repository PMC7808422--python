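import pytest
from dataclasses import replace

import pollenflow as pf


@pytest.fixture(scope="session")
def geo6():
    """6x6 grid with the 2009-1 plot dimensions, no border."""
    return pf.FieldGeometry(n_rows=6, n_cols=6, plot_depth_m=2.5, plot_width_m=0.75)


@pytest.fixture(scope="session")
def field_2009_1():
    """One binomial-noise realization of the 2009-1 preset."""
    return pf.generate_field(pf.preset("2009-1", seed=11))


@pytest.fixture(scope="session")
def noise_free_two_strip_field():
    """Noise-free field on the 2009-1 grid with 0 m and 6.75 m border strips."""
    cfg = pf.with_two_strips(pf.preset("2009-1"), 6.75)
    cfg = replace(cfg, p0=0.05, noise_model="none")
    return pf.generate_field(cfg)
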