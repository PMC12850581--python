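import numpy as np
import pytest

from cestll import signal_model as sm


@pytest.fixture
def water():
    return sm.WaterPool(r1=1.0, r2=1 / 0.110)


@pytest.fixture
def cest_pool():
    return sm.ExchangePool(fs=0.005, ks=200.0, r2s=1 / 0.110, delta_ppm=4.2,
                           r1s=1.0)


@pytest.fixture
def saturation():
    return sm.SaturationSpec(b1_ut=1.0, tprep=1.5)


@pytest.fixture
def readout():
    tg = sm.flash_time_grid(4.2e-3, 960, 20)
    return sm.ReadoutSpec(tr=4.2e-3, flip=np.deg2rad(6.0), time_grid=tg)


@pytest.fixture
def offsets():
    return np.linspace(-5.0, 6.0, 26)


@pytest.fixture
def scheme(saturation, readout, offsets):
    return sm.AcquisitionScheme(sat=saturation, readout=readout,
                                offsets_ppm=offsets)
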