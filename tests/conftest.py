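import numpy as np
import pytest

import liverdce as ld
from liverdce.series import AcquisitionParams, ConcentrationSeries, SignalSeries


@pytest.fixture(scope="session")
def registry():
    return ld.default_registry()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams(tr=0.005, flip_angle_deg=15.0, frame_interval=7.65, bolus_time=76.5, n_baseline=10)


@pytest.fixture(scope="session")
def dog_eob_study():
    """The built-in dog Gd-EOB-DTPA scenario at its default 0.5% noise."""
    return ld.make_study(ld.get_scenario("dog_eob"))


@pytest.fixture(scope="session")
def dog_eob_noiseless():
    return ld.make_study(ld.get_scenario("dog_eob", noise_sigma=0.0))


@pytest.fixture(scope="session")
def dog_eob_curves(dog_eob_study):
    return ld.convert_study(dog_eob_study.to_study_data())


def smooth_bolus(times, peak_time=120.0, tail_tau=1500.0):
    """Smooth nonnegative gamma-variate-plus-tail test curve (zero pre-bolus)."""
    t = np.clip(np.asarray(times, float), 0.0, None)
    v = (t / peak_time) ** 2 * np.exp(2 * (1 - t / peak_time))
    v = v + 0.2 * (1 - np.exp(-t / peak_time)) * np.exp(-t / tail_tau)
    v[np.asarray(times) <= 0] = 0.0
    return v


@pytest.fixture()
def smooth_ce():
    t = np.arange(0.0, 1800.0 + 2.0, 2.0)
    return ConcentrationSeries(times=t, values=smooth_bolus(t), compartment="ees")
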