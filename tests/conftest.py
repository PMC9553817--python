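import numpy as np
import pytest

from ptfmass.kinetics import FrameSchedule, InputFunctions
from ptfmass.phantom import GammaVariate, PhantomSpec, gamma_variate_input


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def input_fns(schedule) -> InputFunctions:
    """Realistic gamma-variate arterial and RV curves on a 0.5 s grid."""
    t = np.arange(0.0, schedule.total_duration + 0.25, 0.5)
    ca = gamma_variate_input(GammaVariate(), t)
    crv = gamma_variate_input(GammaVariate(t0=5.0, alpha=2.5, beta=4.0, amplitude=220.0), t)
    return InputFunctions(time=t, ca=ca, crv=crv)


@pytest.fixture()
def clean_spec() -> PhantomSpec:
    """Noise-free, unblurred default heart (for oracle-style geometry checks)."""
    return PhantomSpec(psf_fwhm=0.0, noise_scale=0.0)


def small_spec(**kw) -> PhantomSpec:
    """A reduced-grid phantom for fast unit tests."""
    base = dict(grid_shape=(48, 48, 48), voxel_size=2.5, supersample=2)
    base.update(kw)
    return PhantomSpec(**base)
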