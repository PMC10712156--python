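import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedtyper import Peak, PeakList, Spectrum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_peaklist(mzs, intensities=None, snrs=None, flatline=False, meta=None) -> PeakList:
    mzs = list(mzs)
    if intensities is None:
        intensities = [50.0] * len(mzs)
    if snrs is None:
        snrs = [None] * len(mzs)
    return PeakList(
        [Peak(float(m), float(i), s) for m, i, s in zip(mzs, intensities, snrs)],
        flatline=flatline,
        meta=meta,
    )


def impulse_spectrum(masses, heights=None, shift=0.0) -> Spectrum:
    """Sparse profile trace with an isolated maximum at each mass."""
    if heights is None:
        heights = [100.0] * len(masses)
    mz, inten = [], []
    for m, h in zip(masses, heights):
        ms = m * (1.0 + shift)
        mz += [ms - 1.0, ms, ms + 1.0]
        inten += [0.0, h, 0.0]
    order = np.argsort(mz)
    return Spectrum(np.asarray(mz)[order], np.asarray(inten)[order])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
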