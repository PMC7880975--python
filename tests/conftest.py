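import numpy as np
import pytest

import perfstrat as ps
from perfstrat.dsc import DscStudy, compute_maps, detect_aif


@pytest.fixture(scope="session")
def timing():
    return ps.default_timing()


@pytest.fixture(scope="session")
def aif_params():
    return {"peak": 40.0, "t0": 12.0, "alpha": 2.0, "beta": 1.0}


@pytest.fixture(scope="session")
def noiseless_phantom(timing):
    return ps.generate_phantom(ps.default_layout(baseline_snr=None), timing, seed=11)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_phantom):
    ph = noiseless_phantom
    return DscStudy(signal=ph.signal, timing=ph.timing, masks=ph.masks)


@pytest.fixture(scope="session")
def detected_aif(noiseless_study, noiseless_phantom):
    return detect_aif(noiseless_study, noiseless_phantom.brain_mask())


@pytest.fixture(scope="session")
def tumor_mask(noiseless_phantom):
    m = noiseless_phantom.masks
    return m["tumor_HAT"] | m["tumor_LAT"]


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_study, noiseless_phantom, detected_aif, tumor_mask):
    return compute_maps(
        noiseless_study,
        detected_aif,
        reference_mask=noiseless_phantom.masks["white_matter"],
        tumor_mask=tumor_mask,
    )


@pytest.fixture(scope="session")
def relative_truth(noiseless_phantom):
    """Ground-truth rCBV/rCBF ratios relative to white matter, per class."""
    wm = noiseless_phantom.truth["white_matter"]

    def rel(cls):
        gt = noiseless_phantom.truth[cls]
        return gt.cbv / wm.cbv, gt.cbf / wm.cbf

    return rel
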