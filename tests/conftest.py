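import warnings

import numpy as np
import pytest

import silkgel as sg
from silkgel import synthetic as syn

#: the packaged synthetic reference is a fixed-seed object
REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def reference_data():
    """The packaged synthetic reference sample (fixed seed)."""
    return syn.reference_dataset(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def reference_trajectory(reference_data):
    """Two-stage fits of the full reference series (computed once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sg.fit_series(reference_data["sans"])


@pytest.fixture()
def peak_params():
    """A representative peak-stage parameter set."""
    return sg.HierParams(
        a=3e-7, n=3.0, c=0.8, eta=50.0, m=2.7, b=0.03,
        d=0.35, q0=0.015, sigma=0.003, stage="peak",
    )


@pytest.fixture()
def simple_curve():
    q = np.geomspace(0.002, 0.5, 120)
    return sg.ScatteringCurve(q=q, intensity=np.full(q.size, 7.0), time_min=5.0)
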