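import numpy as np
import pandas as pd
import pytest

from fixtrack.calibration import make_ruler
from fixtrack.io_formats import FixationSampleTable


def make_fixation_table(
    xy,
    rate: float = 25.0,
    eye: str = "OD",
    fixation_loss_pct: float = 5.0,
    t=None,
) -> FixationSampleTable:
    """Wrap raw (n, 2) degree coordinates into a validated fixation table."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if t is None:
        t = np.arange(n) / rate
    return FixationSampleTable(
        samples=pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]}),
        eye=eye,
        subject_id="T01",
        visit="baseline",
        fixation_loss_pct=fixation_loss_pct,
        test_duration=max(float(np.max(t)), n / rate),
    )


@pytest.fixture
def ruler_23px():
    """The published per-eye ruler: a 200 µm scale bar spanning 23 px."""
    return make_ruler(23.0, 200.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
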