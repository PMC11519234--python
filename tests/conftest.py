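import numpy as np
import pytest

from frthresh.data import StageProtocol, StageRecord, StageSeries
from frthresh.datasets import example_participant


@pytest.fixture
def example_series() -> StageSeries:
    """The bundled 14-stage worked example (PO/HR/f_R only)."""
    return example_participant()


def make_series(po, hr, fr, vo2=None, vco2=None, ve=None, subject_id="test"):
    """Build a StageSeries from parallel arrays (helper for constructed cases)."""
    n = len(po)

    def get(arr, i):
        return None if arr is None else float(arr[i])

    stages = tuple(
        StageRecord(stage_index=i, po=float(po[i]), hr=float(hr[i]),
                    fr=float(fr[i]), vo2=get(vo2, i), vco2=get(vco2, i),
                    ve=get(ve, i))
        for i in range(n)
    )
    return StageSeries(stages=stages, protocol=StageProtocol(),
                       subject_id=subject_id)


@pytest.fixture
def linear_gas_series():
    """Noise-free series with vo2 = 0.5 + 0.01*po and hr = 60 + 0.5*po."""
    po = np.arange(0, 261, 20.0)
    hr = 60 + 0.5 * po
    fr = 12 + 0.05 * po
    vo2 = 0.5 + 0.01 * po
    return make_series(po, hr, fr, vo2=vo2)
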