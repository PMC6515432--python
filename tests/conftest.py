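import numpy as np
import pytest

from caflux.preprocess import DetrendedTrace


def as_detrended(values, cell_id="cell", frame_interval=8.0):
    """Wrap a plain array as a DetrendedTrace (identity baseline)."""
    v = np.asarray(values, dtype=float)
    return DetrendedTrace(
        cell_id=cell_id,
        values=v,
        baseline_estimate=np.full(v.size, v.mean()),
        source_mean=float(v.mean()),
        frame_interval=frame_interval,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def spiky_trace(rng):
    """900-frame baseline-100 trace with noise and a handful of 2.5x plateaus."""
    v = 100.0 * (1.0 + 0.02 * rng.standard_normal(900))
    for onset in (100, 300, 500, 700, 850):
        v[onset : onset + 3] = 250.0
    return as_detrended(v)
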