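import numpy as np
import pytest

from tensionlab.timebase import OnsetTable, SampledSeries


@pytest.fixture
def simple_onsets() -> OnsetTable:
    """Two measures of 3/4 at 60 BPM with melody beats and a bass downbeat."""
    rows = []
    for b in range(7):
        measure, bim = divmod(b, 3)
        t = float(b)
        rows.append((t, measure, bim / 3, "melody", 60 + b, True))
        if bim == 0:
            rows.append((t, measure, bim / 3, "bass", 40, False))
    return OnsetTable.from_rows(rows)


@pytest.fixture
def ramp_series() -> SampledSeries:
    return SampledSeries(0.0, 0.1, np.arange(0, 100) * 0.1)


def make_series(values, start=0.0, period=0.1, domain="clock") -> SampledSeries:
    return SampledSeries(start, period, np.asarray(values, dtype=float), domain=domain)
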