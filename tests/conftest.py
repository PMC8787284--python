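import numpy as np
import pytest

from volecall.consolidation import Vocalization
from volecall.segmentation import FrequencyContour, VocalSegment

STEP_MS = 0.5


def build_contour(fund, start_s=0.0, traces=None, amps=None, times=None):
    """Hand-built contour: ``fund`` per frame, optional higher traces.

    ``traces`` is a list of per-frame arrays (NaN for absent); ``times``
    overrides the contiguous 0.5-ms grid to create internal gaps.
    """
    fund = np.asarray(fund, dtype=float)
    n = fund.size
    if times is None:
        # frame-center times: a segment starting at start_s with n frames
        # spans exactly [start_s, start_s + n * STEP_MS)
        times = start_s + (np.arange(n) + 0.5) * STEP_MS / 1e3
    cols = [fund] + [np.asarray(t, dtype=float) for t in (traces or [])]
    freqs = np.column_stack(cols)
    if amps is None:
        amps = np.where(np.isnan(freqs), np.nan, 1.0)
    return FrequencyContour(times=np.asarray(times, float), freqs=freqs,
                            amps=np.asarray(amps, float))


def build_segment(fund, start_s=0.0, channel="ch0", **kw):
    return VocalSegment(contour=build_contour(fund, start_s=start_s, **kw),
                        source_channel=channel)


def build_voc(*segments):
    return Vocalization(segments=list(segments))


@pytest.fixture
def make_segment():
    return build_segment


@pytest.fixture
def make_contour():
    return build_contour


@pytest.fixture
def make_voc():
    return build_voc
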