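"""Shared fixtures: small synthetic recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from slowosc import synth
from slowosc.detection import StateSegmentation


def label_agreement(seg, truth, rate: float, bin_s: float = 0.005) -> float:
    """Sample-wise Up/Down agreement between a segmentation and ground truth."""
    b = seg.bin_labels
    w = int(round(bin_s * rate))
    tl = truth.state_labels[: b.size * w].reshape(-1, w).mean(axis=1) > 0.5
    return float((b == tl).mean())


def make_segmentation(cycles, bin_s: float = 0.005) -> StateSegmentation:
    """Build a StateSegmentation directly from ((d0,d1),(u0,u1)) tuples."""
    return StateSegmentation(cycles=[tuple(map(tuple, c)) for c in cycles], bin_s=bin_s)


@pytest.fixture(scope="session")
def small_recording():
    """60 s single-channel control-strain recording at 5 kHz, with truth."""
    params = synth.preset("SAMR1_5M", "duration_matched", rate=5000.0, seed=1)
    return synth.synthesize_channel(params, 60.0), params


@pytest.fixture(scope="session")
def small_fit(small_recording):
    """Fitted slow-oscillation results for the small recording."""
    from slowosc.model import SlowOscillationModel

    (rec, truth), params = small_recording
    res = SlowOscillationModel(rec, compute_spectra=False).fit()
    return res, truth, params
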