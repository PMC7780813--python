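"""Shared fixtures: synthetic recordings with ground-truth manifests.

Session-scoped because trace generation with the dense-grid oracle is the
slow part; every test treats the fixtures as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomap.beats import detect_beats, measure_beats
from cardiomap.protocols import PacingProtocol
from cardiomap.synth import (
    ATRIAL,
    VENTRICULAR,
    generate_ap_trace,
    generate_cat_trace,
)
from cardiomap.trace import Trace


@pytest.fixture(scope="session")
def protocol_1hz():
    return PacingProtocol.fixed(1.0, 9, start_ms=100.0)


@pytest.fixture(scope="session")
def ap_recordings(protocol_1hz):
    """Noiseless atrial and ventricular AP recordings at 1 Hz, 100 fps."""
    return {
        "atrial": generate_ap_trace(ATRIAL, protocol_1hz, 100.0, 10_000.0),
        "ventricular": generate_ap_trace(VENTRICULAR, protocol_1hz, 100.0, 10_000.0),
    }


@pytest.fixture(scope="session")
def cat_recordings():
    """Noiseless CaT recordings paced slowly enough for full recovery."""
    return {
        "atrial": generate_cat_trace(
            ATRIAL, PacingProtocol.fixed(0.4, 4, start_ms=100.0), 100.0, 10_000.0
        ),
        "ventricular": generate_cat_trace(
            VENTRICULAR, PacingProtocol.fixed(0.25, 4, start_ms=100.0), 100.0, 16_000.0
        ),
    }


@pytest.fixture(scope="session")
def measured_ap(ap_recordings, protocol_1hz):
    out = {}
    for label, rec in ap_recordings.items():
        beats = detect_beats(rec.trace, protocol_1hz)
        out[label] = measure_beats(rec.trace, beats)
    return out


@pytest.fixture(scope="session")
def measured_cat(cat_recordings):
    protos = {
        "atrial": PacingProtocol.fixed(0.4, 4, start_ms=100.0),
        "ventricular": PacingProtocol.fixed(0.25, 4, start_ms=100.0),
    }
    out = {}
    for label, rec in cat_recordings.items():
        beats = detect_beats(rec.trace, protos[label])
        out[label] = measure_beats(rec.trace, beats)
    return out


def aligned_errors(measured, manifest, metrics):
    """Max |measured − manifest| per metric over non-truncated beats."""
    ok = (~measured["truncated"]).to_numpy()
    man = manifest[~manifest["truncated"].to_numpy()]
    n = min(int(ok.sum()), len(man))
    return {
        m: float(
            np.nanmax(
                np.abs(measured.loc[ok, m].to_numpy()[:n] - man[m].to_numpy()[:n])
            )
        )
        for m in metrics
    }


def make_trace(values, dt=10.0, channel="voltage"):
    values = np.asarray(values, dtype=float)
    return Trace(np.arange(values.size) * dt, values, channel=channel)
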