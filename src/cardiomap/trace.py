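"""Uniformly sampled fluorescence/voltage traces and their delimited-text I/O.

A :class:`Trace` is the common currency of the pipeline: one channel of an
optical-mapping recording (voltage-sensitive or Ca²⁺-sensitive dye) sampled on
a strictly increasing, uniform time base in milliseconds.  Raw movies are
reduced to traces by ROI averaging (:mod:`cardiomap.io_signal`); every
downstream metric operates on traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Trace", "read_trace", "write_trace"]

#: Relative tolerance on time-base uniformity.
_UNIFORM_RTOL = 1e-6


@dataclass
class Trace:
    """One channel of an optical recording on a uniform time base.

    Parameters
    ----------
    time
        Sample timestamps in milliseconds, strictly increasing and uniformly
        spaced, timestamped at frame start (frame index 0 at t=0 by
        convention, though any offset is legal).
    values
        Fluorescence (arbitrary counts) or conditioned/normalized units.
    channel
        ``"voltage"`` or ``"calcium"``.
    meta
        Free-form metadata (``frame_rate``, ``well``, ``dose`` ...).
    """

    time: np.ndarray
    values: np.ndarray
    channel: str = "voltage"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.values.ndim != 1:
            raise ValueError("time and values must be 1-D arrays")
        if self.time.size != self.values.size:
            raise ValueError(
                f"time ({self.time.size}) and values ({self.values.size}) "
                "differ in length"
            )
        if self.time.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time base must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_UNIFORM_RTOL, atol=1e-9):
            raise ValueError("time base must be uniformly spaced")
        if self.channel not in ("voltage", "calcium"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(self.time[1] - self.time[0])

    @property
    def frame_rate(self) -> float:
        """Sampling rate in frames/s."""
        return 1000.0 / self.dt

    @property
    def duration(self) -> float:
        """Recording span in ms (last minus first timestamp)."""
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size

    def with_values(self, values: np.ndarray) -> "Trace":
        """Copy of this trace with ``values`` replaced, time base kept."""
        return replace(self, values=np.asarray(values, dtype=float))

    def slice_time(self, t0: float, t1: float) -> "Trace":
        """Sub-trace covering ``[t0, t1]`` (inclusive of samples inside)."""
        mask = (self.time >= t0) & (self.time <= t1)
        if mask.sum() < 2:
            raise ValueError(f"slice [{t0}, {t1}] ms holds <2 samples")
        return Trace(self.time[mask], self.values[mask], self.channel, dict(self.meta))


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as delimited text: ``time_ms,value`` with ``#`` meta lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# channel: {trace.channel}\n")
        for key, val in sorted(trace.meta.items()):
            fh.write(f"# {key}: {val}\n")
        fh.write("time_ms,value\n")
        for t, v in zip(trace.time, trace.values):
            fh.write(f"{t:.6g},{v:.10g}\n")
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a ``time_ms,value`` delimited-text trace written by :func:`write_trace`."""
    path = Path(path)
    meta: dict[str, Any] = {}
    channel = "voltage"
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key == "channel":
                        channel = val
                    else:
                        try:
                            meta[key] = float(val) if "." in val or val.isdigit() else val
                        except ValueError:
                            meta[key] = val
                continue
            if line.lower().startswith("time"):
                continue
            t_str, _, v_str = line.partition(",")
            rows.append((float(t_str), float(v_str)))
    arr = np.asarray(rows, dtype=float)
    return Trace(arr[:, 0], arr[:, 1], channel=channel, meta=meta)
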