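"""Movie loading, ROI trace extraction, and signal conditioning.

Turns raw dual-channel image stacks (or pre-extracted trace tables) into
analysis-ready traces: ROI-averaged, detrended (photobleaching removal),
polarity-corrected and normalized to [0, 1], optionally smoothed.
Downstream beat metrics are invariant to positive affine transforms of the
raw counts because conditioning removes offset, drift and scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import percentile_filter
from scipy.signal import savgol_filter
from scipy.stats import skew

from .trace import Trace

__all__ = [
    "RoiSpec",
    "load_movie",
    "extract_roi_trace",
    "detrend",
    "normalize_and_orient",
    "smooth",
    "condition",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest in pixel coordinates (half-open rows/cols),
    or an explicit boolean mask."""

    row0: int = 0
    row1: int | None = None
    col0: int = 0
    col1: int | None = None
    mask: np.ndarray | None = None

    def resolve_mask(self, height: int, width: int) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (height, width):
                raise ValueError(
                    f"mask shape {mask.shape} does not match frames ({height}, {width})"
                )
        else:
            r1 = height if self.row1 is None else self.row1
            c1 = width if self.col1 is None else self.col1
            if not (0 <= self.row0 < r1 <= height and 0 <= self.col0 < c1 <= width):
                raise ValueError("ROI rectangle out of frame bounds")
            mask = np.zeros((height, width), dtype=bool)
            mask[self.row0 : r1, self.col0 : c1] = True
        if not mask.any():
            raise ValueError("ROI is empty")
        return mask


def load_movie(
    path: str | Path, layout: dict | str | Path
) -> tuple[np.ndarray, np.ndarray, float]:
    """Load a multi-page dual-channel stack and split it into channels.

    ``layout`` is a mapping (or path to a YAML file) declaring at least
    ``channel_layout`` ("interleaved" or "stacked") and ``frame_rate``;
    stacked layouts give ``split_index`` (frames in the first channel).
    Returns ``(voltage_frames, calcium_frames, frame_rate)`` following the
    declared ``channel_order`` (default voltage first).
    """
    import tifffile

    if isinstance(layout, (str, Path)):
        with open(layout) as fh:
            layout = yaml.safe_load(fh)
    if not isinstance(layout, dict) or "channel_layout" not in layout:
        raise ValueError("layout must declare 'channel_layout'")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    kind = layout["channel_layout"]
    frame_rate = float(layout.get("frame_rate", 100.0))
    if kind == "interleaved":
        if frames.shape[0] % 2:
            raise ValueError(
                f"interleaved stack has odd frame count {frames.shape[0]}"
            )
        ch_a, ch_b = frames[0::2], frames[1::2]
    elif kind == "stacked":
        split = layout.get("split_index")
        if split is None:
            if frames.shape[0] % 2:
                raise ValueError("stacked layout without split_index needs an even count")
            split = frames.shape[0] // 2
        split = int(split)
        if not 0 < split < frames.shape[0]:
            raise ValueError(f"split_index {split} outside stack of {frames.shape[0]}")
        ch_a, ch_b = frames[:split], frames[split:]
    else:
        raise ValueError(f"unknown channel layout {kind!r}")
    order = layout.get("channel_order", ["voltage", "calcium"])
    channels = dict(zip(order, (ch_a, ch_b)))
    return channels["voltage"], channels["calcium"], frame_rate


def extract_roi_trace(
    frames: np.ndarray,
    roi: RoiSpec,
    frame_rate: float,
    channel: str = "voltage",
    meta: dict | None = None,
) -> Trace:
    """Per-frame mean over the ROI; time base from the frame rate.

    At 100 frames/s consecutive timestamps differ by 10 ms, with frame 0 at
    t = 0 (timestamps at frame start).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, height, width) stack")
    mask = roi.resolve_mask(frames.shape[1], frames.shape[2])
    values = frames[:, mask].mean(axis=1)
    time = np.arange(frames.shape[0]) * (1000.0 / frame_rate)
    m = {"frame_rate": frame_rate}
    if meta:
        m.update(meta)
    return Trace(time, values.astype(float), channel=channel, meta=m)


def detrend(
    trace: Trace,
    method: str = "percentile",
    window_ms: float = 2000.0,
    order: int = 2,
    percentile: float = 20.0,
    cycle_length_ms: float | None = None,
) -> Trace:
    """Remove slow baseline (photobleaching drift) so diastole sits near 0.

    ``percentile`` method: subtract a rolling low-percentile baseline over a
    window that should span about two beats, which tracks drift but ignores
    the transients riding on it.  ``polynomial`` method: subtract a global
    least-squares polynomial of the given order.  If the expected cycle
    length is supplied, a window shorter than one beat is rejected.
    """
    if cycle_length_ms is not None and window_ms < cycle_length_ms:
        raise ValueError(
            f"detrend window ({window_ms} ms) is shorter than one beat "
            f"({cycle_length_ms} ms)"
        )
    n_win = int(round(window_ms / trace.dt))
    if n_win < 3:
        raise ValueError(f"detrend window ({window_ms} ms) spans fewer than 3 samples")
    y = trace.values
    if method == "percentile":
        baseline = percentile_filter(y, percentile, size=n_win, mode="reflect")
    elif method == "polynomial":
        coeffs = np.polynomial.polynomial.polyfit(trace.time, y, order)
        baseline = np.polynomial.polynomial.polyval(trace.time, coeffs)
    else:
        raise ValueError(f"unknown detrend method {method!r}")
    return trace.with_values(y - baseline)


def normalize_and_orient(trace: Trace, polarity: str = "auto") -> Trace:
    """Make depolarization/Ca-release positive-going and rescale to [0, 1].

    Rescaling uses robust extremes (1st/99th percentiles), so the output is
    invariant to positive affine transforms of the input.  ``auto`` polarity
    flips the trace when the skewness of its first difference is negative:
    the fast upstroke puts the extreme derivative outliers on the
    depolarizing side, so an inverted voltage-dye signal has strongly
    negative derivative skewness.
    """
    y = trace.values.astype(float)
    if polarity not in ("auto", "positive", "inverted"):
        raise ValueError(f"unknown polarity {polarity!r}")
    flip = polarity == "inverted"
    if polarity == "auto":
        flip = skew(np.diff(y)) < 0
    if flip:
        y = -y
    lo, hi = np.percentile(y, [1.0, 99.0])
    if hi - lo <= 1e-12 * max(abs(hi), abs(lo), 1.0):
        raise ValueError("cannot normalize a constant trace")
    return trace.with_values((y - lo) / (hi - lo))


def smooth(trace: Trace, window_ms: float = 30.0, polyorder: int = 2) -> Trace:
    """Savitzky–Golay (least-squares polynomial) smoothing.

    The default 30 ms quadratic window is deliberately conservative: at
    100 frames/s it spans 3 samples (an exact pass-through), so upstroke
    amplitude and APD levels are untouched, while at higher frame rates it
    averages enough samples to suppress shot noise.  Widen the window
    explicitly for heavily noisy recordings, at the cost of a few ms of
    upstroke distortion.
    """
    n_win = int(round(window_ms / trace.dt))
    if n_win % 2 == 0:
        n_win += 1
    if n_win < 3:
        raise ValueError(f"smoothing window ({window_ms} ms) spans fewer than 3 samples")
    if polyorder >= n_win:
        raise ValueError(f"polyorder {polyorder} must be < window of {n_win} samples")
    return trace.with_values(savgol_filter(trace.values, n_win, polyorder))


def condition(
    trace: Trace,
    polarity: str = "auto",
    detrend_method: str = "percentile",
    detrend_window_ms: float = 2000.0,
    smooth_window_ms: float | None = None,
    smooth_polyorder: int = 3,
) -> Trace:
    """Full conditioning pipeline: orient → detrend → normalize → optional smooth.

    Orientation comes first because the rolling-percentile baseline tracks
    the *diastolic* side of the signal — on an inverted voltage-dye trace it
    would otherwise ride the action potentials themselves.
    """
    y = trace.values
    flip = polarity == "inverted"
    if polarity == "auto":
        flip = bool(skew(np.diff(y)) < 0)
    out = trace.with_values(-y if flip else y)
    out = detrend(out, method=detrend_method, window_ms=detrend_window_ms)
    out = normalize_and_orient(out, polarity="positive")
    if smooth_window_ms is not None:
        out = smooth(out, window_ms=smooth_window_ms, polyorder=smooth_polyorder)
    return out
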