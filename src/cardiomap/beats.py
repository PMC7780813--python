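"""Beat segmentation and per-beat action-potential / Ca²⁺-transient metrics.

Segments a conditioned trace into beats (stimulus-aligned under fixed or ramp
pacing, derivative-threshold detection for spontaneous activity) and computes
the per-beat metrics: APD at 20/50/80/90% repolarization, CaTD at 20/50/80%
recovery, Ca²⁺ time-to-peak, mono-exponential decay τ, maximal upstroke
derivative, resting level, and beating rate.

Conventions (configurable where noted):

* APD is measured from the activation time — the upstroke midpoint, a
  sub-sample refinement of the maximum-derivative location (they coincide for
  a symmetric upstroke) — to the first subsequent downward crossing of
  ``baseline + (1 − level/100)·amplitude``, with linear interpolation
  between samples.
* CaTD and time-to-peak are referenced to the transient onset, the 10%
  upstroke crossing.
* Amplitude is per beat: baseline = median of the pre-upstroke diastolic
  window, peak = maximum inside the beat window.
* Undefined metrics (repolarization never reaches the level before the next
  beat, non-convergent τ fit) propagate as flagged NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import argrelmax

from .protocols import PacingProtocol
from .trace import Trace

__all__ = [
    "Beat",
    "detect_beats",
    "apd",
    "catd",
    "time_to_peak",
    "decay_tau",
    "upstroke_and_rest",
    "beating_rate",
    "measure_beats",
]


@dataclass
class Beat:
    """One detected beat: window, activation, peak, per-beat amplitude."""

    index: int
    t_start: float
    t_end: float
    activation_time: float
    peak_time: float
    amplitude: float
    baseline: float
    stim_time: float = np.nan
    truncated: bool = False
    flags: set[str] = field(default_factory=set)


def _interp_cross_down(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First downward crossing of ``level``; NaN if none."""
    hits = np.nonzero((y[:-1] >= level) & (y[1:] < level))[0]
    if hits.size == 0:
        return np.nan
    i = hits[0]
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def _interp_cross_up_last(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Last upward crossing of ``level``; NaN if none."""
    hits = np.nonzero((y[:-1] < level) & (y[1:] >= level))[0]
    if hits.size == 0:
        return np.nan
    i = hits[-1]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return t[i] + frac * (t[i + 1] - t[i])


def _refine_max_derivative(
    t: np.ndarray, y: np.ndarray, i_dv: int, baseline: float, amplitude: float
) -> float:
    """Sub-sample max-derivative time of the upstroke.

    The upstroke foot is well described by a logistic ramp, whose inflection
    is the maximum-derivative point; fitting ``A·logistic((t−t0)/τ)`` to the
    samples below ~70% of the beat amplitude therefore recovers the
    maximum-derivative time at sub-sample precision even when the waveform
    peaks well after (and below) the upstroke asymptote.  Falls back to a
    cubic-spline derivative maximum, then to the steepest-interval midpoint.
    """
    from scipy.interpolate import CubicSpline
    from scipy.special import expit

    import warnings

    dt = t[1] - t[0] if t.size > 1 else 1.0
    frac = (y - baseline) / amplitude
    # Prefer samples on the pure foot (below ~45% amplitude, ahead of any
    # repolarization droop); widen only while the foot holds fewer than two
    # informative (risen) samples, as with coarse sampling or smoothing.
    ts = ys = None
    for cutoff in (0.45, 0.7, 0.9):
        below = np.nonzero(frac <= cutoff)[0]
        below = below[below <= i_dv + 3]
        if below.size < 3:
            continue
        sel = below[-10:]
        cand_t, cand_y = t[sel], y[sel] - baseline
        if np.sum(cand_y > 0.02 * amplitude) >= 2:
            ts, ys = cand_t, cand_y
            break
    if ts is not None:
        t0_guess = 0.5 * (t[i_dv] + t[min(i_dv + 1, t.size - 1)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda tt, a, t0, tau: a * expit((tt - t0) / tau),
                    ts,
                    ys,
                    p0=(amplitude, t0_guess, max(dt / 2.0, 1.0)),
                    bounds=(
                        # tau floor: a quarter sample, below which the fit
                        # degenerates into an uninformative step
                        (0.1 * amplitude, ts[0] - 2 * dt, 0.25 * dt),
                        (5.0 * amplitude, t[min(i_dv + 3, t.size - 1)] + 2 * dt, 50.0 * dt),
                    ),
                    maxfev=5_000,
                )
            t0 = float(popt[1])
            if t[i_dv] - 3 * dt <= t0 <= t[min(i_dv + 1, t.size - 1)] + 3 * dt:
                return t0
        except (RuntimeError, ValueError):
            pass
    lo = max(i_dv - 3, 0)
    hi = min(i_dv + 5, y.size)
    if hi - lo >= 4:
        spl = CubicSpline(t[lo:hi], y[lo:hi])
        tt = np.arange(t[i_dv], t[min(i_dv + 1, t.size - 1)] + 1e-9, 0.05)
        if tt.size:
            return float(tt[np.argmax(spl(tt, 1))])
    return 0.5 * (t[i_dv] + t[min(i_dv + 1, t.size - 1)])


def _refine_peak(t: np.ndarray, y: np.ndarray, i_peak: int) -> tuple[float, float]:
    """Sub-sample peak (time, value) around the maximum sample.

    A transient peak is typically a corner between a rising and a falling
    limb, so the peak is located as the intersection of straight lines fit
    to the samples flanking the maximum; a cubic-spline maximum serves as
    fallback when the flanks are too short or not opposed in slope.
    """
    from scipy.interpolate import CubicSpline

    dt = t[1] - t[0] if t.size > 1 else 1.0
    # plateau tops (square-pulse-like beats) take the first maximal sample
    if i_peak + 1 < y.size and y[i_peak + 1] >= y[i_peak] - 1e-12 * abs(y[i_peak]):
        return float(t[i_peak]), float(y[i_peak])
    left = slice(max(i_peak - 4, 0), i_peak)
    right = slice(i_peak + 1, min(i_peak + 5, y.size))
    if i_peak - left.start >= 2 and right.stop - right.start >= 2:
        b_up, a_up = np.polyfit(t[left], y[left], 1)
        b_dn, a_dn = np.polyfit(t[right], y[right], 1)
        if b_up > 0 > b_dn:
            tx = (a_dn - a_up) / (b_up - b_dn)
            if t[i_peak] - dt <= tx <= t[i_peak] + dt:
                return float(tx), float(a_up + b_up * tx)
    lo = max(i_peak - 4, 0)
    hi = min(i_peak + 5, y.size)
    if hi - lo < 4:
        return float(t[i_peak]), float(y[i_peak])
    # spline refines the time only; its extremum value can overshoot on
    # step-like rises, so the amplitude keeps the sampled maximum
    spl = CubicSpline(t[lo:hi], y[lo:hi])
    tt = np.arange(t[i_peak] - dt, t[i_peak] + dt + 1e-9, 0.05)
    tt = tt[(tt >= t[lo]) & (tt <= t[hi - 1])]
    k = int(np.argmax(spl(tt)))
    return float(tt[k]), float(y[i_peak])


def _beat_from_window(
    trace: Trace,
    index: int,
    t_start: float,
    t_stim: float,
    t_end: float,
    min_amplitude: float,
    activation_convention: str,
) -> Beat | None:
    """Build a Beat from a candidate window; None if no usable deflection."""
    t, y = trace.time, trace.values
    i0 = int(np.searchsorted(t, t_start))
    i_stim = int(np.searchsorted(t, t_stim))
    i1 = int(np.searchsorted(t, t_end))
    if i1 - i_stim < 4:
        return None
    base_seg = y[i0 : max(i_stim, i0 + 1) + 1]
    baseline = float(np.median(base_seg))
    seg_t, seg_y = t[i_stim:i1], y[i_stim:i1]
    i_peak_rel = int(np.argmax(seg_y))
    peak_time = float(seg_t[i_peak_rel])
    peak_val = float(seg_y[i_peak_rel])
    if trace.channel == "calcium":
        # corner peaks under-sample the true maximum; τ then amplifies the
        # amplitude error into the recovery crossings, so refine both
        peak_time, refined_val = _refine_peak(seg_t, seg_y, i_peak_rel)
        peak_val = max(peak_val, refined_val)
    amplitude = peak_val - baseline
    if amplitude < min_amplitude:
        return None
    # Maximum-derivative location on the upstroke (ties: earliest), refined
    # to sub-sample precision with a cubic-spline derivative.
    up_y = seg_y[: i_peak_rel + 1]
    if up_y.size < 2:
        return None
    dv = np.diff(up_y)
    i_dv = int(np.argmax(dv))
    act = _refine_max_derivative(seg_t[: i_peak_rel + 1], up_y, i_dv, baseline, amplitude)
    if activation_convention == "upstroke_mid":
        mid = _interp_cross_up_last(
            seg_t[: i_peak_rel + 1], up_y, baseline + 0.5 * amplitude
        )
        if np.isfinite(mid):
            act = mid
    elif activation_convention != "max_derivative":
        raise ValueError(f"unknown activation convention {activation_convention!r}")
    return Beat(
        index=index,
        t_start=float(t[i0]),
        t_end=float(seg_t[-1]),
        activation_time=float(act),
        peak_time=peak_time,
        amplitude=float(amplitude),
        baseline=baseline,
        stim_time=t_stim,
    )


def detect_beats(
    trace: Trace,
    protocol: PacingProtocol,
    pre_window_ms: float = 60.0,
    min_amplitude_fraction: float = 0.25,
    refractory_ms: float = 250.0,
    activation_convention: str = "max_derivative",
) -> list[Beat]:
    """Segment a conditioned trace into beats.

    Under ``fixed``/``ramp`` pacing each stimulus opens one window reaching
    to the next stimulus (stimulus-aligned); under ``spontaneous`` mode
    activations are found from derivative-threshold crossings with a
    refractory lockout.  Beats whose window is cut by the end of the trace
    are flagged ``truncated`` (and excluded from metric tables); a trace
    with no detectable deflections yields an empty list, not an exception.
    """
    t, y = trace.time, trace.values
    robust_amp = float(np.percentile(y, 99) - np.percentile(y, 1))
    min_amp = min_amplitude_fraction * robust_amp
    if robust_amp <= 0:
        return []

    if protocol.mode in ("fixed", "ramp"):
        stims = protocol.stimulus_times
        edges = list(stims) + [stims[-1] + float(np.median(np.diff(stims)))
                               if stims.size > 1 else trace.time[-1] + trace.dt]
        windows = [
            (max(stims[k] - pre_window_ms, t[0]), stims[k], edges[k + 1])
            for k in range(len(stims))
        ]
    elif protocol.mode == "spontaneous":
        dv = np.diff(y)
        thr = 0.5 * dv.max()
        if thr <= 0:
            return []
        cand = np.nonzero(dv >= thr)[0]
        acts: list[int] = []
        for i in cand:
            if not acts or (t[i] - t[acts[-1]]) >= refractory_ms:
                acts.append(int(i))
        if not acts:
            return []
        onsets = [max(t[i] - 10.0, t[0]) for i in acts]
        edges = onsets[1:] + [min(t[-1] + trace.dt,
                                  onsets[-1] + (np.median(np.diff(onsets))
                                                if len(onsets) > 1 else t[-1] - onsets[-1]))]
        windows = [
            (max(onsets[k] - pre_window_ms, t[0]), onsets[k], edges[k])
            for k in range(len(onsets))
        ]
    else:
        raise ValueError(f"unknown pacing mode {protocol.mode!r}")

    beats: list[Beat] = []
    for k, (t_start, t_stim, t_end) in enumerate(windows):
        beat = _beat_from_window(
            trace, len(beats), t_start, t_stim, min(t_end, t[-1] + trace.dt),
            min_amp, activation_convention,
        )
        if beat is None:
            continue
        if t_end > t[-1] + 0.5 * trace.dt:
            beat.truncated = True
            beat.flags.add("truncated")
        beats.append(beat)
    return beats


def _beat_segment(trace: Trace, beat: Beat) -> tuple[np.ndarray, np.ndarray, int]:
    """Samples of the beat window plus the index of the peak within it."""
    i0 = int(np.searchsorted(trace.time, beat.stim_time if np.isfinite(beat.stim_time)
                             else beat.t_start))
    i1 = int(np.searchsorted(trace.time, beat.t_end, side="right"))
    seg_t, seg_y = trace.time[i0:i1], trace.values[i0:i1]
    i_peak = int(np.argmin(np.abs(seg_t - beat.peak_time)))
    return seg_t, seg_y, i_peak


def apd(trace: Trace, beat: Beat, level_pct: int) -> float:
    """Action-potential duration at ``level_pct``% repolarization (ms).

    From the activation time to the first subsequent downward crossing of
    ``baseline + (1 − level_pct/100)·amplitude``, linearly interpolated.
    NaN (undefined) if repolarization never reaches the level inside the
    beat window.
    """
    if not 0 < level_pct < 100:
        raise ValueError("level_pct must be in (0, 100)")
    seg_t, seg_y, _ = _beat_segment(trace, beat)
    after = seg_t >= beat.activation_time
    level = beat.baseline + (1.0 - level_pct / 100.0) * beat.amplitude
    cross = _interp_cross_down(seg_t[after], seg_y[after], level)
    return cross - beat.activation_time if np.isfinite(cross) else np.nan


def _cat_onset(seg_t: np.ndarray, seg_y: np.ndarray, i_peak: int, beat: Beat) -> float:
    level = beat.baseline + 0.1 * beat.amplitude
    onset = _interp_cross_up_last(seg_t[: i_peak + 1], seg_y[: i_peak + 1], level)
    return onset


def catd(trace: Trace, beat: Beat, level_pct: int) -> float:
    """Ca²⁺-transient duration at ``level_pct``% recovery (ms).

    Same construction as :func:`apd` but referenced to the transient onset
    (10% upstroke crossing) rather than the maximal-derivative time.
    """
    if not 0 < level_pct < 100:
        raise ValueError("level_pct must be in (0, 100)")
    seg_t, seg_y, i_peak = _beat_segment(trace, beat)
    onset = _cat_onset(seg_t, seg_y, i_peak, beat)
    if not np.isfinite(onset):
        return np.nan
    level = beat.baseline + (1.0 - level_pct / 100.0) * beat.amplitude
    cross = _interp_cross_down(seg_t[i_peak:], seg_y[i_peak:], level)
    return cross - onset if np.isfinite(cross) else np.nan


def time_to_peak(trace: Trace, beat: Beat) -> float:
    """Time from transient onset (10% upstroke crossing) to the peak (ms).

    A beat with several near-maximal peaks uses the first global maximum and
    gains an ``ambiguous_peak`` flag.
    """
    seg_t, seg_y, i_peak = _beat_segment(trace, beat)
    onset = _cat_onset(seg_t, seg_y, i_peak, beat)
    if not np.isfinite(onset):
        return np.nan
    maxima = argrelmax(seg_y)[0]
    near = maxima[seg_y[maxima] >= beat.baseline + 0.95 * beat.amplitude]
    if near.size > 1:
        beat.flags.add("ambiguous_peak")
    return beat.peak_time - onset


def decay_tau(
    trace: Trace, beat: Beat, min_samples: int = 10
) -> tuple[float, float]:
    """Mono-exponential decay constant τ of the transient decay (ms).

    Fits ``y(t) = A·exp(−t/τ) + C`` by nonlinear least squares over the
    segment from 90% down to 10% of the beat amplitude (or to the window end
    if recovery is incomplete), initialized from a log-linear regression.
    Returns ``(tau, rmse)``; ``(nan, nan)`` with an ``undefined_tau`` flag on
    failure — never the initializer.
    """
    seg_t, seg_y, i_peak = _beat_segment(trace, beat)
    post_t, post_y = seg_t[i_peak:], seg_y[i_peak:]
    t90 = _interp_cross_down(post_t, post_y, beat.baseline + 0.9 * beat.amplitude)
    t10 = _interp_cross_down(post_t, post_y, beat.baseline + 0.1 * beat.amplitude)
    if not np.isfinite(t90):
        beat.flags.add("undefined_tau")
        return np.nan, np.nan
    t_hi = t10 if np.isfinite(t10) else post_t[-1]
    sel = (post_t >= t90) & (post_t <= t_hi)
    ts, ys = post_t[sel], post_y[sel]
    if ts.size < min_samples:
        beat.flags.add("undefined_tau")
        return np.nan, np.nan
    ts = ts - ts[0]
    span = float(ts[-1])

    # log-linear initializer, floor offset slightly below the observed minimum
    c0 = min(beat.baseline, float(ys.min()) - 1e-6 * beat.amplitude)
    pos = ys - c0 > 0
    slope, intercept = np.polyfit(ts[pos], np.log(ys[pos] - c0), 1)
    tau0 = float(np.clip(-1.0 / slope if slope < 0 else span, 1.0, 10.0 * span))
    a0 = float(np.exp(intercept))

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            ts,
            ys,
            p0=(a0, tau0, c0),
            bounds=(
                (0.0, 1.0, c0 - 2.0 * beat.amplitude),
                (10.0 * beat.amplitude, 10.0 * span, c0 + 2.0 * beat.amplitude),
            ),
            maxfev=10_000,
        )
    except RuntimeError:
        beat.flags.add("undefined_tau")
        return np.nan, np.nan
    rmse = float(np.sqrt(np.mean((model(ts, *popt) - ys) ** 2)))
    return float(popt[1]), rmse


def upstroke_and_rest(
    trace: Trace, beat: Beat, rest_epoch: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Maximal upstroke derivative (units/ms) and resting level.

    The derivative is the maximum finite difference inside the beat window;
    the resting level is the median over ``rest_epoch`` (ms interval) when
    given, otherwise over the beat's pre-upstroke diastolic window.  A beat
    with no quiescent samples (fusion beat) gets NaN and a flag.
    """
    seg_t, seg_y, i_peak = _beat_segment(trace, beat)
    dv = np.diff(seg_y[: i_peak + 1]) / trace.dt
    max_up = float(dv.max()) if dv.size else np.nan
    if rest_epoch is not None:
        mask = (trace.time >= rest_epoch[0]) & (trace.time <= rest_epoch[1])
        rest_samples = trace.values[mask]
    else:
        mask = (trace.time >= beat.t_start) & (
            trace.time <= beat.stim_time if np.isfinite(beat.stim_time)
            else trace.time <= beat.activation_time - 2 * trace.dt
        )
        rest_samples = trace.values[mask]
    if rest_samples.size == 0:
        beat.flags.add("no_diastole")
        return max_up, np.nan
    return max_up, float(np.median(rest_samples))


def beating_rate(beats: list[Beat]) -> float:
    """Mean beating rate in bpm: 60000 / mean inter-activation interval (ms).

    NaN for fewer than two beats.
    """
    acts = np.array([b.activation_time for b in beats])
    if acts.size < 2:
        return np.nan
    return 60000.0 / float(np.mean(np.diff(acts)))


def measure_beats(trace: Trace, beats: list[Beat], meta: dict | None = None) -> pd.DataFrame:
    """Per-beat metrics table for a conditioned trace.

    Voltage traces get APD20/50/80/90, max upstroke and resting level;
    calcium traces get CaTD20/50/80, time-to-peak and decay τ.  Truncated
    beats are excluded from metrics (row kept, metrics NaN, flag recorded).
    """
    rows = []
    rate = beating_rate([b for b in beats if not b.truncated])
    for beat in beats:
        row: dict = {
            "beat": beat.index,
            "channel": trace.channel,
            "stim_time": beat.stim_time,
            "activation_time": beat.activation_time,
            "peak_time": beat.peak_time,
            "amplitude": beat.amplitude,
            "baseline": beat.baseline,
            "rate_bpm": rate,
            "truncated": beat.truncated,
        }
        if not beat.truncated:
            if trace.channel == "voltage":
                for pct in (20, 50, 80, 90):
                    row[f"apd{pct}"] = apd(trace, beat, pct)
                max_up, rest = upstroke_and_rest(trace, beat)
                row["max_upstroke"] = max_up
                row["resting_level"] = rest
            else:
                for pct in (20, 50, 80):
                    row[f"catd{pct}"] = catd(trace, beat, pct)
                row["ttp"] = time_to_peak(trace, beat)
                tau, rmse = decay_tau(trace, beat)
                row["tau"] = tau
                row["tau_rmse"] = rmse
        row["flags"] = ";".join(sorted(beat.flags)) if beat.flags else ""
        if meta:
            row.update(meta)
        rows.append(row)
    return pd.DataFrame(rows)
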