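"""Electrical restitution: APD80 versus diastolic interval under ramp pacing.

The restitution curve describes how the action-potential duration
accommodates faster pacing: as the diastolic interval (DI) shortens, APD80
shortens.  Under the dynamic (variable-rate ramp) protocol, each beat
contributes one point ``(DI_n, APD80_n)`` with ``DI_n = CL_n − APD80_{n−1}``
— the current cycle length minus the preceding beat's APD80.  The curve is
summarized by a monoexponential fit ``APD80(DI) = a − b·exp(−DI/c)`` whose
maximum slope ``(b/c)·exp(−DI_min/c)``, evaluated at the shortest observed
DI, is a classical arrhythmia-dynamics index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import PacingProtocol

__all__ = ["RestitutionCurve", "compute_di", "fit_restitution"]


@dataclass
class RestitutionCurve:
    """Restitution points, monoexponential fit, and maximum slope."""

    points: pd.DataFrame  # columns: di, apd80 (+ beat bookkeeping)
    a: float = np.nan
    b: float = np.nan
    c: float = np.nan
    max_slope: float = np.nan
    fit_rmse: float = np.nan
    method: str = "exponential"  # or "local_linear", "undefined"
    diagnostics: dict = field(default_factory=dict)


def compute_di(
    metrics: pd.DataFrame,
    protocol: PacingProtocol,
    discard_per_step: int = 2,
) -> pd.DataFrame:
    """Per-beat (DI, APD80) points from a ramp recording's metrics table.

    ``metrics`` is the voltage table from :func:`cardiomap.beats.measure_beats`
    (needs ``activation_time`` and ``apd80`` per beat, in recording order).
    The first ``discard_per_step`` beats of each rate step are dropped as
    non-steady-state, as is any beat whose own or preceding APD80 is
    undefined (dropped counts are reported in ``attrs``).

    Raises for fixed-rate recordings: a single cycle length yields a single
    DI and no curve — per-beat metrics already live in the beats table.
    """
    if protocol.mode != "ramp":
        raise ValueError(
            "restitution needs a ramp (variable-rate) recording; fixed-rate "
            "metrics are already summarized by the beats module"
        )
    df = metrics.sort_values("beat").reset_index(drop=True)
    acts = df["activation_time"].to_numpy(dtype=float)
    apd80 = df["apd80"].to_numpy(dtype=float) if "apd80" in df else np.full(len(df), np.nan)
    steps = protocol.step_of_stimulus
    # align metrics rows to stimuli by beat index (one window per stimulus,
    # but low-amplitude windows may have been skipped)
    stim_idx = df["beat"].to_numpy(dtype=int)

    rows = []
    n_dropped = 0
    for k in range(1, len(df)):
        if stim_idx[k] != stim_idx[k - 1] + 1:
            n_dropped += 1
            continue  # non-consecutive beats: DI undefined
        step = int(steps[stim_idx[k]]) if steps is not None else 0
        within = int(np.sum(steps[: stim_idx[k]] == step)) if steps is not None else k
        if within < discard_per_step:
            n_dropped += 1
            continue
        cl = acts[k] - acts[k - 1]
        if not (np.isfinite(apd80[k]) and np.isfinite(apd80[k - 1])):
            n_dropped += 1
            continue
        di = cl - apd80[k - 1]
        if di <= 0:
            n_dropped += 1
            continue
        rows.append({"beat": int(stim_idx[k]), "step": step, "cl": cl,
                     "di": di, "apd80": apd80[k]})
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out


def _max_slope_local(points: pd.DataFrame, window: int = 5) -> float:
    """Fallback max slope: steepest local linear regression over a sliding
    window of the DI-sorted points."""
    pts = points.sort_values("di")
    di, apd = pts["di"].to_numpy(), pts["apd80"].to_numpy()
    if di.size < window:
        return np.nan
    slopes = []
    for i in range(di.size - window + 1):
        x, y = di[i : i + window], apd[i : i + window]
        if np.ptp(x) < 1e-9:
            continue
        slopes.append(np.polyfit(x, y, 1)[0])
    if not slopes:
        return np.nan
    return float(max(max(slopes), 0.0))


def fit_restitution(
    points: pd.DataFrame,
    rmse_threshold: float = 10.0,
    min_points: int = 5,
    min_di_span: float = 100.0,
) -> RestitutionCurve:
    """Fit ``APD80(DI) = a − b·exp(−DI/c)`` and evaluate the maximum slope.

    The maximum slope is the fitted curve's derivative ``(b/c)·exp(−DI/c)``
    at the smallest retained DI.  If the exponential fit fails to converge
    or its RMSE exceeds ``rmse_threshold`` (ms), the slope falls back to the
    steepest 5-point local linear regression of the DI-sorted points; if
    that also fails the curve is returned with ``max_slope`` undefined and
    diagnostics attached — never an exception.
    """
    pts = points.dropna(subset=["di", "apd80"]).copy()
    if len(pts) < min_points or np.ptp(pts["di"].to_numpy()) < min_di_span:
        raise ValueError(
            f"restitution fit needs >= {min_points} points spanning "
            f">= {min_di_span} ms of DI"
        )
    di = pts["di"].to_numpy(dtype=float)
    apd = pts["apd80"].to_numpy(dtype=float)
    di_min = float(di.min())
    curve = RestitutionCurve(points=pts)

    # flat curve: zero slope by construction, no exponential decay scale
    if float(np.var(apd)) < 1e-12:
        curve.a, curve.b, curve.c = float(apd.mean()), 0.0, np.nan
        curve.max_slope, curve.fit_rmse = 0.0, 0.0
        return curve

    def model(x, a, b, c):
        return a - b * np.exp(-x / c)

    try:
        span = max(float(np.ptp(di)), 1.0)
        p0 = (float(apd.max()), max(float(np.ptp(apd)), 1.0), span / 3.0)
        popt, _ = curve_fit(
            model, di, apd, p0=p0,
            bounds=((0.0, 0.0, 1.0), (np.inf, np.inf, 10.0 * span)),
            maxfev=20_000,
        )
        a, b, c = (float(v) for v in popt)
        rmse = float(np.sqrt(np.mean((model(di, a, b, c) - apd) ** 2)))
    except RuntimeError as exc:
        curve.diagnostics["exponential_fit"] = str(exc)
        a = b = c = rmse = np.nan

    if np.isfinite(rmse) and rmse <= rmse_threshold:
        curve.a, curve.b, curve.c = a, b, c
        curve.fit_rmse = rmse
        curve.max_slope = float(b / c * np.exp(-di_min / c))
        return curve

    curve.a, curve.b, curve.c, curve.fit_rmse = a, b, c, rmse
    curve.method = "local_linear"
    curve.diagnostics.setdefault("exponential_fit", f"rmse {rmse:.2f} ms above threshold")
    slope = _max_slope_local(pts)
    if np.isfinite(slope):
        curve.max_slope = slope
    else:
        curve.method = "undefined"
        curve.diagnostics["local_linear"] = "no window with usable DI spread"
    return curve
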