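"""Ground-truth-annotated synthetic optical-mapping recordings.

Emulates dual-dye (voltage + Ca²⁺) monolayer recordings of atrial-like and
ventricular-like cardiomyocytes: action potentials as a logistic upstroke
multiplied by a plateau-then-fall repolarization envelope, Ca²⁺ transients
as a linear rise to peak followed by an exact mono-exponential decay.  Every generated beat carries ground truth (APD/CaTD at several
repolarization levels, time-to-peak, decay τ, activation time) measured on a
dense 0.01 ms grid with the same conventions the analysis modules use, so
recovery can be tested against an oracle that is independent of sampling.

Rate dependence (electrical restitution) is modelled by rescaling each beat's
duration-controlling parameters so that its true APD80 follows a prescribed
monoexponential restitution map APD80(DI) = a − b·exp(−DI/c).

Drug action rescales duration-controlling parameters through saturating Hill
dose-effect curves; acquisition is emulated by additive Gaussian noise, slow
linear baseline drift (photobleaching) and an affine counts model with
optional voltage-polarity inversion, rendered to multi-page image stacks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .protocols import PacingProtocol
from .trace import Trace

__all__ = [
    "CellTypeParams",
    "RestitutionParams",
    "HillEffect",
    "DrugModel",
    "NoiseModel",
    "MovieSpec",
    "SyntheticRecording",
    "ATRIAL",
    "VENTRICULAR",
    "ATRIAL_RESTITUTION",
    "VENTRICULAR_RESTITUTION",
    "PRESETS",
    "PRESET_RESTITUTION",
    "generate_ap_trace",
    "generate_cat_trace",
    "apply_drug_effect",
    "add_noise",
    "render_movie",
    "write_movie",
]

#: Ground-truth oracle grid spacing (ms).
TRUTH_DT = 0.01
#: Coarser grid used only inside the restitution scale solver.
_SOLVE_DT = 0.1

# The Ca²⁺ rise is linear, so the 10% level sits at 0.1 of the rise
# duration; rise duration is cat_ttp / 0.9 so that the 10%-to-peak time
# equals cat_ttp by construction.
_CAT_RISE10 = 0.1

_AP_DURATION_FIELDS = ("ap_plateau_dur", "ap_notch_tau", "ap_repol_tau")
_CAT_DURATION_FIELDS = ("cat_ttp", "cat_decay_tau")
_SCALABLE_FIELDS = _AP_DURATION_FIELDS + _CAT_DURATION_FIELDS


@dataclass(frozen=True)
class CellTypeParams:
    """Waveform parameters of one cardiomyocyte subtype.

    Action potential: logistic upstroke (time constant ``ap_upstroke_tau``)
    multiplied by a repolarization envelope: a fraction
    ``1 − ap_plateau_fraction`` of the amplitude decays early with time
    constant ``ap_notch_tau`` while ``ap_plateau_fraction`` is held for
    ``ap_plateau_dur`` and then falls with an exponential tail of time
    constant ``ap_repol_tau``.  Ca²⁺ transient: linear rise whose
    10%-to-peak time is ``cat_ttp``, then exact exponential decay with
    ``cat_decay_tau``, starting ``cat_onset_delay`` after voltage activation.
    All times in ms; ``amplitude``/``resting_level`` in arbitrary units.
    """

    label: str
    ap_upstroke_tau: float
    ap_plateau_fraction: float
    ap_plateau_dur: float
    ap_repol_tau: float
    cat_ttp: float
    cat_decay_tau: float
    cat_onset_delay: float
    amplitude: float = 1.0
    resting_level: float = 0.0
    ap_notch_tau: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "ap_upstroke_tau",
            "ap_repol_tau",
            "ap_notch_tau",
            "cat_ttp",
            "cat_decay_tau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ap_plateau_fraction <= 1.0:
            raise ValueError("ap_plateau_fraction must lie in [0, 1]")
        if self.ap_plateau_dur < 0 or self.cat_onset_delay < 0:
            raise ValueError("durations and delays must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def scaled(self, factor: float, fields: tuple[str, ...]) -> "CellTypeParams":
        """Copy with the named duration fields multiplied by ``factor``."""
        changes = {f: getattr(self, f) * factor for f in fields}
        return replace(self, **changes)


@dataclass(frozen=True)
class RestitutionParams:
    """Monoexponential restitution map APD80(DI) = a − b·exp(−DI/c) (ms)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b < 0 or self.c <= 0:
            raise ValueError("restitution requires b >= 0 and c > 0")

    def apd80(self, di: float) -> float:
        return self.a - self.b * np.exp(-di / self.c)

    def slope(self, di: float) -> float:
        """d(APD80)/d(DI) at ``di`` — the closed-form restitution slope."""
        return self.b / self.c * np.exp(-di / self.c)


@dataclass(frozen=True)
class HillEffect:
    """Saturating dose effect: fractional change emax·dⁿ/(dⁿ + ec50ⁿ)."""

    emax: float
    ec50: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")

    def fraction(self, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be non-negative")
        if dose == 0:
            return 0.0
        dn = dose**self.hill_n
        return self.emax * dn / (dn + self.ec50**self.hill_n)


@dataclass(frozen=True)
class DrugModel:
    """Named drug with per-target Hill effects.

    Targets are waveform duration fields (``ap_repol_tau`` ...) or the
    composite keys ``"apd"`` (all AP duration parameters) and ``"catd"``
    (all CaT duration parameters).
    """

    name: str
    effects: Mapping[str, HillEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(_SCALABLE_FIELDS) | {"apd", "catd"}
        for target in self.effects:
            if target not in valid:
                raise ValueError(f"unknown drug target {target!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive acquisition noise: white Gaussian (as a fraction of signal
    amplitude) plus slow linear baseline drift emulating photobleaching."""

    gaussian_sd: float = 0.02
    drift_slope: float = 0.005  # fraction of amplitude per second
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class MovieSpec:
    """Geometry and counts model of a rendered dual-channel image stack."""

    height: int = 24
    width: int = 24
    frame_rate: float = 100.0
    channel_layout: str = "interleaved"  # or "stacked"
    gain: float = 1.0
    offset: float = 0.0
    voltage_polarity: str = "inverted"  # or "positive"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.gain == 0:
            raise ValueError("gain must be nonzero")
        if self.channel_layout not in ("interleaved", "stacked"):
            raise ValueError(f"unknown channel_layout {self.channel_layout!r}")
        if self.voltage_polarity not in ("positive", "inverted"):
            raise ValueError(f"unknown voltage_polarity {self.voltage_polarity!r}")


@dataclass
class SyntheticRecording:
    """A generated trace plus its per-beat ground-truth manifest."""

    trace: Trace
    manifest: pd.DataFrame
    params: CellTypeParams


# ---------------------------------------------------------------------------
# Tuned subtype presets.
#
# Targets for the tuning (frozen values below) are optically measured
# monolayer phenotypes: atrial-like APD20/50/80 = 84/131/179 ms with a short
# triangular AP, ventricular-like 127/191/251 ms with a prolonged plateau;
# CaT 10%-to-peak 116 vs 246 ms and decay tau 350 vs 430 ms (the ventricular
# decay is capped so the transient completes 80% recovery inside a 1 Hz
# cycle, which a literal mono-exponential with the slower published tail
# cannot; see docs/methods.md).
# ---------------------------------------------------------------------------

ATRIAL = CellTypeParams(
    label="atrial",
    ap_upstroke_tau=4.0,
    ap_plateau_fraction=0.610388,
    ap_plateau_dur=133.0391,
    ap_repol_tau=24.5419,
    ap_notch_tau=137.3969,
    cat_ttp=116.0,
    cat_decay_tau=350.0,
    cat_onset_delay=15.0,
)

VENTRICULAR = CellTypeParams(
    label="ventricular",
    ap_upstroke_tau=4.0,
    ap_plateau_fraction=0.842704,
    ap_plateau_dur=194.1550,
    ap_repol_tau=42.4048,
    ap_notch_tau=16.5654,
    cat_ttp=246.0,
    cat_decay_tau=430.0,
    cat_onset_delay=15.0,
)

PRESETS = {"atrial": ATRIAL, "ventricular": VENTRICULAR}

# Restitution maps per subtype, tuned (scratch calibration against the full
# ramp pipeline) so the measured maximum restitution slope lands near the
# optical phenotype targets: ~0.91 (atrial) and ~1.26 (ventricular), with
# the ventricular curve steeper at short DI.
ATRIAL_RESTITUTION = RestitutionParams(a=180.0, b=720.0, c=120.0)
VENTRICULAR_RESTITUTION = RestitutionParams(a=252.0, b=520.0, c=120.0)
PRESET_RESTITUTION = {
    "atrial": ATRIAL_RESTITUTION,
    "ventricular": VENTRICULAR_RESTITUTION,
}


# ---------------------------------------------------------------------------
# Waveform algebra
# ---------------------------------------------------------------------------


def _ap_shape(t: np.ndarray, p: CellTypeParams, scale: float = 1.0) -> np.ndarray:
    """Unnormalized AP waveform at times ``t`` (ms from stimulus).

    The waveform is a logistic upstroke (time constant ``ap_upstroke_tau``,
    centred 5 time constants after the stimulus) multiplied by a
    repolarization envelope with two components: a fast early decay of
    weight ``1 − ap_plateau_fraction`` and time constant ``ap_notch_tau``,
    plus a plateau component of weight ``ap_plateau_fraction`` that holds
    for ``ap_plateau_dur`` and then falls sigmoidally with time constant
    ``ap_repol_tau`` (so the late tail decays exponentially with
    ``ap_repol_tau``).  A large plateau fraction gives the prolonged
    ventricular dome; a small one the short triangular atrial shape.

    ``scale`` multiplies the duration-controlling envelope constants
    (plateau duration, notch tau, repolarization tau); the upstroke is rate
    independent.
    """
    t = np.asarray(t, dtype=float)
    t_up = 5.0 * p.ap_upstroke_tau
    s = expit((t - t_up) / p.ap_upstroke_tau)
    u = np.maximum(t - t_up, 0.0)
    pf = p.ap_plateau_fraction
    d = p.ap_plateau_dur * scale
    tau_n = p.ap_notch_tau * scale
    tau_r = p.ap_repol_tau * scale
    r = (1.0 - pf) * np.exp(-u / tau_n) + pf * expit((d - u) / tau_r)
    return s * r


def _cat_shape(t: np.ndarray, p: CellTypeParams, scale: float = 1.0) -> np.ndarray:
    """Unit-amplitude CaT waveform at times ``t`` (ms from CaT onset).

    Linear rise to the peak over ``cat_ttp/0.9`` followed by an exact
    mono-exponential decay with ``cat_decay_tau`` — the fitted τ and the
    recovery-level crossings therefore have closed forms.
    """
    t = np.asarray(t, dtype=float)
    t_rise = p.cat_ttp * scale / (1.0 - _CAT_RISE10)
    tau = p.cat_decay_tau * scale
    rise = np.clip(t, 0.0, t_rise) / t_rise
    out = np.where(t <= t_rise, rise, np.exp(-(np.maximum(t, t_rise) - t_rise) / tau))
    return np.where(t < 0, 0.0, out)


def _crossing_down(t: np.ndarray, y: np.ndarray, level: float, start: int) -> float:
    """First downward crossing of ``level`` at index >= start, linear interp."""
    yy = y[start:]
    hits = np.nonzero((yy[:-1] >= level) & (yy[1:] < level))[0]
    if hits.size == 0:
        return np.nan
    i = start + hits[0]
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def _crossing_up(t: np.ndarray, y: np.ndarray, level: float, stop: int) -> float:
    """Last upward crossing of ``level`` at index < stop, linear interp."""
    yy = y[: stop + 1]
    hits = np.nonzero((yy[:-1] < level) & (yy[1:] >= level))[0]
    if hits.size == 0:
        return np.nan
    i = hits[-1]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return t[i] + frac * (t[i + 1] - t[i])


def _params_key(p: CellTypeParams) -> tuple:
    return dataclasses.astuple(p)


@lru_cache(maxsize=512)
def _measure_ap_cached(key: tuple, scale: float, dt: float) -> dict:
    p = CellTypeParams(*key)
    return _measure_ap(p, scale, dt)


def _ap_window(p: CellTypeParams, scale: float) -> float:
    """Analytic bound on the time (ms from stimulus) of ~99.5% repolarization."""
    pf = p.ap_plateau_fraction
    d = p.ap_plateau_dur * scale
    tau_n = p.ap_notch_tau * scale
    tau_r = p.ap_repol_tau * scale
    tail_notch = tau_n * np.log(max(1.0 - pf, 1e-6) / 0.004)
    tail_plateau = d + tau_r * np.log(max(pf, 1e-6) / 0.004)
    return 5.0 * p.ap_upstroke_tau + max(tail_notch, tail_plateau, 0.0) + 20.0


def _measure_ap(p: CellTypeParams, scale: float = 1.0, dt: float = TRUTH_DT) -> dict:
    """Dense-grid ground-truth metrics of a single AP beat (baseline 0)."""
    t = np.arange(0.0, _ap_window(p, scale), dt)
    w = _ap_shape(t, p, scale)
    wmax = w.max()
    w = w / wmax  # unit amplitude
    i_peak = int(np.argmax(w))
    dv = np.gradient(w, dt)
    i_act = int(np.argmax(dv[: i_peak + 1]))  # earliest tie wins via argmax
    act_t = t[i_act]
    out = {
        "act_offset": act_t,
        "peak_offset": t[i_peak],
        "shape_max": wmax,
        "scale": scale,
    }
    for level_pct in (20, 50, 80, 90):
        level = 1.0 - level_pct / 100.0
        cross = _crossing_down(t, w, level, i_peak)
        out[f"apd{level_pct}"] = cross - act_t if np.isfinite(cross) else np.nan
    t99 = _crossing_down(t, w, 0.01, i_peak)
    out["t99_offset"] = t99 if np.isfinite(t99) else t[-1]
    return out


def _measure_cat(p: CellTypeParams, scale: float = 1.0, dt: float = TRUTH_DT) -> dict:
    """Dense-grid ground-truth metrics of a single CaT beat (baseline 0)."""
    t_rise = p.cat_ttp * scale / (1.0 - _CAT_RISE10)
    tau = p.cat_decay_tau * scale
    t_end = t_rise + tau * np.log(1.0 / 0.005) + 20.0
    t = np.arange(0.0, t_end, dt)
    w = _cat_shape(t, p, scale)
    i_peak = int(np.argmax(w))
    onset = _crossing_up(t, w, 0.1, i_peak)
    out = {
        "onset_offset": onset,
        "peak_offset": t[i_peak],
        "ttp": t[i_peak] - onset,
        "tau": tau,
        "scale": scale,
    }
    for level_pct in (20, 50, 80):
        level = 1.0 - level_pct / 100.0
        cross = _crossing_down(t, w, level, i_peak)
        out[f"catd{level_pct}"] = cross - onset if np.isfinite(cross) else np.nan
    t99 = _crossing_down(t, w, 0.01, i_peak)
    out["t99_offset"] = t99 if np.isfinite(t99) else t[-1]
    return out


def _solve_ap_scale(p: CellTypeParams, target_apd80: float) -> float:
    """Scale factor on duration parameters giving the target true APD80."""
    key = _params_key(p)

    def err(k: float) -> float:
        return _measure_ap_cached(key, round(k, 6), _SOLVE_DT)["apd80"] - target_apd80

    base = _measure_ap_cached(key, 1.0, _SOLVE_DT)["apd80"]
    k0 = max(target_apd80 / base, 0.05)
    lo, hi = 0.5 * k0, 2.0 * k0
    flo, fhi = err(lo), err(hi)
    for _ in range(30):
        if flo < 0 < fhi:
            break
        if flo >= 0:
            lo *= 0.7
            flo = err(lo)
        if fhi <= 0:
            hi *= 1.4
            fhi = err(hi)
    return float(brentq(err, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# Trace generation
# ---------------------------------------------------------------------------


def _time_grid(frame_rate: float, duration: float) -> np.ndarray:
    n = int(round(duration * frame_rate / 1000.0))
    return np.arange(n) * (1000.0 / frame_rate)


def _check_protocol(protocol: PacingProtocol, duration: float) -> np.ndarray:
    if protocol.mode == "spontaneous" or protocol.stimulus_times is None:
        raise ValueError("generation requires a fixed or ramp protocol with stimuli")
    stims = protocol.stimulus_times
    if stims[0] < 0 or stims[-1] > duration:
        raise ValueError("stimulus times must fall inside [0, duration]")
    return stims


def generate_ap_trace(
    params: CellTypeParams,
    protocol: PacingProtocol,
    frame_rate: float = 100.0,
    duration: float = 10_000.0,
    restitution: RestitutionParams | None = None,
) -> SyntheticRecording:
    """Generate a voltage trace with one AP per stimulus plus ground truth.

    With ``restitution``, each beat's duration parameters are rescaled so its
    true APD80 equals a − b·exp(−DI/c) where DI = cycle length − preceding
    true APD80 (dynamic restitution).  Beats whose stimulus lands before 99%
    repolarization of the previous beat are flagged ``overlap`` in the
    manifest (the waveforms are combined by pointwise maximum, emulating an
    elevated take-off level), never raised as errors — the fast end of a
    restitution ramp needs this regime.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    stims = _check_protocol(protocol, duration)
    t = _time_grid(frame_rate, duration)
    signal = np.zeros_like(t)
    rows: list[dict] = []
    if params.amplitude == 0.0:
        trace = Trace(t, np.full_like(t, params.resting_level), "voltage",
                      {"frame_rate": frame_rate, "label": params.label})
        return SyntheticRecording(trace, pd.DataFrame(), params)

    key = _params_key(params)
    prev_apd80 = np.nan
    prev_end99 = -np.inf
    for n, s in enumerate(stims):
        cl = s - stims[n - 1] if n > 0 else np.nan
        di = np.nan
        scale = 1.0
        if restitution is not None and n > 0 and np.isfinite(prev_apd80):
            di = cl - prev_apd80
            # floor keeps the target physiological when DI collapses
            target = max(restitution.apd80(max(di, 1.0)), 30.0)
            scale = _solve_ap_scale(params, target)
        truth = _measure_ap_cached(key, round(scale, 6), TRUTH_DT)
        window_end = s + _ap_window(params, scale)
        mask = (t >= s) & (t <= window_end)
        w = _ap_shape(t[mask] - s, params, scale) / truth["shape_max"]
        signal[mask] = np.maximum(signal[mask], params.amplitude * w)
        overlap = bool(s < prev_end99)
        row = {
            "beat": n,
            "stim_time": s,
            "cycle_length": cl,
            "di": di,
            "scale": scale,
            "activation_time": s + truth["act_offset"],
            "peak_time": s + truth["peak_offset"],
            "amplitude": params.amplitude,
            "overlap": overlap,
            "truncated": bool(s + truth["t99_offset"] > duration),
        }
        for m in ("apd20", "apd50", "apd80", "apd90"):
            row[m] = truth[m]
        rows.append(row)
        prev_apd80 = truth["apd80"]
        prev_end99 = s + truth["t99_offset"]

    values = params.resting_level + signal
    trace = Trace(t, values, "voltage", {"frame_rate": frame_rate, "label": params.label})
    return SyntheticRecording(trace, pd.DataFrame(rows), params)


def generate_cat_trace(
    params: CellTypeParams,
    protocol: PacingProtocol,
    frame_rate: float = 100.0,
    duration: float = 10_000.0,
) -> SyntheticRecording:
    """Generate a Ca²⁺-transient trace with one transient per stimulus.

    The transient starts ``cat_onset_delay`` after the voltage activation
    time of the same stimulus; its decay is exactly exponential with
    ``cat_decay_tau``, so the manifest τ is exact by construction.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    stims = _check_protocol(protocol, duration)
    t = _time_grid(frame_rate, duration)
    signal = np.zeros_like(t)
    if params.amplitude == 0.0:
        trace = Trace(t, np.full_like(t, params.resting_level), "calcium",
                      {"frame_rate": frame_rate, "label": params.label})
        return SyntheticRecording(trace, pd.DataFrame(), params)

    truth = _measure_cat(params, 1.0, TRUTH_DT)
    ap_act = 5.0 * params.ap_upstroke_tau
    rows: list[dict] = []
    prev_end99 = -np.inf
    for n, s in enumerate(stims):
        onset_abs = s + ap_act + params.cat_onset_delay
        window_end = onset_abs + truth["t99_offset"] + 10.0
        mask = (t >= onset_abs) & (t <= window_end)
        w = _cat_shape(t[mask] - onset_abs, params)
        signal[mask] = np.maximum(signal[mask], params.amplitude * w)
        rows.append(
            {
                "beat": n,
                "stim_time": s,
                "onset_time": onset_abs + truth["onset_offset"],
                "peak_time": onset_abs + truth["peak_offset"],
                "amplitude": params.amplitude,
                "ttp": truth["ttp"],
                "tau": truth["tau"],
                "catd20": truth["catd20"],
                "catd50": truth["catd50"],
                "catd80": truth["catd80"],
                "overlap": bool(s < prev_end99),
                "truncated": bool(onset_abs + truth["t99_offset"] > duration),
            }
        )
        prev_end99 = onset_abs + truth["t99_offset"]

    values = params.resting_level + signal
    trace = Trace(t, values, "calcium", {"frame_rate": frame_rate, "label": params.label})
    return SyntheticRecording(trace, pd.DataFrame(rows), params)


# ---------------------------------------------------------------------------
# Drug action and noise
# ---------------------------------------------------------------------------

_COMPOSITE_TARGETS = {"apd": _AP_DURATION_FIELDS, "catd": _CAT_DURATION_FIELDS}


def apply_drug_effect(
    params: CellTypeParams, drug: DrugModel, dose: float
) -> CellTypeParams:
    """Rescale the drug's target duration parameters at the given dose.

    Each target parameter is multiplied by ``1 + emax·dⁿ/(dⁿ + ec50ⁿ)``;
    untargeted parameters are untouched, and dose 0 is the exact identity.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    out = params
    for target, effect in drug.effects.items():
        factor = 1.0 + effect.fraction(dose)
        fields = _COMPOSITE_TARGETS.get(target, (target,))
        out = out.scaled(factor, fields)
    return out


def add_noise(trace: Trace, noise: NoiseModel, rng: np.random.Generator | None = None) -> Trace:
    """Additive Gaussian noise and linear baseline drift, scaled to amplitude."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    amp = float(np.ptp(trace.values))
    if amp == 0.0:
        amp = 1.0
    drift = noise.drift_slope * amp * (trace.time - trace.time[0]) / 1000.0
    jitter = rng.normal(0.0, noise.gaussian_sd * amp, size=len(trace))
    return trace.with_values(trace.values + drift + jitter)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


def render_movie(
    v_trace: Trace,
    ca_trace: Trace,
    spec: MovieSpec,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a dual-channel image stack from voltage and Ca²⁺ traces.

    Every pixel carries ``offset + gain·(signal + noise + drift)``; the
    voltage channel is negated about its mean when
    ``spec.voltage_polarity == "inverted"`` (voltage-sensitive dyes report
    depolarization as a fluorescence decrease).  Returns the float frame
    stack (channel layout per ``spec``) and a manifest dict.
    """
    if len(v_trace) != len(ca_trace):
        raise ValueError("voltage and calcium traces differ in length")
    if not np.allclose(v_trace.time, ca_trace.time):
        raise ValueError("voltage and calcium traces must share a time base")
    if not np.isclose(v_trace.frame_rate, spec.frame_rate, rtol=1e-6):
        raise ValueError(
            f"trace frame rate {v_trace.frame_rate:g} does not match "
            f"spec.frame_rate {spec.frame_rate:g}"
        )
    n = len(v_trace)
    h, w = spec.height, spec.width
    v_sig = v_trace.values.copy()
    if spec.voltage_polarity == "inverted":
        v_sig = 2.0 * v_sig.mean() - v_sig
    ca_sig = ca_trace.values

    rng = np.random.default_rng(noise.seed) if noise is not None else None
    channels = []
    for sig in (v_sig, ca_sig):
        frames = np.broadcast_to(sig[:, None, None], (n, h, w)).astype(float).copy()
        if noise is not None:
            amp = float(np.ptp(sig)) or 1.0
            t_s = (v_trace.time - v_trace.time[0]) / 1000.0
            frames += (noise.drift_slope * amp * t_s)[:, None, None]
            frames += rng.normal(0.0, noise.gaussian_sd * amp, size=(n, h, w))
        channels.append(spec.offset + spec.gain * frames)

    if spec.channel_layout == "interleaved":
        movie = np.empty((2 * n, h, w), dtype=float)
        movie[0::2] = channels[0]
        movie[1::2] = channels[1]
    else:
        movie = np.concatenate(channels, axis=0)

    manifest = {
        "channel_layout": spec.channel_layout,
        "frame_rate": float(spec.frame_rate),
        "n_frames_per_channel": int(n),
        "split_index": int(n) if spec.channel_layout == "stacked" else None,
        "channel_order": ["voltage", "calcium"],
        "gain": float(spec.gain),
        "offset": float(spec.offset),
        "voltage_polarity": spec.voltage_polarity,
        "height": h,
        "width": w,
    }
    return movie, manifest


def write_movie(
    path: str | Path,
    movie: np.ndarray,
    manifest: dict,
    ground_truth: Mapping[str, pd.DataFrame] | None = None,
) -> Path:
    """Write a rendered stack as 16-bit multi-page TIFF plus a YAML sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(movie), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = dict(manifest)
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            ch: df.to_dict(orient="list") for ch, df in ground_truth.items()
        }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return path
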