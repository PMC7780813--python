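"""Study-level synthetic cohorts: wells, screens, and null simulations.

Emulates the design of a multiwell drug screen on atrial-like and
ventricular-like cardiomyocyte monolayers: n wells per group (default 6,
one per differentiation batch), each recorded at a predrug baseline and at
four sequentially increasing doses of one drug.  Biological variability is
modelled as a per-well lognormal scale on all duration parameters plus a
smaller per-recording scale (dish-to-dish and session-to-session spread);
acquisition noise and photobleaching drift come from
:class:`cardiomap.synth.NoiseModel`.

Baseline phenotyping is paced at 1 Hz; drug-screen recordings are paced
slightly slower (0.75 Hz) so that the slowest Ca²⁺ transient retains
headroom to complete its 80% recovery inside the cycle after drug
prolongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beats import detect_beats, measure_beats
from .io_signal import condition
from .protocols import PacingProtocol
from .synth import (
    ATRIAL,
    VENTRICULAR,
    CellTypeParams,
    DrugModel,
    HillEffect,
    NoiseModel,
    apply_drug_effect,
    add_noise,
    generate_ap_trace,
    generate_cat_trace,
)

__all__ = [
    "ScreenDrug",
    "DOFETILIDE_LIKE",
    "UCL1684_LIKE",
    "NIFEDIPINE_LIKE",
    "NULL_DRUG",
    "DRUGS",
    "CohortDesign",
    "simulate_well_recording",
    "simulate_screen",
    "simulate_null_metrics",
]

#: Duration fields rescaled by well/recording variability.
_VARIABLE_FIELDS = (
    "ap_plateau_dur",
    "ap_notch_tau",
    "ap_repol_tau",
    "cat_ttp",
    "cat_decay_tau",
)

AP_METRICS = ("apd20", "apd50", "apd80")
CAT_METRICS = ("catd20", "catd50", "catd80")


@dataclass(frozen=True)
class ScreenDrug:
    """A screening compound: dose series plus per-group Hill models."""

    name: str
    doses: tuple[float, ...]
    dose_unit: str
    models: dict[str, DrugModel] = field(default_factory=dict)

    def model_for(self, group: str) -> DrugModel:
        return self.models.get(group, DrugModel(self.name, {}))


# Canonical screen compounds.  Emax/EC50 values are chosen so that the
# group-mean percent changes at the top dose land near the printed optical
# dose-response magnitudes (e.g. ~+95% atrial vs ~+34% ventricular APD80
# prolongation for the pan-cardiac repolarization blocker at 100 nM, and an
# atrial-only response for the SK-channel blocker).
DOFETILIDE_LIKE = ScreenDrug(
    name="dofetilide_like",
    doses=(3.0, 10.0, 30.0, 100.0),
    dose_unit="nM",
    models={
        "atrial": DrugModel(
            "dofetilide_like",
            {
                "apd": HillEffect(emax=1.05, ec50=12.0),
                "catd": HillEffect(emax=0.30, ec50=12.0),
            },
        ),
        "ventricular": DrugModel(
            "dofetilide_like",
            {
                "apd": HillEffect(emax=0.40, ec50=20.0),
                "catd": HillEffect(emax=0.18, ec50=20.0),
            },
        ),
    },
)

UCL1684_LIKE = ScreenDrug(
    name="ucl1684_like",
    doses=(0.3, 1.0, 3.0, 10.0),
    dose_unit="uM",
    models={
        "atrial": DrugModel(
            "ucl1684_like",
            {
                "apd": HillEffect(emax=0.55, ec50=1.3),
                "catd": HillEffect(emax=0.42, ec50=0.25),
            },
        ),
        "ventricular": DrugModel("ucl1684_like", {}),
    },
)

NIFEDIPINE_LIKE = ScreenDrug(
    name="nifedipine_like",
    doses=(10.0, 30.0, 100.0, 300.0),
    dose_unit="nM",
    models={
        "atrial": DrugModel(
            "nifedipine_like",
            {
                "apd": HillEffect(emax=-0.10, ec50=60.0),
                "catd": HillEffect(emax=-0.12, ec50=60.0),
            },
        ),
        "ventricular": DrugModel(
            "nifedipine_like",
            {
                "apd": HillEffect(emax=-0.30, ec50=40.0),
                "catd": HillEffect(emax=-0.35, ec50=40.0),
            },
        ),
    },
)

NULL_DRUG = ScreenDrug(
    name="null_drug",
    doses=(1.0, 2.0, 3.0, 4.0),
    dose_unit="au",
    models={},
)

#: Registry of the canonical screen compounds.
DRUGS = {
    d.name: d for d in (DOFETILIDE_LIKE, UCL1684_LIKE, NIFEDIPINE_LIKE, NULL_DRUG)
}


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of a simulated screen."""

    n_wells: int = 6
    groups: tuple[str, ...] = ("atrial", "ventricular")
    well_cv: float = 0.10  # per-well lognormal sd on duration scales
    recording_cv: float = 0.04  # per-recording lognormal sd
    frame_rate: float = 100.0
    pacing_hz: float = 0.75
    n_beats: int = 8
    noise: NoiseModel = NoiseModel(gaussian_sd=0.02, drift_slope=0.005)

    def preset(self, group: str) -> CellTypeParams:
        return {"atrial": ATRIAL, "ventricular": VENTRICULAR}[group]


def _scale_params(params: CellTypeParams, factor: float) -> CellTypeParams:
    return params.scaled(factor, _VARIABLE_FIELDS)


def simulate_well_recording(
    params: CellTypeParams,
    rng: np.random.Generator,
    design: CohortDesign,
    pacing_hz: float | None = None,
) -> pd.DataFrame:
    """Simulate one dual-channel recording and measure its per-beat metrics.

    Returns the merged voltage + calcium metrics table of the conditioned
    recording (noise and drift applied, then detrended/normalized).
    """
    hz = pacing_hz if pacing_hz is not None else design.pacing_hz
    cl = 1000.0 / hz
    protocol = PacingProtocol.fixed(hz, design.n_beats, start_ms=100.0)
    duration = protocol.end_time(cl)
    frames = []
    for gen in (generate_ap_trace, generate_cat_trace):
        rec = gen(params, protocol, design.frame_rate, duration)
        noise = replace(design.noise, seed=int(rng.integers(2**31)))
        noisy = add_noise(rec.trace, noise)
        tr = condition(noisy, polarity="positive", detrend_window_ms=2.0 * cl)
        beats = detect_beats(tr, protocol)
        frames.append(measure_beats(tr, beats))
    return pd.concat(frames, ignore_index=True)


def _mean_metrics(df: pd.DataFrame) -> dict[str, float]:
    out = {}
    ok = df[~df["truncated"]]
    for metric in AP_METRICS + CAT_METRICS:
        if metric in ok.columns:
            out[metric] = float(ok[metric].mean())
    return out


def simulate_screen(
    drug: ScreenDrug,
    design: CohortDesign = CohortDesign(),
    seed: int = 0,
    metrics: tuple[str, ...] = AP_METRICS + CAT_METRICS,
) -> pd.DataFrame:
    """Simulate a sequential-dose screen; return the tidy dose table.

    One row per (well, group, dose, metric) holding the well's beat-averaged
    metric from a full trace simulation.  Dose 0 is the predrug baseline
    recording of the same well.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in design.groups:
        preset = design.preset(group)
        model = drug.model_for(group)
        for w in range(design.n_wells):
            well_id = f"{group[0]}CM-{w + 1}"
            well_scale = float(np.exp(rng.normal(0.0, design.well_cv)))
            well_params = _scale_params(preset, well_scale)
            for dose in (0.0,) + tuple(drug.doses):
                dosed = apply_drug_effect(well_params, model, dose)
                rec_scale = float(np.exp(rng.normal(0.0, design.recording_cv)))
                dosed = _scale_params(dosed, rec_scale)
                measured = _mean_metrics(
                    simulate_well_recording(dosed, rng, design)
                )
                for metric in metrics:
                    rows.append(
                        {
                            "well": well_id,
                            "group": group,
                            "dose": dose,
                            "dose_unit": drug.dose_unit,
                            "metric": metric,
                            "value": measured.get(metric, np.nan),
                            "drug": drug.name,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_null_metrics(
    rng: np.random.Generator,
    design: CohortDesign = CohortDesign(),
    doses: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0),
    metric: str = "apd80",
    base_value: float = 179.0,
) -> pd.DataFrame:
    """Metric-level screen under the null hypothesis of no drug effect.

    Samples the same two-level variability model the trace simulator uses —
    a lognormal per-well scale and an independent lognormal per-recording
    scale — without rendering traces, so large replicate counts stay cheap.
    """
    rows = []
    for group in design.groups:
        for w in range(design.n_wells):
            well_id = f"{group[0]}CM-{w + 1}"
            well_scale = np.exp(rng.normal(0.0, design.well_cv))
            for dose in (0.0,) + tuple(doses):
                rec_scale = np.exp(rng.normal(0.0, design.recording_cv))
                rows.append(
                    {
                        "well": well_id,
                        "group": group,
                        "dose": dose,
                        "metric": metric,
                        "value": base_value * well_scale * rec_scale,
                    }
                )
    return pd.DataFrame(rows)
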