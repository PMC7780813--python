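"""End-to-end orchestration: reproducible runs from a single config.

A :class:`RunConfig` (YAML-serializable, fully explicit — no hidden
defaults affecting numerics) drives the three analysis stages over
synthetic cohorts:

1. baseline phenotyping — fixed 1 Hz pacing, per-beat AP/CaT metrics and
   atrial-vs-ventricular comparisons;
2. electrical restitution — 60–200 bpm ramp per well, (DI, APD80) curve
   and maximum-slope fits;
3. drug screens — sequential four-dose tables, percent change from
   baseline, between-group t tests and within-group ANOVA + Dunnett.

Every random draw descends from the single run seed through
``numpy.random.SeedSequence``, so a run is reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import detect_beats, measure_beats
from .cohort import (
    DRUGS,
    NIFEDIPINE_LIKE,
    NULL_DRUG,
    CohortDesign,
    simulate_well_recording,
    _scale_params,
)
from .doseresponse import add_percent_change, assemble_screen_report
from .io_signal import condition
from .protocols import PacingProtocol
from .restitution import compute_di, fit_restitution
from .stats import welch_ttest
from .synth import (
    ATRIAL,
    MovieSpec,
    NoiseModel,
    PRESET_RESTITUTION,
    PRESETS,
    VENTRICULAR,
    generate_ap_trace,
    generate_cat_trace,
    add_noise,
    render_movie,
    write_movie,
)
from .trace import write_trace

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """Fully explicit configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    n_wells: int = 6
    groups: tuple[str, ...] = ("atrial", "ventricular")
    frame_rate: float = 100.0
    baseline_pacing_hz: float = 1.0
    baseline_n_beats: int = 8
    screen_pacing_hz: float = 0.75
    ramp: dict = field(
        default_factory=lambda: {
            "bpm_start": 60.0,
            "bpm_end": 200.0,
            "bpm_step": 10.0,
            "beats_per_step": 8,
            "discard_per_step": 2,
        }
    )
    drugs: tuple[str, ...] = ("dofetilide_like", "ucl1684_like", "null_drug")
    noise: dict = field(
        default_factory=lambda: {"gaussian_sd": 0.02, "drift_slope": 0.005}
    )
    well_cv: float = 0.10
    recording_cv: float = 0.04
    activation_convention: str = "max_derivative"
    detrend_method: str = "percentile"
    ttest_variant: str = "welch"
    restitution_wells: int = 4

    def validate(self) -> None:
        """Raise with a field path on the first invalid entry."""
        checks = [
            ("n_wells", self.n_wells >= 1),
            ("frame_rate", self.frame_rate > 0),
            ("baseline_pacing_hz", self.baseline_pacing_hz > 0),
            ("screen_pacing_hz", self.screen_pacing_hz > 0),
            ("restitution_wells", self.restitution_wells >= 1),
            ("well_cv", self.well_cv >= 0),
            ("recording_cv", self.recording_cv >= 0),
            (
                "activation_convention",
                self.activation_convention in ("max_derivative", "upstroke_mid"),
            ),
            ("detrend_method", self.detrend_method in ("percentile", "polynomial")),
            ("ttest_variant", self.ttest_variant in ("welch", "student")),
        ]
        for path, ok in checks:
            if not ok:
                raise ValueError(f"config field {path!r}: invalid value")
        for g in self.groups:
            if g not in PRESETS:
                raise ValueError(f"config field 'groups': unknown group {g!r}")
        for key in ("bpm_start", "bpm_end", "bpm_step", "beats_per_step"):
            if key not in self.ramp:
                raise ValueError(f"config field 'ramp.{key}': missing")
        for key in ("gaussian_sd", "drift_slope"):
            if key not in self.noise:
                raise ValueError(f"config field 'noise.{key}': missing")
        for d in self.drugs:
            if d not in DRUGS:
                raise ValueError(f"config field 'drugs': unknown drug {d!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config fields unknown: {sorted(unknown)}")
        for key in ("groups", "drugs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["groups"] = list(self.groups)
        data["drugs"] = list(self.drugs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def design(self, seed_noise: int = 0) -> CohortDesign:
        return CohortDesign(
            n_wells=self.n_wells,
            groups=self.groups,
            well_cv=self.well_cv,
            recording_cv=self.recording_cv,
            frame_rate=self.frame_rate,
            pacing_hz=self.screen_pacing_hz,
            n_beats=self.baseline_n_beats,
            noise=NoiseModel(seed=seed_noise, **self.noise),
        )


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_baseline(config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline phenotyping: per-beat metrics of every well at 1 Hz."""
    design = config.design()
    frames = []
    for group in config.groups:
        preset = PRESETS[group]
        for w in range(config.n_wells):
            well_scale = float(np.exp(rng.normal(0.0, config.well_cv)))
            params = _scale_params(preset, well_scale)
            df = simulate_well_recording(
                params, rng, design, pacing_hz=config.baseline_pacing_hz
            )
            df["group"] = group
            df["well"] = f"{group[0]}CM-{w + 1}"
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_baseline(metrics: pd.DataFrame) -> pd.DataFrame:
    """Well-mean metrics, group mean ± SEM, and between-group Welch tests."""
    value_cols = [
        c for c in ("apd20", "apd50", "apd80", "apd90",
                    "catd20", "catd50", "catd80", "ttp", "tau")
        if c in metrics.columns
    ]
    ok = metrics[~metrics["truncated"]]
    well_means = ok.groupby(["group", "well"])[value_cols].mean().reset_index()
    rows = []
    groups = sorted(well_means["group"].unique())
    for metric in value_cols:
        row: dict = {"metric": metric}
        for g in groups:
            vals = well_means.loc[well_means["group"] == g, metric].dropna()
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sem"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            row[f"{g}_n"] = len(vals)
        if len(groups) == 2:
            a = well_means.loc[well_means["group"] == groups[0], metric].dropna()
            b = well_means.loc[well_means["group"] == groups[1], metric].dropna()
            res = welch_ttest(a, b, label=metric)
            row["t"] = res.statistic
            row["p"] = res.pvalue
            row["stars"] = res.stars
        rows.append(row)
    return pd.DataFrame(rows)


def run_restitution(config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ramp-pacing restitution per well: fitted curve and maximum slope."""
    ramp = config.ramp
    protocol = PacingProtocol.ramp(
        ramp["bpm_start"], ramp["bpm_end"], ramp["bpm_step"], ramp["beats_per_step"]
    )
    duration = protocol.end_time(1000.0)
    rows = []
    for group in config.groups:
        preset = PRESETS[group]
        rest = PRESET_RESTITUTION[group]
        for w in range(config.restitution_wells):
            well_scale = float(np.exp(rng.normal(0.0, config.well_cv)))
            params = _scale_params(preset, well_scale)
            rec = generate_ap_trace(
                params, protocol, config.frame_rate, duration, restitution=rest
            )
            noise = NoiseModel(seed=int(rng.integers(2**31)), **config.noise)
            tr = condition(
                add_noise(rec.trace, noise),
                polarity="positive",
                detrend_method=config.detrend_method,
                detrend_window_ms=2000.0,
            )
            beats = detect_beats(
                tr, protocol, activation_convention=config.activation_convention
            )
            metrics = measure_beats(tr, beats)
            points = compute_di(metrics, protocol, ramp.get("discard_per_step", 2))
            curve = fit_restitution(points)
            rows.append(
                {
                    "group": group,
                    "well": f"{group[0]}CM-{w + 1}",
                    "n_points": len(curve.points),
                    "di_min": curve.points["di"].min(),
                    "a": curve.a,
                    "b": curve.b,
                    "c": curve.c,
                    "max_slope": curve.max_slope,
                    "fit_rmse": curve.fit_rmse,
                    "method": curve.method,
                }
            )
    return pd.DataFrame(rows)


def run_screens(
    config: RunConfig, rngs: list[np.random.Generator]
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Simulate and analyze every configured drug screen."""
    from .cohort import simulate_screen

    tables = {}
    for drug_name, rng in zip(config.drugs, rngs):
        design = config.design(seed_noise=int(rng.integers(2**31)))
        table = simulate_screen(
            DRUGS[drug_name], design, seed=int(rng.integers(2**31))
        )
        tables[drug_name] = add_percent_change(table)
    report, text = assemble_screen_report(tables, variant=config.ttest_variant)
    tidy = pd.concat(tables.values(), ignore_index=True)
    return tidy, report, text


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; write tables, log, and config echo.

    Returns the result bundle as a dict of DataFrames/paths.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_base, rng_rest, *rng_screens = _rng_children(
        config.seed, 2 + max(len(config.drugs), 1)
    )

    baseline = run_baseline(config, rng_base)
    baseline_summary = summarize_baseline(baseline)
    restitution = run_restitution(config, rng_rest)
    screens_tidy, screens_report, screens_text = run_screens(config, rng_screens)

    baseline.to_csv(out / "beat_metrics.csv", index=False)
    baseline_summary.to_csv(out / "baseline_groups.csv", index=False)
    restitution.to_csv(out / "restitution.csv", index=False)
    screens_tidy.to_csv(out / "dose_tables.csv", index=False)
    screens_report.to_csv(out / "dose_response.csv", index=False)
    (out / "screen_report.txt").write_text(screens_text + "\n")
    config.to_yaml(out / "config_echo.yaml")
    (out / "run_log.txt").write_text(
        f"cardiomap {__version__}\n"
        f"python {platform.python_version()}  numpy {np.__version__}  "
        f"pandas {pd.__version__}\nseed {config.seed}\n"
    )
    return {
        "baseline": baseline,
        "baseline_summary": baseline_summary,
        "restitution": restitution,
        "screens": screens_tidy,
        "report": screens_report,
        "out_dir": out,
    }


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> dict[str, Path]:
    """Write the canonical test fixture set.

    Noiseless atrial/ventricular AP and CaT traces, a noisy rendered movie,
    a ramp (restitution) recording, and three 4-dose screens (prolonging,
    shortening, null), each with its ground-truth manifest.
    """
    from .cohort import simulate_screen, DOFETILIDE_LIKE

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _rng_children(seed, 4)
    paths: dict[str, Path] = {}

    prot1 = PacingProtocol.fixed(1.0, 8, start_ms=100.0)
    prot_cat = PacingProtocol.fixed(0.4, 4, start_ms=100.0)
    for label, preset in (("atrial", ATRIAL), ("ventricular", VENTRICULAR)):
        ap = generate_ap_trace(preset, prot1, 100.0, 9000.0)
        cat = generate_cat_trace(preset, prot_cat, 100.0, 10_000.0)
        paths[f"{label}_ap"] = write_trace(ap.trace, out / f"{label}_ap.csv")
        ap.manifest.to_csv(out / f"{label}_ap_manifest.csv", index=False)
        paths[f"{label}_cat"] = write_trace(cat.trace, out / f"{label}_cat.csv")
        cat.manifest.to_csv(out / f"{label}_cat_manifest.csv", index=False)

    ap = generate_ap_trace(ATRIAL, prot1, 100.0, 9000.0)
    cat = generate_cat_trace(ATRIAL, prot1, 100.0, 9000.0)
    # offset sized so the inverted voltage channel stays on-scale in uint16
    spec = MovieSpec(height=16, width=16, gain=15000.0, offset=12000.0)
    movie, manifest = render_movie(
        ap.trace, cat.trace, spec, NoiseModel(seed=int(rngs[0].integers(2**31)))
    )
    paths["movie"] = write_movie(
        out / "demo_movie.tif", movie, manifest,
        ground_truth={"voltage": ap.manifest, "calcium": cat.manifest},
    )

    ramp = PacingProtocol.ramp()
    rec = generate_ap_trace(
        ATRIAL, ramp, 100.0, ramp.end_time(1000.0),
        restitution=PRESET_RESTITUTION["atrial"],
    )
    paths["ramp"] = write_trace(rec.trace, out / "atrial_ramp.csv")
    rec.manifest.to_csv(out / "atrial_ramp_manifest.csv", index=False)

    design = CohortDesign(n_wells=3)
    for drug, rng in zip((DOFETILIDE_LIKE, NIFEDIPINE_LIKE, NULL_DRUG), rngs[1:]):
        table = simulate_screen(drug, design, seed=int(rng.integers(2**31)))
        path = out / f"screen_{drug.name}.csv"
        table.to_csv(path, index=False)
        paths[f"screen_{drug.name}"] = path
    return paths
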