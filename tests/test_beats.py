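"""Beat segmentation and per-beat metrics: geometric oracles, closed-form
exponentials, manifest recovery, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.beats import (
    apd,
    beating_rate,
    catd,
    decay_tau,
    detect_beats,
    measure_beats,
    time_to_peak,
    upstroke_and_rest,
)
from cardiomap.protocols import PacingProtocol
from cardiomap.synth import ATRIAL, VENTRICULAR, generate_ap_trace, generate_cat_trace
from cardiomap.trace import Trace

from conftest import aligned_errors, make_trace


def _single_beat(values, dt=10.0, stim_ms=None, channel="voltage"):
    """One-beat trace plus its detected Beat."""
    tr = make_trace(values, dt=dt, channel=channel)
    stim = stim_ms if stim_ms is not None else 50.0
    prot = PacingProtocol("fixed", stimulus_times=np.array([stim]))
    beats = detect_beats(tr, prot)
    assert len(beats) == 1
    return tr, beats[0]


def square_pulse(width_ms, dt=10.0, start_ms=500.0, total_ms=3000.0, channel="voltage"):
    n = int(total_ms / dt)
    y = np.zeros(n)
    i0, i1 = int(start_ms / dt), int((start_ms + width_ms) / dt)
    y[i0:i1] = 1.0
    return _single_beat(y, dt=dt, stim_ms=start_ms - 20.0, channel=channel)


class TestApd:
    def test_square_pulse_is_level_independent(self):
        tr, beat = square_pulse(300.0)
        vals = [apd(tr, beat, pct) for pct in (20, 50, 80, 90)]
        for v in vals:
            assert v == pytest.approx(300.0, abs=10.0)  # within one sample
        assert max(vals) - min(vals) <= 10.0

    def test_triangular_ap_has_linear_level_geometry(self):
        """Instant upstroke + 400 ms linear repolarization: APDx = 4x ms."""
        dt = 1.0
        t = np.arange(0, 3000, dt)
        y = np.where((t >= 500) & (t < 900), np.clip(1.0 - (t - 500) / 400.0, 0, 1), 0.0)
        tr, beat = _single_beat(y, dt=dt, stim_ms=480.0)
        assert apd(tr, beat, 20) == pytest.approx(80.0, abs=1.0)
        assert apd(tr, beat, 50) == pytest.approx(200.0, abs=1.0)
        assert apd(tr, beat, 80) == pytest.approx(320.0, abs=1.0)

    def test_undefined_when_repolarization_incomplete(self):
        y = np.zeros(200)
        y[50:] = 1.0  # never comes back down
        tr, beat = _single_beat(y, stim_ms=480.0)
        assert np.isnan(apd(tr, beat, 80))

    def test_invalid_level_rejected(self):
        tr, beat = square_pulse(300.0)
        with pytest.raises(ValueError):
            apd(tr, beat, 0)


class TestCatd:
    def test_square_ca_pulse_level_independent(self):
        tr, beat = square_pulse(500.0, channel="calcium")
        for pct in (20, 50, 80):
            assert catd(tr, beat, pct) == pytest.approx(500.0, abs=10.0)

    def test_exponential_decay_closed_form(self):
        """Instant rise, τ=300 ms decay: CaTD50 = 300·ln2, CaTD80 = 300·ln5."""
        dt = 0.1
        t = np.arange(0, 3000, dt)
        y = np.where(t >= 500, np.exp(-(t - 500) / 300.0), 0.0)
        tr, beat = _single_beat(y, dt=dt, stim_ms=495.0, channel="calcium")
        assert catd(tr, beat, 50) == pytest.approx(300 * np.log(2), abs=0.3)
        assert catd(tr, beat, 80) == pytest.approx(300 * np.log(5), abs=0.3)


class TestTimeToPeak:
    def test_linear_rise_measured_from_10pct_onset(self):
        """100 ms linear rise: onset at 10% ⇒ TTP = 90 ms."""
        dt = 1.0
        t = np.arange(0, 2000, dt)
        y = np.where(t < 500, 0.0, np.where(t < 600, (t - 500) / 100.0,
                     np.exp(-(t - 600) / 250.0)))
        tr, beat = _single_beat(y, dt=dt, stim_ms=490.0, channel="calcium")
        assert time_to_peak(tr, beat) == pytest.approx(90.0, abs=1.0)

    def test_square_pulse_ttp_within_one_sample(self):
        tr, beat = square_pulse(500.0, channel="calcium")
        assert time_to_peak(tr, beat) == pytest.approx(0.0, abs=10.0)


class TestDecayTau:
    def _exp_beat(self, tau, dt=10.0, noise_sd=0.0, rng=None):
        t = np.arange(0, 6000, dt)
        y = np.where(t >= 500, np.exp(-(t - 500) / tau), 0.0)
        rise = (t >= 480) & (t < 500)
        y[rise] = (t[rise] - 480) / 20.0
        if noise_sd:
            y = y + rng.normal(0.0, noise_sd, y.size)
        return _single_beat(y, dt=dt, stim_ms=470.0, channel="calcium")

    @pytest.mark.parametrize("tau", [350.0, 671.0])
    def test_noiseless_exponential_recovered_within_1pct(self, tau):
        tr, beat = self._exp_beat(tau)
        fit, rmse = decay_tau(tr, beat)
        assert fit == pytest.approx(tau, rel=0.01)
        assert rmse < 1e-6

    def test_mean_tau_under_noise_within_3pct(self):
        """5% amplitude Gaussian noise, 100 replicate beats."""
        rng = np.random.default_rng(11)
        fits = []
        for _ in range(100):
            tr, beat = self._exp_beat(350.0, noise_sd=0.05, rng=rng)
            fit, _ = decay_tau(tr, beat)
            if np.isfinite(fit):
                fits.append(fit)
        assert len(fits) >= 95
        assert np.mean(fits) == pytest.approx(350.0, rel=0.03)

    def test_too_short_segment_flagged_undefined(self):
        tr, beat = self._exp_beat(350.0)
        fit, rmse = decay_tau(tr, beat, min_samples=1000)
        assert np.isnan(fit) and "undefined_tau" in beat.flags


class TestUpstrokeAndRest:
    def test_linear_ramp_upstroke_slope(self):
        dt = 10.0
        t = np.arange(0, 3000, dt)
        y = np.where(t < 500, 0.0, np.where(t < 700, (t - 500) * 0.005,
                     np.maximum(1.0 - (t - 700) / 400.0, 0.0)))
        tr, beat = _single_beat(y, dt=dt, stim_ms=490.0)
        max_up, rest = upstroke_and_rest(tr, beat)
        assert max_up == pytest.approx(0.005, rel=1e-6)
        assert rest == pytest.approx(0.0, abs=1e-12)

    def test_synth_max_derivative_at_manifest_activation(self, ap_recordings,
                                                         measured_ap):
        for label in ("atrial", "ventricular"):
            man = ap_recordings[label].manifest
            df = measured_ap[label]
            ok = ~df["truncated"]
            err = np.abs(
                df.loc[ok, "activation_time"].to_numpy()[: len(man)]
                - man["activation_time"].to_numpy()[: int(ok.sum())]
            )
            assert err.max() < 10.0  # within one sample at 100 fps


class TestDetection:
    def test_one_beat_per_stimulus(self, ap_recordings, protocol_1hz, measured_ap):
        df = measured_ap["atrial"]
        assert len(df) == protocol_1hz.n_stimuli

    def test_flat_trace_yields_no_beats(self):
        tr = make_trace(np.zeros(500))
        prot = PacingProtocol.fixed(1.0, 4, start_ms=100.0)
        assert detect_beats(tr, prot) == []

    def test_spontaneous_detection_matches_known_event_times(self):
        prot = PacingProtocol.fixed(0.8, 6, start_ms=300.0)
        rec = generate_ap_trace(ATRIAL, prot, 100.0, 8000.0)
        found = detect_beats(rec.trace, PacingProtocol.spontaneous())
        acts = [b.activation_time for b in found if not b.truncated]
        man = rec.manifest[~rec.manifest.truncated]
        assert len(acts) >= len(man) - 1
        for a, m in zip(acts, man.activation_time):
            assert a == pytest.approx(m, abs=10.0)  # within one sample

    def test_truncated_final_beat_flagged(self):
        prot = PacingProtocol.fixed(1.0, 10, start_ms=100.0)  # last window cut
        rec = generate_ap_trace(ATRIAL, prot, 100.0, 10_000.0)
        df = measure_beats(rec.trace, detect_beats(rec.trace, prot))
        assert df["truncated"].iloc[-1]
        assert np.isnan(df["apd80"].iloc[-1])


class TestBeatingRate:
    @pytest.mark.parametrize("cl_ms,expected", [(1000.0, 60.0), (500.0, 120.0)])
    def test_fixed_interval_rates(self, cl_ms, expected):
        beats = detect_beats(
            *(lambda p: (generate_ap_trace(ATRIAL, p, 100.0, 6000.0).trace, p))(
                PacingProtocol("fixed",
                               stimulus_times=100.0 + cl_ms * np.arange(5))
            )
        )
        assert beating_rate(beats) == pytest.approx(expected, rel=0.01)

    def test_fewer_than_two_beats_undefined(self):
        assert np.isnan(beating_rate([]))


class TestManifestRecovery:
    """Noiseless duration metrics within 2 ms of the 0.01 ms-grid oracle at
    100 fps, and within 0.2 ms at 1000 fps."""

    AP = ("apd20", "apd50", "apd80", "apd90")
    CAT = ("catd20", "catd50", "catd80", "ttp")

    def test_ap_recovery_100fps(self, ap_recordings, measured_ap):
        for label in ("atrial", "ventricular"):
            errs = aligned_errors(
                measured_ap[label], ap_recordings[label].manifest, self.AP
            )
            assert max(errs.values()) < 2.0, errs

    def test_cat_recovery_100fps(self, cat_recordings, measured_cat):
        for label in ("atrial", "ventricular"):
            errs = aligned_errors(
                measured_cat[label], cat_recordings[label].manifest, self.CAT
            )
            assert max(errs.values()) < 2.0, errs
            tau_errs = aligned_errors(
                measured_cat[label], cat_recordings[label].manifest, ("tau",)
            )
            truth = cat_recordings[label].manifest["tau"].iloc[0]
            assert tau_errs["tau"] < 0.01 * truth

    def test_ap_recovery_1000fps(self):
        prot = PacingProtocol.fixed(1.0, 4, start_ms=100.0)
        for preset in (ATRIAL, VENTRICULAR):
            rec = generate_ap_trace(preset, prot, 1000.0, 5000.0)
            df = measure_beats(rec.trace, detect_beats(rec.trace, prot))
            errs = aligned_errors(df, rec.manifest, self.AP)
            assert max(errs.values()) < 0.2, errs

    def test_level_monotonicity_across_suite(self, measured_ap, measured_cat):
        for df in measured_ap.values():
            ok = df[~df["truncated"]]
            assert (ok.apd20 <= ok.apd50 + 1e-9).all()
            assert (ok.apd50 <= ok.apd80 + 1e-9).all()
            assert (ok.apd80 <= ok.apd90 + 1e-9).all()
        for df in measured_cat.values():
            ok = df[~df["truncated"]]
            assert (ok.catd20 <= ok.catd50 + 1e-9).all()
            assert (ok.catd50 <= ok.catd80 + 1e-9).all()
            assert (ok.ttp < ok.catd80).all()


class TestInvariances:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(a=st.floats(0.2, 20.0), b=st.floats(-50.0, 50.0))
    def test_metrics_invariant_to_positive_affine_values(self, a, b):
        prot = PacingProtocol.fixed(1.0, 4, start_ms=100.0)
        rec = generate_ap_trace(ATRIAL, prot, 100.0, 5000.0)
        ref = measure_beats(rec.trace, detect_beats(rec.trace, prot))
        scaled_tr = rec.trace.with_values(a * rec.trace.values + b)
        scaled = measure_beats(scaled_tr, detect_beats(scaled_tr, prot))
        for m in ("apd20", "apd50", "apd80", "apd90"):
            assert np.allclose(
                ref[m].dropna(), scaled[m].dropna(), atol=1e-6
            )

    def test_metrics_invariant_to_time_shift(self):
        shift = 700.0
        p0 = PacingProtocol.fixed(1.0, 4, start_ms=100.0)
        p1 = PacingProtocol.fixed(1.0, 4, start_ms=100.0 + shift)
        r0 = generate_ap_trace(ATRIAL, p0, 100.0, 5000.0)
        r1 = generate_ap_trace(ATRIAL, p1, 100.0, 5000.0 + shift)
        d0 = measure_beats(r0.trace, detect_beats(r0.trace, p0))
        d1 = measure_beats(r1.trace, detect_beats(r1.trace, p1))
        for m in ("apd20", "apd80"):
            assert np.allclose(d0[m].dropna(), d1[m].dropna(), atol=1e-6)
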