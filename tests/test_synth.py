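"""Synthetic generator: waveform identities, manifest oracle, drug model,
noise/rendering determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.protocols import PacingProtocol
from cardiomap.synth import (
    ATRIAL,
    VENTRICULAR,
    CellTypeParams,
    DrugModel,
    HillEffect,
    MovieSpec,
    NoiseModel,
    RestitutionParams,
    add_noise,
    apply_drug_effect,
    generate_ap_trace,
    generate_cat_trace,
    render_movie,
)
from dataclasses import replace


PROT = PacingProtocol.fixed(1.0, 5, start_ms=100.0)


class TestWaveforms:
    def test_zero_amplitude_gives_flat_trace(self):
        flat = replace(ATRIAL, amplitude=0.0, resting_level=0.3)
        for gen in (generate_ap_trace, generate_cat_trace):
            rec = gen(flat, PROT, 100.0, 6000.0)
            assert np.all(rec.trace.values == 0.3)

    def test_stimuli_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            generate_ap_trace(ATRIAL, PROT, 100.0, 2000.0)

    def test_one_beat_per_stimulus_in_manifest(self):
        rec = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0)
        assert len(rec.manifest) == PROT.n_stimuli

    def test_manifest_apd_levels_are_monotone(self):
        for preset in (ATRIAL, VENTRICULAR):
            man = generate_ap_trace(preset, PROT, 100.0, 6000.0).manifest
            assert (man.apd20 <= man.apd50).all()
            assert (man.apd50 <= man.apd80).all()
            assert (man.apd80 <= man.apd90).all()

    def test_preset_apd80_matches_optical_phenotype(self):
        """Atrial ≈179 ms and ventricular ≈251 ms true APD80."""
        a = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0).manifest.apd80.iloc[0]
        v = generate_ap_trace(VENTRICULAR, PROT, 100.0, 6000.0).manifest.apd80.iloc[0]
        assert a == pytest.approx(179.0, abs=0.5)
        assert v == pytest.approx(251.0, abs=0.5)

    def test_cat_manifest_tau_and_ttp_exact(self):
        man = generate_cat_trace(ATRIAL, PROT, 100.0, 6000.0).manifest
        assert man.tau.iloc[0] == 350.0
        assert man.ttp.iloc[0] == pytest.approx(116.0, abs=0.02)

    def test_atrial_shorter_than_ventricular_everywhere(self):
        ma = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0).manifest
        mv = generate_ap_trace(VENTRICULAR, PROT, 100.0, 6000.0).manifest
        ca = generate_cat_trace(ATRIAL, PROT, 100.0, 6000.0).manifest
        cv = generate_cat_trace(VENTRICULAR, PROT, 100.0, 6000.0).manifest
        for m in ("apd20", "apd50", "apd80"):
            assert ma[m].iloc[0] < mv[m].iloc[0]
        for m in ("ttp", "tau", "catd20", "catd50", "catd80"):
            assert ca[m].iloc[0] < cv[m].iloc[0]
        assert ATRIAL.ap_plateau_fraction < VENTRICULAR.ap_plateau_fraction

    def test_cat_closed_form_recovery_crossings(self):
        """Manifest CaTD agrees with the closed form of the exponential decay."""
        man = generate_cat_trace(ATRIAL, PROT, 100.0, 6000.0).manifest
        tau, ttp = 350.0, 116.0
        assert man.catd50.iloc[0] == pytest.approx(ttp + tau * np.log(2), abs=0.05)
        assert man.catd80.iloc[0] == pytest.approx(ttp + tau * np.log(5), abs=0.05)

    def test_overlap_flagged_not_raised(self):
        fast = PacingProtocol.fixed(4.0, 8, start_ms=100.0)
        rec = generate_ap_trace(VENTRICULAR, fast, 100.0, 2500.0)
        assert rec.manifest.overlap.iloc[2:].all()

    def test_restitution_scales_true_apd80_to_map(self):
        rest = RestitutionParams(a=200.0, b=100.0, c=120.0)
        prot = PacingProtocol.fixed(1.0, 6, start_ms=100.0)
        man = generate_ap_trace(ATRIAL, prot, 100.0, 7000.0, restitution=rest).manifest
        for k in range(1, len(man)):
            di = man.cycle_length[k] - man.apd80[k - 1]
            assert man.apd80[k] == pytest.approx(rest.apd80(di), abs=0.1)


class TestDrugModel:
    DRUG = DrugModel("test", {"ap_repol_tau": HillEffect(emax=0.5, ec50=10.0)})

    def test_zero_dose_is_identity(self):
        assert apply_drug_effect(ATRIAL, self.DRUG, 0.0) == ATRIAL

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            apply_drug_effect(ATRIAL, self.DRUG, -1.0)

    def test_hill_midpoint_scaling(self):
        dosed = apply_drug_effect(ATRIAL, self.DRUG, 10.0)
        assert dosed.ap_repol_tau == pytest.approx(ATRIAL.ap_repol_tau * 1.25)

    def test_untargeted_parameters_unchanged(self):
        dosed = apply_drug_effect(ATRIAL, self.DRUG, 10.0)
        assert dosed.cat_decay_tau == ATRIAL.cat_decay_tau
        assert dosed.ap_plateau_dur == ATRIAL.ap_plateau_dur

    @settings(derandomize=True, max_examples=25)
    @given(
        emax=st.floats(-0.8, 2.0),
        ec50=st.floats(0.1, 100.0),
        hill_n=st.floats(0.5, 4.0),
    )
    def test_hill_saturation_approaches_emax(self, emax, ec50, hill_n):
        eff = HillEffect(emax=emax, ec50=ec50, hill_n=hill_n)
        assert eff.fraction(0.0) == 0.0
        sat = eff.fraction(1e6 * ec50)
        assert sat == pytest.approx(emax, rel=0.01, abs=1e-9)

    def test_large_dose_within_1pct_of_emax(self):
        eff = HillEffect(emax=0.5, ec50=5.0, hill_n=1.0)
        assert 1.0 + eff.fraction(500.0) == pytest.approx(1.5, rel=0.01)


class TestNoiseAndRendering:
    def test_seeded_noise_is_reproducible(self):
        rec = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0)
        noise = NoiseModel(gaussian_sd=0.05, drift_slope=0.01, seed=42)
        a = add_noise(rec.trace, noise)
        b = add_noise(rec.trace, noise)
        assert np.array_equal(a.values, b.values)
        c = add_noise(rec.trace, NoiseModel(0.05, 0.01, seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_changing_seed_changes_only_noise(self):
        rec = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0)
        a = add_noise(rec.trace, NoiseModel(0.0, 0.01, seed=1))
        b = add_noise(rec.trace, NoiseModel(0.0, 0.01, seed=2))
        # drift-only output is seed independent
        assert np.allclose(a.values, b.values)

    def _traces(self):
        ap = generate_ap_trace(ATRIAL, PROT, 100.0, 6000.0)
        cat = generate_cat_trace(ATRIAL, PROT, 100.0, 6000.0)
        return ap.trace, cat.trace

    def test_identity_rendering_roundtrip(self):
        v, ca = self._traces()
        spec = MovieSpec(height=4, width=5, gain=1.0, offset=0.0,
                         voltage_polarity="positive")
        movie, manifest = render_movie(v, ca, spec)
        roi_v = movie[0::2].mean(axis=(1, 2))
        roi_ca = movie[1::2].mean(axis=(1, 2))
        assert np.allclose(roi_v, v.values, atol=1e-12)
        assert np.allclose(roi_ca, ca.values, atol=1e-12)

    def test_frame_count_at_100fps(self):
        """10 s at 100 frames/s gives 1000 frames per channel."""
        prot = PacingProtocol.fixed(1.0, 9, start_ms=100.0)
        v = generate_ap_trace(ATRIAL, prot, 100.0, 10_000.0).trace
        ca = generate_cat_trace(ATRIAL, prot, 100.0, 10_000.0).trace
        assert len(v) == 1000
        movie, manifest = render_movie(v, ca, MovieSpec())
        assert movie.shape[0] == 2000
        assert manifest["n_frames_per_channel"] == 1000

    def test_inverted_polarity_negates_about_baseline(self):
        v, ca = self._traces()
        spec = MovieSpec(height=2, width=2, voltage_polarity="inverted",
                         gain=1.0, offset=0.0)
        movie, _ = render_movie(v, ca, spec)
        roi_v = movie[0::2].mean(axis=(1, 2))
        assert np.allclose(roi_v, 2.0 * v.values.mean() - v.values, atol=1e-12)

    def test_render_is_bit_identical_under_fixed_seed(self):
        v, ca = self._traces()
        spec = MovieSpec(height=3, width=3)
        m1, _ = render_movie(v, ca, spec, NoiseModel(seed=7))
        m2, _ = render_movie(v, ca, spec, NoiseModel(seed=7))
        assert np.array_equal(m1, m2)

    def test_mismatched_traces_rejected(self):
        v, ca = self._traces()
        short = generate_cat_trace(ATRIAL, PROT, 100.0, 5000.0).trace
        with pytest.raises(ValueError, match="length"):
            render_movie(v, short, MovieSpec())


class TestParamValidation:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            replace(ATRIAL, ap_repol_tau=-1.0)
        with pytest.raises(ValueError):
            replace(ATRIAL, ap_plateau_fraction=1.5)
        with pytest.raises(ValueError):
            HillEffect(emax=0.5, ec50=-1.0)
        with pytest.raises(ValueError):
            RestitutionParams(a=100.0, b=10.0, c=0.0)
        with pytest.raises(ValueError):
            DrugModel("x", {"not_a_param": HillEffect(0.1, 1.0)})
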