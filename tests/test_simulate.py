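"""Synthetic generator: presets, breathing, beat dynamics, determinism, cohorts."""

import numpy as np
import pytest

from cardioresp.io import RespSeries
from cardioresp.protocol import Phase, default_protocol
from cardioresp.simulate import (
    COHORT_SIZES,
    TypePreset,
    generate_beats,
    generate_breathing,
    generate_cohort,
    generate_recording,
    make_preset,
)


class TestPresets:
    def test_type_iv_band_targets(self, presets):
        p = presets["IV"]
        assert (p.target_vlf, p.target_lf, p.target_hf) == (1024, 4487, 5789)

    def test_type_i_baroreflex_gain(self, presets):
        assert presets["I"].alpha_lf == 11.29

    def test_mean_rr_from_heart_rate(self, presets):
        assert presets["I"].mean_rr == pytest.approx(60000.0 / 74.1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown HRR type"):
            make_preset("V")

    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            TypePreset("X", 800, -1, 100, 100, None, 115, 75, 10, 12, 65, 14,
                       0.5, 1.5, 1.0)


class TestBreathing:
    def test_paced_cr6_gives_12_breaths_of_10s(self, presets):
        br = generate_breathing(Phase("CR6", 120.0, 5.0, 5.0), presets["I"], seed=0)
        assert len(br) == 12
        assert np.allclose(br.ti, 5.0) and np.allclose(br.te, 5.0)

    def test_paced_cr15_gives_30_breaths_of_4s(self, presets):
        br = generate_breathing(Phase("CR15", 120.0, 2.0, 2.0), presets["I"], seed=0)
        assert len(br) == 30
        assert np.allclose(br.ti + br.te, 4.0)

    def test_minute_ventilation_identity(self, presets):
        # V_E = mean(VT) x RR holds exactly by construction
        br = generate_breathing(Phase("SR", 120.0), presets["II"], seed=1)
        assert br.minute_ventilation() == pytest.approx(np.mean(br.vt) * br.minute_rate())

    def test_spontaneous_rate_near_preset(self, presets):
        rates = [
            generate_breathing(Phase("SR", 120.0), presets["III"], seed=s).minute_rate()
            for s in range(10)
        ]
        assert np.median(rates) == pytest.approx(presets["III"].resp_rate_sr, rel=0.06)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            Phase("SR", -5.0)

    def test_phase_shorter_than_breath_cycle_rejected(self, presets):
        with pytest.raises(ValueError, match="one breath cycle"):
            generate_breathing(Phase("SR", 2.0), presets["I"], seed=0)


class TestBeats:
    def test_single_sinusoid_tachogram_variance(self):
        # uncalibrated minimal preset: one 0.1 Hz component of amplitude 20 ms
        # -> variance A^2/2 = 200 ms^2
        p = TypePreset("X", 800.0, 1e-6, 200.0, 1e-6, None, 115, 75, 10.0, 12.0,
                       65.0, 15.0, 0.5, 1.5, 1.0, noise_sd=0.0)
        br = RespSeries(np.arange(0, 120, 4.0), np.full(30, 1.8), np.full(30, 2.2),
                        np.full(30, 0.5))
        beats = generate_beats(p, br, seed=0)
        assert np.var(beats.rr) == pytest.approx(200.0, rel=0.05)

    def test_sbp_oscillation_scaled_by_gain(self):
        # alpha_lf = 10 and A_LF = 20 ms -> SBP LF amplitude 2 mmHg
        p = TypePreset("X", 800.0, 1e-6, 200.0, 1e-6, None, 115, 75, 10.0, 12.0,
                       65.0, 15.0, 0.5, 1.5, 1.0, noise_sd=0.0, sbp_noise_sd=0.0)
        br = RespSeries(np.arange(0, 120, 4.0), np.full(30, 1.8), np.full(30, 2.2),
                        np.full(30, 0.5))
        beats = generate_beats(p, br, seed=0)
        lf_amp = (beats.sbp.max() - beats.sbp.min()) / 2
        # SBP carries the 0.1 Hz component at A/alpha plus the (negligible) HF term
        assert lf_amp == pytest.approx(2.0, rel=0.05)

    def test_same_seed_bit_identical(self, presets):
        a = generate_recording(presets["II"], seed=7)
        b = generate_recording(presets["II"], seed=7)
        assert np.array_equal(a.beats.t, b.beats.t)
        assert np.array_equal(a.beats.rr, b.beats.rr)
        assert np.array_equal(a.beats.sbp, b.beats.sbp)
        assert np.array_equal(a.breaths.vt, b.breaths.vt)

    def test_different_seeds_differ(self, presets):
        a = generate_recording(presets["II"], seed=7)
        b = generate_recording(presets["II"], seed=8)
        assert not np.array_equal(a.beats.rr, b.beats.rr)

    def test_breaths_must_cover_duration(self, presets):
        br = generate_breathing(Phase("CR6", 60.0, 5.0, 5.0), presets["I"], seed=0)
        with pytest.raises(ValueError, match="cover"):
            generate_beats(presets["I"], br, seed=0, duration=120.0)


class TestRecordingAndCohort:
    def test_default_protocol_recording_structure(self, presets):
        rec = generate_recording(presets["I"], seed=0)
        assert [p[0] for p in rec.phases] == ["SR", "CR6", "CR15"]
        assert rec.phases[-1][2] == 360.0
        assert rec.beats.t[-1] - rec.beats.t[0] >= 355.0

    def test_published_cohort_sizes(self, default_cohort):
        assert len(default_cohort) == 183
        counts = {}
        for s in default_cohort:
            counts[s.hrr_type] = counts.get(s.hrr_type, 0) + 1
        assert counts == COHORT_SIZES

    def test_cohort_subject_regeneration_is_deterministic(self):
        a = generate_cohort({"I": 3}, seed=5)
        b = generate_cohort({"I": 3}, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.recording.beats.rr, y.recording.beats.rr)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort({"I": 0}, seed=1)
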