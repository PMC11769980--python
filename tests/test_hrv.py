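"""Time-domain, Baevsky and spectral HRV calculations against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioresp import hrv


class TestTimeDomain:
    def test_rmssd_hand_arithmetic(self):
        # diffs 10, -20, 20 -> sqrt((100+400+400)/3) = sqrt(300) = 17.3205
        td = hrv.time_domain([800, 810, 790, 810])
        assert td.rmssd == pytest.approx(17.3205, abs=1e-4)

    def test_pnn50_counts_large_differences(self):
        # diffs 60, 10, -70: two of three exceed 50 ms
        td = hrv.time_domain([800, 860, 870, 800])
        assert td.pnn50 == pytest.approx(100 * 2 / 3, abs=1e-9)

    def test_constant_series(self):
        td = hrv.time_domain([800.0] * 20)
        assert (td.rmssd, td.pnn50, td.hr) == (0.0, 0.0, 75.0)

    def test_hr_is_reciprocal_mean(self):
        td = hrv.time_domain([1000.0, 500.0])
        assert td.hr == pytest.approx(60000.0 / 750.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv.time_domain([800.0])


class TestStressIndex:
    def _sample(self):
        # 60 intervals at 780 ms (bin [750, 800), midpoint 775 -> Mo 0.775 s),
        # 40 spread out, extremes 650 and 950 -> MxDMn 0.3 s, AMo 60 %
        rr = [780.0] * 60 + [650.0] + [950.0] + [820.0] * 19 + [870.0] * 19
        return rr

    def test_hand_computed_value(self):
        g = hrv.stress_index(self._sample())
        assert g.mo == pytest.approx(0.775)
        assert g.amo == pytest.approx(60.0)
        assert g.mxdmn == pytest.approx(0.300)
        assert g.si == pytest.approx(60.0 / (2 * 0.775 * 0.300), rel=1e-12)

    def test_duplicating_sample_leaves_si_unchanged(self):
        rr = self._sample()
        assert hrv.stress_index(rr).si == pytest.approx(hrv.stress_index(rr * 2).si)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError, match="SI undefined"):
            hrv.stress_index([800.0] * 50)

    @pytest.mark.parametrize("spread", [50.0, 100.0, 200.0])
    def test_larger_dispersion_decreases_si(self, spread, rng):
        base = 800 + 30 * rng.standard_normal(300)
        wide = 800 + (30 + spread) * rng.standard_normal(300)
        assert hrv.stress_index(wide).si < hrv.stress_index(base).si


class TestResample:
    def _tach(self, values, dt=0.8):
        t = np.arange(len(values)) * dt
        return hrv.Tachogram(t, np.asarray(values))

    def test_constant_input_constant_output(self):
        v, fs = hrv.resample_tachogram(self._tach([800.0] * 120))
        assert np.allclose(v, 0.0, atol=1e-9)  # detrended constant is zero

    def test_linear_ramp_removed_by_detrend(self):
        v, fs = hrv.resample_tachogram(self._tach(800 + 0.5 * np.arange(120)))
        assert np.max(np.abs(v)) < 1e-6

    def test_sinusoid_amplitude_preserved(self):
        t = np.cumsum(np.full(150, 0.8))
        tach = hrv.Tachogram(t, 800 + 20 * np.sin(2 * np.pi * 0.1 * t))
        v, fs = hrv.resample_tachogram(tach)
        # RMS amplitude sqrt(2)*std survives resampling within 1 %
        assert np.sqrt(2.0) * np.std(v) == pytest.approx(20.0, rel=0.01)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            hrv.resample_tachogram(self._tach([800.0] * 40, dt=0.5))


class TestBandPowers:
    def test_pure_lf_sinusoid_power(self):
        fs = 4.0
        t = np.arange(0, 120, 1 / fs)
        bp = hrv.band_powers(20 * np.sin(2 * np.pi * 0.1 * t), fs=fs)
        assert bp.lf == pytest.approx(200.0, rel=0.05)  # A^2/2
        assert bp.hf < 0.01 * bp.lf

    def test_band_limited_noise_parseval(self, rng):
        # noise synthesized inside the analysis band: total power ~ variance
        fs = 4.0
        t = np.arange(0, 600, 1 / fs)
        freqs = rng.uniform(0.01, 0.39, 80)
        phases = rng.uniform(0, 2 * np.pi, 80)
        x = np.sum([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)], axis=0)
        bp = hrv.band_powers(x, fs=fs)
        assert bp.tp == pytest.approx(np.var(x), rel=0.10)

    @pytest.mark.parametrize("f,band", [(0.02, "vlf"), (0.1, "lf"), (0.25, "hf"), (0.35, "hf")])
    def test_frequency_localization(self, f, band):
        fs = 4.0
        t = np.arange(0, 120, 1 / fs)
        bp = hrv.band_powers(10 * np.sin(2 * np.pi * f * t), fs=fs)
        total = bp.vlf + bp.lf + bp.hf
        assert getattr(bp, band) / total >= 0.95

    def test_normalized_powers_sum_to_100(self, rng):
        x = rng.standard_normal(480)
        bp = hrv.band_powers(x, fs=4.0)
        assert bp.lfn + bp.hfn == pytest.approx(100.0, abs=1e-6)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            hrv.band_powers(np.zeros(100), fs=4.0)


@given(st.integers(0, 1000))
def test_spectral_analysis_is_pure(seed):
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(0.7, 1.0, 150))
    v = 800 + 30 * rng.standard_normal(150)
    tach = hrv.Tachogram(t, v)
    a = hrv.spectral_analysis(tach)
    b = hrv.spectral_analysis(tach)
    assert a == b
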