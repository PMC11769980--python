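"""Time-domain, geometric (Baevsky) and spectral heart-rate / blood-pressure
variability analysis.

Spectral analysis follows the conventional short-term HRV recipe: the
beat-value series (tachogram) is cubic-spline resampled onto a uniform grid
(default 4 Hz), linearly detrended, and its power spectral density estimated
by Welch's method (Hann window, 100 s segments, 50 % overlap).  Band powers
are trapezoid integrals of the PSD over the standard short-term bands

* VLF 0.0033–0.04 Hz,
* LF  0.04–0.15 Hz,
* HF  0.15–0.40 Hz,

with total power TP the integral over 0.0033–0.40 Hz.  Units follow the
input series: ms² for RR tachograms, mmHg² for beat-to-beat pressure.

The Baevsky stress index SI = AMo / (2·Mo·MxDMn) is computed from the RR
histogram with fixed 50 ms bins anchored at zero; Mo (modal-bin midpoint) and
MxDMn (RR range) enter in seconds, AMo in per cent, giving SI in the
conventional units (c.u.) of the 30/100 classification thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

#: Standard short-term band edges, Hz.
DEFAULT_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}
DEFAULT_FS = 4.0
DEFAULT_WELCH_WINDOW_S = 100.0
SI_BIN_MS = 50.0


@dataclass(frozen=True)
class TimeDomain:
    """Time-domain indices: mean RR (ms), heart rate (min⁻¹), RMSSD (ms), pNN50 (%)."""

    mean_rr: float
    hr: float
    rmssd: float
    pnn50: float


@dataclass(frozen=True)
class GeometricSI:
    """Baevsky histogram indices: Mo (s), AMo (%), MxDMn (s), SI (c.u.)."""

    mo: float
    amo: float
    mxdmn: float
    si: float


@dataclass(frozen=True)
class BandPowers:
    """Band powers (ms² or mmHg²), normalized powers (%), and the LF/HF ratio."""

    tp: float
    vlf: float
    lf: float
    hf: float
    lfn: float
    hfn: float
    lf_hf: float


@dataclass(frozen=True)
class Tachogram:
    """Beat-indexed value series: times (s, strictly increasing) and values
    (RR in ms, or SBP/DBP in mmHg)."""

    t: np.ndarray
    value: np.ndarray
    kind: str = "rr"  # rr | sbp | dbp

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if len(self.t) != len(self.value):
            raise ValueError("t and value lengths differ")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("tachogram times must be strictly increasing")


def time_domain(rr) -> TimeDomain:
    """Mean RR, HR, RMSSD and pNN50 from a list of RR intervals in ms.

    RMSSD is the root of the mean squared successive difference; pNN50 the
    percentage of successive-difference magnitudes exceeding 50 ms.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    d = np.diff(rr)
    mean_rr = float(np.mean(rr))
    return TimeDomain(
        mean_rr=mean_rr,
        hr=60000.0 / mean_rr,
        rmssd=float(np.sqrt(np.mean(d**2))),
        pnn50=100.0 * float(np.mean(np.abs(d) > 50.0)),
    )


def stress_index(rr, bin_width: float = SI_BIN_MS) -> GeometricSI:
    """Baevsky stress index from the RR histogram.

    Bins of ``bin_width`` ms are anchored at 0; Mo is the modal-bin midpoint
    (ties broken toward the slower bin), AMo the percentage of intervals in
    that bin, MxDMn the RR range.  All-identical input makes SI undefined.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    mxdmn_ms = float(np.max(rr) - np.min(rr))
    if mxdmn_ms == 0:
        raise ValueError("SI undefined: all RR intervals identical (MxDMn = 0)")
    idx = np.floor(rr / bin_width).astype(int)
    counts = np.bincount(idx - idx.min())
    modal = int(np.argmax(counts)) + idx.min()
    mo = (modal + 0.5) * bin_width / 1000.0
    amo = 100.0 * counts[modal - idx.min()] / rr.size
    mxdmn = mxdmn_ms / 1000.0
    return GeometricSI(mo=mo, amo=amo, mxdmn=mxdmn, si=amo / (2.0 * mo * mxdmn))


def resample_tachogram(tach: Tachogram, fs: float = DEFAULT_FS) -> tuple[np.ndarray, float]:
    """Cubic-spline resample onto a uniform grid at ``fs`` Hz and linearly detrend.

    Returns ``(values, fs)``.  Requires ≥ 30 beats spanning ≥ 60 s.
    """
    if len(tach.t) < 30:
        raise ValueError(f"need at least 30 points, got {len(tach.t)}")
    span = tach.t[-1] - tach.t[0]
    if span < 60.0:
        raise ValueError(f"tachogram span {span:.1f}s < 60s")
    grid = np.arange(tach.t[0], tach.t[-1], 1.0 / fs)
    spline = interpolate.CubicSpline(tach.t, tach.value)
    return signal.detrend(spline(grid), type="linear"), fs


def band_powers(values: np.ndarray, fs: float = DEFAULT_FS,
                bands: dict | None = None,
                window_s: float = DEFAULT_WELCH_WINDOW_S) -> BandPowers:
    """Welch band powers of a uniformly sampled, detrended series.

    PSD: Hann window of ``min(window_s, record length)`` seconds, 50 % overlap.
    Band powers are trapezoid integrals over the configured edges; TP spans
    the union of all bands; LFn/HFn normalize LF and HF to their sum.
    """
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    values = np.asarray(values, dtype=float)
    duration = values.size / fs
    if duration < 60.0:
        raise ValueError(f"record of {duration:.1f}s too short for spectral analysis")
    nperseg = min(int(round(window_s * fs)), values.size)
    f, psd = signal.welch(values, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend=False)

    def integrate(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], f[m]))

    vlf = integrate(*bands["vlf"])
    lf = integrate(*bands["lf"])
    hf = integrate(*bands["hf"])
    tp = integrate(bands["vlf"][0], bands["hf"][1])
    denom = lf + hf
    lfn = 100.0 * lf / denom if denom > 0 else float("nan")
    hfn = 100.0 * hf / denom if denom > 0 else float("nan")
    lf_hf = lf / hf if hf > 0 else float("inf")
    return BandPowers(tp=tp, vlf=vlf, lf=lf, hf=hf, lfn=lfn, hfn=hfn, lf_hf=lf_hf)


def spectral_analysis(tach: Tachogram, fs: float = DEFAULT_FS,
                      bands: dict | None = None) -> BandPowers:
    """Resample → detrend → Welch → integrate, in one call."""
    values, fs = resample_tachogram(tach, fs=fs)
    return band_powers(values, fs=fs, bands=bands)
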