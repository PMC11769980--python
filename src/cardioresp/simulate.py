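"""Synthetic baroreflex-coupled beat and breath series for the paced-breathing maneuver.

The generator produces beat-by-beat RR/SBP/DBP(/SV) and breath-by-breath
series with analytically controlled spectral content.  The RR series is a sum
of sinusoids plus white noise fed through an integrate-to-next-beat rule
(IPFM-like): beat times advance by the instantaneous RR interval,

    t_{k+1} = t_k + RR(t_k) / 1000,

    RR(t) = mean_rr + sat( x(t) ) + ε,          ε ~ N(0, noise_sd²)

    x(t) = c_vlf·A_VLF · sin(2π·0.025·t + φ_v)          (VLF)
         + g_lf · c_lf·A_LF · sin(2π·0.1·t + φ_lf)      (LF, Mayer wave)
         + g_rsa · c_hf·A_HF · sin(φ_resp(t))           (RSA)

with A = √(2·power target), so each component's nominal power (A²/2) equals
the requested band power.  Two refinements make the *measured* indices land
on the per-type profiles:

* ``sat(x) = S·tanh(x/S)`` — a saturating "rhythm clamp" that bounds RR
  excursions, emulating the bounded, mode-concentrated RR histograms of real
  records (a pure sinusoid sum is platykurtic and produces unrealistically
  low Baevsky stress-index values).  S is per type: tight for central
  (sympathicotonic) regulation, loose for autonomous predominance.
* calibration gains ``c_vlf, c_lf, c_hf`` — fixed multipliers solved once per
  type (deterministic internal seeds) so that the band powers *estimated by
  the analysis pipeline* match the targets; they absorb the systematic
  losses of detrending, windowing and saturation.  The VLF target rides on a
  single narrowband component at 0.025 Hz: on 2-min records any broader VLF
  realization has unresolvable inter-component beating and its estimate
  scatters severalfold.

The respiratory-sinus-arrhythmia phase φ_resp follows the breath-by-breath
instantaneous respiratory frequency (phase-continuous), so RSA energy lands
in the LF band during 6 min⁻¹ paced breathing and in the HF band during
spontaneous and 15 min⁻¹ breathing.

Systolic pressure carries the corresponding oscillations scaled by the
baroreflex gains,

    SBP(t) = sbp0 + (A_LF/α_LF)·sin(2π·0.1·t + φ_lf)
                  + (A_HF/α_HF)·sin(φ_resp(t)) + ε_bp,

kept linear and phase-independent, so the spectral ratio √(LF_RR/LF_SBP) of
a spontaneous-breathing segment recovers α_LF (and the HF ratio α_HF).
Diastolic pressure is SBP minus a fixed pulse pressure plus noise; stroke
volume is constant.

Phase-dependent gains model the maneuver response: slow deep breathing
amplifies the RR-side RSA (``rsa_gain_cr6``, default 2.0 — vagal
enhancement), while hyperventilation withdraws vagal drive across both LF
and HF RR components (``rsa_gain_cr15``, default 0.6).  Pressure-side
amplitudes stay fixed, so measured baroreflex sensitivity rises at CR6 and
falls at CR15 — the qualitative maneuver response the simulator is built to
emulate.  These two gains are calibration knobs of the generative model, not
measured quantities.

Per-type presets target the published group medians of the four
heart-rhythm-regulation (HRR) types; :func:`make_preset` derives the
generator parameters from those medians.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import BeatSeries, Recording, RespSeries, write_beats, write_breaths
from .protocol import ManeuverProtocol, Phase, default_protocol

LF_FREQ = 0.1    # Hz, Mayer-wave component
VLF_FREQ = 0.025  # Hz, narrowband VLF carrier

#: Published group sizes of the four HRR types (n = 183).
COHORT_SIZES = {"I": 53, "II": 29, "III": 85, "IV": 16}

# Resting group medians per HRR type, used to derive generator presets:
# heart rate (min⁻¹), band-power targets (ms²), stress index (c.u.),
# systolic/diastolic pressure (mmHg), baroreflex gains (ms·mmHg⁻¹), cardiac
# output (dm³·min⁻¹), spontaneous respiratory rate (min⁻¹), minute
# ventilation (L·min⁻¹) and the median VSI drop at each paced phase
# (dm³·L⁻¹, used to set phase tidal volumes).
_TYPE_MEDIANS = {
    #        hr    vlf    lf    hf     si  sbp dbp  a_lf   a_hf   co   rr    ve   dvsi6   dvsi15
    "I":   (74.1,  581,  924, 1089, 172.1, 114, 74, 11.29, 14.85, 4.8, 15.7, 8.5, -0.157, -0.249),
    "II":  (74.8,  169,  557, 1129, 210.0, 118, 76,  9.03, 12.00, 4.7, 14.7, 8.6, -0.106, -0.173),
    "III": (65.1,  538, 1640, 2642,  59.7, 114, 70, 16.49, 21.54, 4.4, 13.4, 7.6, -0.120, -0.299),
    "IV":  (62.2, 1024, 4487, 5789,  24.9, 110, 68, 25.18, 32.03, 4.3, 12.9, 7.1, -0.261, -0.349),
}


@dataclass(frozen=True)
class TypePreset:
    """Generator parameters for one HRR type (see module docstring)."""

    name: str
    mean_rr: float        # ms
    target_vlf: float     # ms²
    target_lf: float      # ms²
    target_hf: float      # ms²
    si_target: float | None  # c.u.; None disables the rhythm clamp
    sbp0: float           # mmHg
    dbp0: float           # mmHg
    alpha_lf: float       # ms·mmHg⁻¹
    alpha_hf: float       # ms·mmHg⁻¹
    sv: float             # ml
    resp_rate_sr: float   # breaths·min⁻¹
    vt: float             # L, spontaneous breathing
    vt_cr6: float         # L, paced 6 min⁻¹
    vt_cr15: float        # L, paced 15 min⁻¹
    rsa_gain_cr6: float = 2.0
    rsa_gain_cr15: float = 0.6
    noise_sd: float = 3.0       # ms, beat-timing noise
    sbp_noise_sd: float = 1.5   # mmHg
    pulse_pressure: float = 40.0  # mmHg
    # calibration constants (solved by _calibrate; identity by default)
    cal_vlf: float = 1.0
    cal_lf: float = 1.0
    cal_hf: float = 1.0
    sat_rr: float = math.inf    # ms, rhythm-clamp scale

    def __post_init__(self) -> None:
        for f in ("target_vlf", "target_lf", "target_hf", "alpha_lf", "alpha_hf"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        for f in ("vt", "vt_cr6", "vt_cr15"):
            if not 0 < getattr(self, f) < 5:
                raise ValueError(f"{f} must be in (0, 5) L")
        if not 4 <= self.resp_rate_sr <= 30:
            raise ValueError("resp_rate_sr must be in [4, 30] min⁻¹")
        if self.mean_rr <= 0 or self.sv <= 0:
            raise ValueError("mean_rr and sv must be > 0")

    @property
    def total_target(self) -> float:
        return self.target_vlf + self.target_lf + self.target_hf


_CALIBRATION_CACHE: dict[str, tuple[float, float, float, float]] = {}


def make_preset(type_label: str, calibrate: bool = True) -> TypePreset:
    """Preset targeting the published group medians of one HRR type (I–IV).

    Derived quantities: mean RR = 60000/HR; stroke volume = 1000·CO/HR;
    spontaneous tidal volume = V_E / respiratory rate; paced-phase tidal
    volumes are set so the median VSI increment of each paced phase is
    reproduced at the median cardiac output.  Unless ``calibrate=False``,
    the generator's calibration constants (band-power gains and rhythm-clamp
    scale) are solved once per type on fixed internal seeds and cached, so
    repeated calls are cheap and deterministic.
    """
    if type_label not in _TYPE_MEDIANS:
        raise ValueError(f"unknown HRR type {type_label!r}; expected one of I, II, III, IV")
    (hr, vlf, lf, hf, si, sbp, dbp, a_lf, a_hf, co, rr, ve,
     dvsi6, dvsi15) = _TYPE_MEDIANS[type_label]
    vsi_sr = co / ve
    preset = TypePreset(
        name=type_label,
        mean_rr=60000.0 / hr,
        target_vlf=vlf, target_lf=lf, target_hf=hf,
        si_target=si,
        sbp0=sbp, dbp0=dbp,
        alpha_lf=a_lf, alpha_hf=a_hf,
        sv=1000.0 * co / hr,
        resp_rate_sr=rr,
        vt=ve / rr,
        vt_cr6=co / (vsi_sr + dvsi6) / 6.0,
        vt_cr15=co / (vsi_sr + dvsi15) / 15.0,
    )
    if not calibrate:
        return preset
    if type_label not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[type_label] = _calibrate(preset)
    c_vlf, c_lf, c_hf, sat = _CALIBRATION_CACHE[type_label]
    return replace(preset, cal_vlf=c_vlf, cal_lf=c_lf, cal_hf=c_hf, sat_rr=sat)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _phase_vt(preset: TypePreset, label: str) -> float:
    return {"SR": preset.vt, "CR6": preset.vt_cr6, "CR15": preset.vt_cr15}[label]


def _phase_gains(preset: TypePreset, label: str) -> tuple[float, float]:
    """(RSA gain, LF gain) applied to the RR side in the given phase."""
    if label == "CR6":
        return preset.rsa_gain_cr6, 1.0
    if label == "CR15":
        return preset.rsa_gain_cr15, preset.rsa_gain_cr15
    return 1.0, 1.0


def generate_breathing(phase: Phase, preset: TypePreset, seed, t0: float = 0.0) -> RespSeries:
    """Breath series covering one phase.

    Paced phases get fixed inspiratory/expiratory durations; spontaneous
    breathing draws cycle lengths with 5 % jitter around the preset rate
    (inspiration 45 % of the cycle, itself mildly jittered).  Tidal volume is
    the preset's phase value with 5 % jitter.
    """
    if phase.duration <= 0:
        raise ValueError("phase duration must be > 0")
    rng = _rng(seed)
    vt0 = _phase_vt(preset, phase.label)
    if phase.paced:
        cycle = phase.cycle
        if phase.duration < cycle:
            raise ValueError("phase shorter than one breath cycle")
        n = int(np.floor(phase.duration / cycle + 1e-9))
        starts = t0 + cycle * np.arange(n)
        ti = np.full(n, phase.t_insp)
        te = np.full(n, phase.t_exp)
    else:
        mean_cycle = 60.0 / preset.resp_rate_sr
        if phase.duration < mean_cycle:
            raise ValueError("phase shorter than one breath cycle")
        starts_l, ti_l, te_l = [], [], []
        t = t0
        end = t0 + phase.duration
        while t < end - 1e-9:
            cyc = mean_cycle * float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.85, 1.15))
            frac = float(np.clip(0.45 + 0.03 * rng.standard_normal(), 0.3, 0.6))
            if t + cyc > end:
                # the final breath is clipped at the phase boundary so phases
                # never overlap; a short remnant is absorbed into the previous
                # breath's expiration rather than becoming an implausibly fast
                # breath (which would spike the instantaneous RSA frequency)
                remnant = end - t
                if starts_l and remnant < 0.85 * mean_cycle:
                    te_l[-1] += remnant
                    break
                cyc = remnant
            starts_l.append(t)
            ti_l.append(frac * cyc)
            te_l.append((1 - frac) * cyc)
            t += cyc
        starts, ti, te = map(np.array, (starts_l, ti_l, te_l))
        n = len(starts)
    vt = vt0 * np.clip(1.0 + 0.05 * rng.standard_normal(len(starts)), 0.7, 1.3)
    return RespSeries(starts, ti, te, vt)


def _resp_phase(breaths: RespSeries, t: float) -> float:
    """Phase-continuous respiratory angle: 2π per breath cycle."""
    starts = breaths.breath_start
    cycles = breaths.ti + breaths.te
    k = int(np.searchsorted(starts, t, side="right")) - 1
    k = max(0, min(k, len(starts) - 1))
    return 2 * np.pi * (k + (t - starts[k]) / cycles[k])


@dataclass(frozen=True)
class _Oscillators:
    """Fixed per-recording phases of the deterministic RR/SBP components."""

    phi_lf: float
    phi_vlf: float

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "_Oscillators":
        return cls(
            phi_lf=float(rng.uniform(0, 2 * np.pi)),
            phi_vlf=float(rng.uniform(0, 2 * np.pi)),
        )


def _gen_segment(preset: TypePreset, breaths: RespSeries, rng: np.random.Generator,
                 t_start: float, t_end: float, osc: _Oscillators,
                 rsa_gain: float, lf_gain: float) -> BeatSeries:
    a_lf = np.sqrt(2.0 * preset.target_lf)
    a_hf = np.sqrt(2.0 * preset.target_hf)
    a_vlf = np.sqrt(2.0 * preset.target_vlf)
    sat = preset.sat_rr

    ts, rrs, sbps, dbps = [], [], [], []
    t = t_start
    while t < t_end:
        lf_arg = 2 * np.pi * LF_FREQ * t + osc.phi_lf
        vlf_arg = 2 * np.pi * VLF_FREQ * t + osc.phi_vlf
        resp_arg = _resp_phase(breaths, t)
        x = (
            preset.cal_vlf * a_vlf * np.sin(vlf_arg)
            + lf_gain * preset.cal_lf * a_lf * np.sin(lf_arg)
            + rsa_gain * preset.cal_hf * a_hf * np.sin(resp_arg)
        )
        if np.isfinite(sat):
            x = sat * np.tanh(x / sat)
        rr = preset.mean_rr + x + preset.noise_sd * rng.standard_normal()
        rr = max(rr, 0.3 * preset.mean_rr)  # physiological floor
        sbp = (
            preset.sbp0
            + (a_lf / preset.alpha_lf) * np.sin(lf_arg)
            + (a_hf / preset.alpha_hf) * np.sin(resp_arg)
            + preset.sbp_noise_sd * rng.standard_normal()
        )
        dbp = sbp - preset.pulse_pressure + 2.0 * rng.standard_normal()
        ts.append(t)
        rrs.append(rr)
        sbps.append(sbp)
        dbps.append(min(dbp, sbp - 5.0))
        t += rr / 1000.0
    sv = np.full(len(ts), preset.sv)
    return BeatSeries(np.array(ts), np.array(rrs), np.array(sbps), np.array(dbps), sv)


def _calibrate(preset: TypePreset, n_seeds: int = 15, n_iter: int = 8) -> tuple:
    """Solve the calibration gains and rhythm-clamp scale for a preset.

    Damped fixed-point iteration: generate a spontaneous-breathing phase on
    fixed internal seeds, measure VLF/LF/HF with the package's own spectral
    pipeline and the stress index from the RR histogram, then move the gains
    toward target/measured and the clamp toward the SI target.  Deterministic
    by construction.
    """
    from . import hrv  # deferred: hrv does not import simulate

    targets = np.array([preset.target_vlf, preset.target_lf, preset.target_hf])
    sigma = float(np.sqrt(preset.total_target))
    gains = np.ones(3)
    sat = 3.0 * sigma if preset.si_target is not None else math.inf
    phase = Phase("SR", 120.0)
    # joint iterations first, then the clamp is frozen and the gains settle
    for it in range(n_iter + 2):
        trial = replace(preset, cal_vlf=gains[0], cal_lf=gains[1], cal_hf=gains[2], sat_rr=sat)
        bands, sis = [], []
        for s in range(n_seeds):
            rng = np.random.default_rng(900_000 + s)
            osc = _Oscillators.draw(rng)
            breaths = generate_breathing(phase, trial, rng, t0=0.0)
            seg = _gen_segment(trial, breaths, rng, 0.0, 120.0, osc, 1.0, 1.0)
            sp = hrv.spectral_analysis(hrv.Tachogram(seg.t, seg.rr, "rr"))
            bands.append([sp.vlf, sp.lf, sp.hf])
            sis.append(hrv.stress_index(seg.rr).si)
        med = np.median(bands, axis=0)
        gains *= np.clip((targets / med) ** 0.5, 0.5, 2.0)
        gains = np.clip(gains, 0.25, 4.0)
        if preset.si_target is not None and it < n_iter:
            si_med = float(np.median(sis))
            sat *= float(np.clip((si_med / preset.si_target) ** 0.5, 0.7, 1.4))
            sat = float(np.clip(sat, 0.8 * sigma, 6.0 * sigma))
    return float(gains[0]), float(gains[1]), float(gains[2]), float(sat)


def generate_beats(preset: TypePreset, breaths: RespSeries, seed,
                   duration: float | None = None, label: str = "SR") -> BeatSeries:
    """Beat series driven by the given breath series, over ``duration`` seconds
    (default: the breath-series span).  ``label`` selects the phase gains."""
    rng = _rng(seed)
    span = breaths.breath_start[-1] + breaths.ti[-1] + breaths.te[-1] - breaths.breath_start[0]
    duration = span if duration is None else duration
    if duration > span + 1e-6:
        raise ValueError("breath series does not cover the requested duration")
    osc = _Oscillators.draw(rng)
    rsa_gain, lf_gain = _phase_gains(preset, label)
    return _gen_segment(preset, breaths, rng, breaths.breath_start[0],
                        breaths.breath_start[0] + duration, osc, rsa_gain, lf_gain)


def generate_recording(preset: TypePreset, protocol: ManeuverProtocol | None = None,
                       seed=0, subject_id: str = "S000") -> Recording:
    """Full maneuver recording: per-phase breath and beat generation with
    continuous time and shared oscillator phases, plus phase annotations."""
    protocol = protocol or default_protocol()
    rng = _rng(seed)
    osc = _Oscillators.draw(rng)

    all_breaths: list[RespSeries] = []
    segments: list[BeatSeries] = []
    annotations = []
    for phase, start, end in protocol.windows():
        breaths = generate_breathing(phase, preset, rng, t0=start)
        rsa_gain, lf_gain = _phase_gains(preset, phase.label)
        seg = _gen_segment(preset, breaths, rng, start, end, osc, rsa_gain, lf_gain)
        all_breaths.append(breaths)
        segments.append(seg)
        annotations.append((phase.label, start, end))

    beats = BeatSeries(
        np.concatenate([s.t for s in segments]),
        np.concatenate([s.rr for s in segments]),
        np.concatenate([s.sbp for s in segments]),
        np.concatenate([s.dbp for s in segments]),
        np.concatenate([s.sv for s in segments]),
    )
    breaths = RespSeries(
        np.concatenate([b.breath_start for b in all_breaths]),
        np.concatenate([b.ti for b in all_breaths]),
        np.concatenate([b.te for b in all_breaths]),
        np.concatenate([b.vt for b in all_breaths]),
    )
    return Recording(subject_id=subject_id, beats=beats, breaths=breaths, phases=annotations)


# ---------------------------------------------------------------------------
# Cohorts

# Invented subject-level dispersion (the published tables give only medians
# and quartiles): median-preserving lognormal scatter on powers and gains,
# mild normal scatter on rates and volumes.  Draws are truncated at ±1.8 σ —
# an unbounded lognormal occasionally produces subjects with several-fold the
# type's oscillation power, outside the physiological range the cohort is
# meant to emulate.
DISPERSION = {
    "power_sigma": 0.30,   # lognormal σ on the shared band-power factor
    "band_sigma": 0.15,    # extra lognormal σ per band
    "alpha_sigma": 0.15,   # lognormal σ on baroreflex gains
    "rr_cv": 0.04,         # CV of mean RR
    "resp_cv": 0.08,       # CV of spontaneous respiratory rate
    "vol_cv": 0.08,        # CV of tidal volumes and stroke volume
    "sbp_sd": 6.0,         # mmHg, additive on resting SBP
    "trunc": 1.8,          # truncation of every draw, in σ
}


def individualize(preset: TypePreset, rng: np.random.Generator,
                  dispersion: dict | None = None) -> TypePreset:
    """Draw one subject's parameters around a type preset.

    The rhythm-clamp scale co-varies with the subject's overall oscillation
    amplitude so the clamp's relative strength — a type trait — is preserved.
    """
    d = dict(DISPERSION if dispersion is None else dispersion)
    tr = d.get("trunc", 1.8)
    tn = lambda: float(np.clip(rng.standard_normal(), -tr, tr))
    ln = lambda sigma: float(np.exp(sigma * tn()))
    pf = ln(d["power_sigma"])  # shared factor keeps the band-power profile coherent
    new_vlf = preset.target_vlf * pf * ln(d["band_sigma"])
    new_lf = preset.target_lf * pf * ln(d["band_sigma"])
    new_hf = preset.target_hf * pf * ln(d["band_sigma"])
    sat_scale = np.sqrt((new_vlf + new_lf + new_hf) / preset.total_target)
    resp = float(np.clip(preset.resp_rate_sr * (1 + d["resp_cv"] * tn()), 9.0, 24.0))
    return replace(
        preset,
        mean_rr=preset.mean_rr * (1 + d["rr_cv"] * tn()),
        target_vlf=new_vlf, target_lf=new_lf, target_hf=new_hf,
        sat_rr=preset.sat_rr * float(sat_scale),
        alpha_lf=preset.alpha_lf * ln(d["alpha_sigma"]),
        alpha_hf=preset.alpha_hf * ln(d["alpha_sigma"]),
        sv=preset.sv * (1 + d["vol_cv"] * tn()),
        vt=preset.vt * (1 + d["vol_cv"] * tn()),
        vt_cr6=preset.vt_cr6 * (1 + d["vol_cv"] * tn()),
        vt_cr15=preset.vt_cr15 * (1 + d["vol_cv"] * tn()),
        resp_rate_sr=resp,
        sbp0=preset.sbp0 + d["sbp_sd"] * tn(),
    )


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    hrr_type: str
    seed: int
    recording: Recording


def generate_cohort(sizes: dict[str, int] | None = None, seed: int = 0,
                    protocol: ManeuverProtocol | None = None,
                    dispersion: dict | None = None) -> list[CohortSubject]:
    """Simulate a cohort with the published group sizes (53/29/85/16 by default).

    One master seed spawns independent per-subject child seeds through
    ``numpy.random.SeedSequence``, so any subject can be regenerated alone.
    """
    sizes = dict(COHORT_SIZES if sizes is None else sizes)
    if any(n < 0 for n in sizes.values()) or sum(sizes.values()) == 0:
        raise ValueError("cohort sizes must be non-negative and not all zero")
    protocol = protocol or default_protocol()
    n_total = sum(sizes.values())
    children = np.random.SeedSequence(seed).spawn(n_total)
    out = []
    i = 0
    for label in sorted(sizes):
        base = make_preset(label)
        for _ in range(sizes[label]):
            child = children[i]
            rng = np.random.default_rng(child)
            subject_preset = individualize(base, rng, dispersion)
            sid = f"S{i:03d}"
            rec = generate_recording(subject_preset, protocol, seed=rng, subject_id=sid)
            out.append(CohortSubject(
                sid, label,
                int(child.generate_state(1, np.uint64)[0] >> np.uint64(33)), rec))
            i += 1
    return out


def write_cohort(subjects: list[CohortSubject], outdir) -> Path:
    """Write per-subject beat/breath CSVs and a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in subjects:
        beats_path = outdir / f"{s.subject_id}_beats.csv"
        breaths_path = outdir / f"{s.subject_id}_breaths.csv"
        write_beats(s.recording.beats, beats_path)
        write_breaths(s.recording.breaths, breaths_path)
        manifest.append(
            {
                "subject_id": s.subject_id,
                "hrr_type": s.hrr_type,
                "seed": s.seed,
                "beats": beats_path.name,
                "breaths": breaths_path.name,
                "phases": [[lbl, st, en] for lbl, st, en in s.recording.phases],
            }
        )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def inject_rr_spikes(beats: BeatSeries, n_spikes: int, seed) -> BeatSeries:
    """Return a copy with ``n_spikes`` RR values halved — a crude extrasystole
    stand-in for exercising the rhythm-screening QC."""
    rng = _rng(seed)
    rr = beats.rr.copy()
    idx = rng.choice(len(rr), size=n_spikes, replace=False)
    rr[idx] *= 0.5
    return BeatSeries(beats.t, rr, beats.sbp, beats.dbp, beats.sv)
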