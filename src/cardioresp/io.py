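"""Beat and breath series containers, CSV round-trip, maneuver segmentation and rhythm QC.

File dialects (UTF-8, comma-separated, decimal point, header row required):

* beats:   ``t_s,rr_ms,sbp_mmhg,dbp_mmhg[,sv_ml]``
* breaths: ``breath_start_s,ti_s,te_s,vt_l``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import ManeuverProtocol

#: Minimum number of beats a phase must contain to be analyzable.
MIN_BEATS_PER_PHASE = 30

BEAT_COLUMNS = ["t_s", "rr_ms", "sbp_mmhg", "dbp_mmhg"]
BREATH_COLUMNS = ["breath_start_s", "ti_s", "te_s", "vt_l"]


class ParseError(ValueError):
    """A file violated the beat/breath dialect; the message names the offending row."""


@dataclass
class BeatSeries:
    """Beat-by-beat series: beat times (s), RR intervals (ms), systolic and
    diastolic pressure (mmHg) and, optionally, stroke volume (ml).

    All arrays have equal length; ``t`` is strictly increasing.
    """

    t: np.ndarray
    rr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    sv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if self.sv is not None:
            self.sv = np.asarray(self.sv, dtype=float)
        n = len(self.t)
        for name in ("rr", "sbp", "dbp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"beat series columns have unequal lengths ({name})")
        if self.sv is not None and len(self.sv) != n:
            raise ValueError("beat series columns have unequal lengths (sv)")
        if n:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ParseError(f"beat times not strictly increasing at row {row}")
            if np.any(self.rr <= 0):
                row = int(np.argmax(self.rr <= 0))
                raise ParseError(f"non-positive RR interval at row {row}")
            bad = ~(self.sbp > self.dbp) | ~(self.dbp > 0)
            if np.any(bad):
                row = int(np.argmax(bad))
                raise ParseError(f"pressure invariant sbp > dbp > 0 violated at row {row}")

    def __len__(self) -> int:
        return len(self.t)

    def window(self, start: float, end: float) -> "BeatSeries":
        """Beats with ``start <= t < end`` (half-open)."""
        m = (self.t >= start) & (self.t < end)
        return BeatSeries(
            self.t[m], self.rr[m], self.sbp[m], self.dbp[m],
            None if self.sv is None else self.sv[m],
        )


@dataclass
class RespSeries:
    """Breath-by-breath series: breath start (s), inspiratory and expiratory
    durations (s) and tidal volume (L)."""

    breath_start: np.ndarray
    ti: np.ndarray
    te: np.ndarray
    vt: np.ndarray

    def __post_init__(self) -> None:
        self.breath_start = np.asarray(self.breath_start, dtype=float)
        self.ti = np.asarray(self.ti, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        self.vt = np.asarray(self.vt, dtype=float)
        n = len(self.breath_start)
        for name in ("ti", "te", "vt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"breath series columns have unequal lengths ({name})")
        if n:
            for name in ("ti", "te", "vt"):
                v = getattr(self, name)
                if np.any(v <= 0):
                    row = int(np.argmax(v <= 0))
                    raise ParseError(f"non-positive {name} at row {row}")
            if np.any(np.diff(self.breath_start) <= 0):
                raise ParseError("breath starts not strictly increasing")
            # tolerance covers 6-decimal file rounding of abutting breaths
            ends = self.breath_start + self.ti + self.te
            if np.any(ends[:-1] > self.breath_start[1:] + 1e-5):
                raise ParseError("overlapping breaths")

    def __len__(self) -> int:
        return len(self.breath_start)

    def window(self, start: float, end: float) -> "RespSeries":
        m = (self.breath_start >= start) & (self.breath_start < end)
        return RespSeries(self.breath_start[m], self.ti[m], self.te[m], self.vt[m])

    def minute_rate(self) -> float:
        """Count-based respiratory rate over the series span, breaths·min⁻¹."""
        if len(self) == 0:
            raise ValueError("empty breath series")
        span = (self.breath_start[-1] + self.ti[-1] + self.te[-1]) - self.breath_start[0]
        return 60.0 * len(self) / span

    def minute_ventilation(self) -> float:
        """V_E = mean VT × respiratory rate, L·min⁻¹."""
        return float(np.mean(self.vt)) * self.minute_rate()


@dataclass
class Recording:
    """One subject's maneuver recording: beats, breaths and phase annotations
    as (label, start s, end s) windows."""

    subject_id: str
    beats: BeatSeries
    breaths: RespSeries
    phases: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.phases:
            if end <= start:
                raise ValueError(f"phase {label}: empty or inverted window")
            if start < prev_end:
                raise ValueError(f"phase {label}: overlapping phase windows")
            prev_end = end


@dataclass
class PhaseRecord:
    """Beats and breaths of one maneuver phase."""

    label: str
    start: float
    end: float
    beats: BeatSeries
    breaths: RespSeries


@dataclass(frozen=True)
class QCReport:
    n_beats: int
    ectopic_fraction: float
    verdict: str  # "accept" | "exclude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ectopic_fraction <= 1.0:
            raise ValueError("ectopic_fraction out of [0, 1]")


# ---------------------------------------------------------------------------
# CSV round trip

def read_beats(path) -> BeatSeries:
    df = pd.read_csv(path)
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    sv = df["sv_ml"].to_numpy() if "sv_ml" in df.columns else None
    try:
        return BeatSeries(
            df["t_s"].to_numpy(), df["rr_ms"].to_numpy(),
            df["sbp_mmhg"].to_numpy(), df["dbp_mmhg"].to_numpy(), sv,
        )
    except ParseError as e:
        raise ParseError(f"{path}: {e}") from None


def write_beats(series: BeatSeries, path) -> None:
    cols = {
        "t_s": series.t, "rr_ms": series.rr,
        "sbp_mmhg": series.sbp, "dbp_mmhg": series.dbp,
    }
    if series.sv is not None:
        cols["sv_ml"] = series.sv
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_breaths(path) -> RespSeries:
    df = pd.read_csv(path)
    missing = [c for c in BREATH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    try:
        return RespSeries(
            df["breath_start_s"].to_numpy(), df["ti_s"].to_numpy(),
            df["te_s"].to_numpy(), df["vt_l"].to_numpy(),
        )
    except ParseError as e:
        raise ParseError(f"{path}: {e}") from None


def write_breaths(series: RespSeries, path) -> None:
    pd.DataFrame(
        {
            "breath_start_s": series.breath_start, "ti_s": series.ti,
            "te_s": series.te, "vt_l": series.vt,
        }
    ).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Segmentation and QC

def segment_phases(recording: Recording, protocol: ManeuverProtocol) -> list[PhaseRecord]:
    """Split a recording into per-phase records using half-open windows
    [start, end) laid end to end from the first beat's phase origin.

    Every beat inside the protocol span lands in exactly one phase.  Raises if
    the recording is shorter than the protocol or a phase holds fewer than
    :data:`MIN_BEATS_PER_PHASE` beats.
    """
    if len(recording.beats) == 0:
        raise ValueError("empty recording")
    t0 = recording.phases[0][1] if recording.phases else recording.beats.t[0]
    data_span = recording.beats.t[-1] - t0
    # the last beat of a 6-min recording falls one RR short of the nominal span
    if data_span < protocol.span - 10.0:
        raise ValueError(
            f"recording span {data_span:.1f}s shorter than protocol span {protocol.span:.0f}s"
        )
    out = []
    for phase, start, end in protocol.windows():
        beats = recording.beats.window(t0 + start, t0 + end)
        breaths = recording.breaths.window(t0 + start, t0 + end)
        if len(beats) < MIN_BEATS_PER_PHASE:
            raise ValueError(
                f"phase {phase.label} has < {MIN_BEATS_PER_PHASE} beats ({len(beats)})"
            )
        out.append(PhaseRecord(phase.label, t0 + start, t0 + end, beats, breaths))
    return out


def screen_rhythm(beats: BeatSeries, threshold: float = 0.2) -> QCReport:
    """Flag ectopic beats and return an accept/exclude verdict.

    Beat *k* is flagged when (a) its RR interval deviates by more than
    ``threshold`` (default ±20 %) of the local median from the median of the
    11-beat neighbourhood (k−5 … k+5), and (b) it shows the jump-pair
    signature of an ectopic beat: sign-reversing successive differences on
    both sides, each exceeding 1.25 × ``threshold`` of the local median.
    The first condition is the classic local-median filter; the second makes
    the rule specific to isolated premature beats and compensatory pauses —
    a smooth high-amplitude oscillation (deep respiratory sinus arrhythmia
    sweeps 20–30 % of mean RR in vagotonic subjects) moves beats far from
    the 11-beat median but never produces an abrupt down-up jump pair of
    that size.  Any flagged beat excludes the record, mirroring the practice
    of dropping whole recordings that show extrasystoles or non-sinus
    rhythm.
    """
    n = len(beats)
    if n < 10:
        raise ValueError(f"need at least 10 beats to screen rhythm, got {n}")
    rr = beats.rr
    n_ect = 0
    for k in range(1, n - 1):
        lo, hi = max(0, k - 5), min(n, k + 6)
        med = float(np.median(rr[lo:hi]))
        d_prev = rr[k] - rr[k - 1]
        d_next = rr[k + 1] - rr[k]
        pair = min(abs(d_prev), abs(d_next)) if d_prev * d_next < 0 else 0.0
        if abs(rr[k] - med) > threshold * med and pair > 1.25 * threshold * med:
            n_ect += 1
    frac = n_ect / n
    return QCReport(n_beats=n, ectopic_fraction=frac,
                    verdict="exclude" if n_ect > 0 else "accept")
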