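"""Per-phase index panels, per-subject maneuver increments, and cohort summaries.

A *panel* collects every index computed on one maneuver phase: time-domain
HRV, Baevsky histogram indices, RR/SBP/DBP band powers, baroreflex
sensitivity, respiration parameters and the Hildebrandt and volume
synchronization indices.  *Increments* (δ) are per-subject paced-minus-
spontaneous differences (CR − SR); cohort tables summarize either panels or
increments per HRR type as median (Q1; Q3) with linear-interpolation
(type-7) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import coupling, hrv
from .io import PhaseRecord


@dataclass(frozen=True)
class IndexPanel:
    """All indices of one maneuver phase (units as in the component modules)."""

    phase: str
    # time domain
    mean_rr: float
    hr: float
    rmssd: float
    pnn50: float
    # Baevsky
    mo: float
    amo: float
    mxdmn: float
    si: float
    # RR spectra, ms²
    tp: float
    vlf: float
    lf: float
    hf: float
    lfn: float
    hfn: float
    lf_hf: float
    # SBP / DBP spectra, mmHg²
    tp_sbp: float
    vlf_sbp: float
    lf_sbp: float
    hf_sbp: float
    tp_dbp: float
    vlf_dbp: float
    lf_dbp: float
    hf_dbp: float
    # coupling
    br_lf: float
    br_hf: float
    hi: float
    vsi: float
    co: float
    # respiration
    rr_resp: float
    vt: float
    ve: float


DELTA_FIELDS = ("hi", "vsi", "br_lf", "br_hf")


@dataclass(frozen=True)
class DeltaPanel:
    """Per-subject increments CR − SR of the coupling indices for one paced phase."""

    subject_id: str
    condition: str  # CR6 | CR15
    d_hi: float
    d_vsi: float
    d_br_lf: float
    d_br_hf: float


def phase_panel(record: PhaseRecord, brs_formula: str = "sqrt",
                fs: float = hrv.DEFAULT_FS) -> IndexPanel:
    """Compute the full index panel for one phase record.

    Respiratory rate is the count-based per-minute rate over the phase;
    cardiac output comes from the mean per-beat stroke volume and the phase
    heart rate.  Errors from component calculations propagate annotated with
    the phase label.
    """
    beats, breaths = record.beats, record.breaths
    try:
        td = hrv.time_domain(beats.rr)
        geo = hrv.stress_index(beats.rr)
        sp_rr = hrv.spectral_analysis(hrv.Tachogram(beats.t, beats.rr, "rr"), fs=fs)
        sp_sbp = hrv.spectral_analysis(hrv.Tachogram(beats.t, beats.sbp, "sbp"), fs=fs)
        sp_dbp = hrv.spectral_analysis(hrv.Tachogram(beats.t, beats.dbp, "dbp"), fs=fs)
        if len(breaths) == 0:
            raise ValueError("no breaths in phase")
        rr_resp = breaths.minute_rate()
        vt = float(np.mean(breaths.vt))
        ve = breaths.minute_ventilation()
        if beats.sv is None:
            raise ValueError("CO unavailable: no stroke volume channel")
        co = coupling.cardiac_output(float(np.mean(beats.sv)), td.hr)
        panel = IndexPanel(
            phase=record.label,
            mean_rr=td.mean_rr, hr=td.hr, rmssd=td.rmssd, pnn50=td.pnn50,
            mo=geo.mo, amo=geo.amo, mxdmn=geo.mxdmn, si=geo.si,
            tp=sp_rr.tp, vlf=sp_rr.vlf, lf=sp_rr.lf, hf=sp_rr.hf,
            lfn=sp_rr.lfn, hfn=sp_rr.hfn, lf_hf=sp_rr.lf_hf,
            tp_sbp=sp_sbp.tp, vlf_sbp=sp_sbp.vlf, lf_sbp=sp_sbp.lf, hf_sbp=sp_sbp.hf,
            tp_dbp=sp_dbp.tp, vlf_dbp=sp_dbp.vlf, lf_dbp=sp_dbp.lf, hf_dbp=sp_dbp.hf,
            br_lf=coupling.brs_alpha(sp_rr.lf, sp_sbp.lf, brs_formula),
            br_hf=coupling.brs_alpha(sp_rr.hf, sp_sbp.hf, brs_formula),
            hi=coupling.hildebrandt(td.hr, rr_resp),
            vsi=coupling.vsi(co, ve),
            co=co, rr_resp=rr_resp, vt=vt, ve=ve,
        )
    except ValueError as e:
        raise ValueError(f"phase {record.label}: {e}") from None
    return panel


def deltas(panel_sr: IndexPanel, panel_cr: IndexPanel, subject_id: str = "") -> DeltaPanel:
    """Increments CR − SR of the coupling indices.

    The convention is paced minus spontaneous: a positive δHI means the
    Hildebrandt index rose under paced breathing.
    """
    if panel_sr.phase != "SR":
        raise ValueError(f"first panel must be the SR phase, got {panel_sr.phase}")
    if panel_cr.phase not in ("CR6", "CR15"):
        raise ValueError(f"second panel must be a paced phase, got {panel_cr.phase}")
    return DeltaPanel(
        subject_id=subject_id,
        condition=panel_cr.phase,
        d_hi=panel_cr.hi - panel_sr.hi,
        d_vsi=panel_cr.vsi - panel_sr.vsi,
        d_br_lf=panel_cr.br_lf - panel_sr.br_lf,
        d_br_hf=panel_cr.br_hf - panel_sr.br_hf,
    )


def panels_frame(panels: dict[str, list[IndexPanel]]) -> pd.DataFrame:
    """Wide table: one row per subject × phase (``panels`` maps subject → panels)."""
    rows = []
    for sid, plist in panels.items():
        for p in plist:
            row = {"subject_id": sid}
            row.update({f.name: getattr(p, f.name) for f in fields(IndexPanel)})
            rows.append(row)
    return pd.DataFrame(rows)


def deltas_frame(delta_panels: list[DeltaPanel]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": d.subject_id, "condition": d.condition,
            "d_hi": d.d_hi, "d_vsi": d.d_vsi,
            "d_br_lf": d.d_br_lf, "d_br_hf": d.d_br_hf,
        }
        for d in delta_panels
    ]
    return pd.DataFrame(rows)


def cohort_summary(values: pd.DataFrame, value_cols: list[str] | None = None,
                   group_col: str = "hrr_type") -> pd.DataFrame:
    """Per-group median and quartiles, one row per group × variable.

    Quantiles use linear interpolation (type 7).  Empty groups are simply
    absent from the output.
    """
    if group_col not in values.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    if value_cols is None:
        value_cols = [c for c in values.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(values[c])]
    rows = []
    for group, sub in values.groupby(group_col, sort=True):
        for col in value_cols:
            v = sub[col].dropna().to_numpy()
            if v.size == 0:
                continue
            rows.append(
                {
                    group_col: group, "variable": col, "n": int(v.size),
                    "q1": float(np.quantile(v, 0.25)),
                    "median": float(np.quantile(v, 0.5)),
                    "q3": float(np.quantile(v, 0.75)),
                }
            )
    return pd.DataFrame(rows)
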