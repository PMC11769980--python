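"""End-to-end analysis: QC → segmentation → per-phase panels → increments →
classification → cohort tables and tests.

These functions are the library behind the command-line entry points; they
operate on in-memory recordings or on the manifest/CSV layout written by the
simulator.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .classify import ClassifierThresholds, classify
from .io import Recording, read_beats, read_breaths, screen_rhythm, segment_phases
from .maneuver import DeltaPanel, IndexPanel, deltas, deltas_frame, panels_frame, phase_panel
from .protocol import ManeuverProtocol, default_protocol

log = logging.getLogger("cardioresp")


def analyze_recording(rec: Recording, protocol: ManeuverProtocol | None = None,
                      brs_formula: str = "sqrt",
                      qc_threshold: float = 0.2,
                      thresholds: ClassifierThresholds | None = None) -> dict:
    """Analyze one maneuver recording.

    Returns a dict with the QC report, per-phase panels, CR6/CR15 increments
    and the HRR classification from the spontaneous-breathing phase.  Raises
    ``ValueError`` if QC excludes the record or a phase is unusable.
    """
    protocol = protocol or default_protocol()
    qc = screen_rhythm(rec.beats, threshold=qc_threshold)
    if qc.verdict == "exclude":
        raise ValueError(
            f"subject {rec.subject_id}: rhythm QC excluded record "
            f"(ectopic fraction {qc.ectopic_fraction:.3f})"
        )
    records = segment_phases(rec, protocol)
    panels = {r.label: phase_panel(r, brs_formula=brs_formula) for r in records}
    if "SR" not in panels:
        raise ValueError(f"subject {rec.subject_id}: no spontaneous-breathing phase")
    sr = panels["SR"]
    dpanels = [
        deltas(sr, panels[lbl], subject_id=rec.subject_id)
        for lbl in ("CR6", "CR15") if lbl in panels
    ]
    hrr = classify(sr.si, sr.vlf, sr.tp, thresholds)
    return {"qc": qc, "panels": panels, "deltas": dpanels, "hrr": hrr}


def analyze_cohort(subjects, protocol: ManeuverProtocol | None = None,
                   brs_formula: str = "sqrt") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a list of subjects (``CohortSubject`` or (id, type, Recording)).

    Subjects failing QC or with an unusable phase are dropped whole
    (complete-case) and logged.  Returns (panel table, delta table); both
    carry ``hrr_type`` (generating label) and ``classified`` columns.
    """
    panel_rows: dict[str, list[IndexPanel]] = {}
    delta_panels: list[DeltaPanel] = []
    meta: dict[str, dict] = {}
    for s in subjects:
        sid, label, rec = s.subject_id, s.hrr_type, s.recording
        try:
            res = analyze_recording(rec, protocol, brs_formula=brs_formula)
        except ValueError as e:
            log.warning("dropping subject %s: %s", sid, e)
            continue
        panel_rows[sid] = list(res["panels"].values())
        delta_panels.extend(res["deltas"])
        meta[sid] = {"hrr_type": label, "classified": res["hrr"].label}

    panels = panels_frame(panel_rows)
    dframe = deltas_frame(delta_panels)
    for frame in (panels, dframe):
        if not frame.empty:
            frame["hrr_type"] = frame["subject_id"].map(lambda x: meta[x]["hrr_type"])
            frame["classified"] = frame["subject_id"].map(lambda x: meta[x]["classified"])
    return panels, dframe


def load_cohort(manifest_path) -> list:
    """Load a simulated cohort from its JSON manifest (as written by
    :func:`cardioresp.simulate.write_cohort`)."""
    from .simulate import CohortSubject  # local import to avoid cycle

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    entries = json.loads(manifest_path.read_text())
    out = []
    for e in entries:
        rec = Recording(
            subject_id=e["subject_id"],
            beats=read_beats(base / e["beats"]),
            breaths=read_breaths(base / e["breaths"]),
            phases=[tuple(p) for p in e["phases"]],
        )
        out.append(CohortSubject(e["subject_id"], e["hrr_type"], e.get("seed", 0), rec))
    return out


def delta_anova_tables(dframe: pd.DataFrame) -> dict[str, stats.AnovaTable]:
    """Two-way ANOVA (condition × HRR type) of each δ index.

    Factor A is the paced condition (CR6/CR15), factor B the HRR type; every
    subject contributes one row per condition.
    """
    out = {}
    for col in ("d_hi", "d_vsi", "d_br_lf", "d_br_hf"):
        out[col] = stats.anova2(dframe[col], dframe["condition"], dframe["hrr_type"])
    return out


def delta_wilcoxon_tests(dframe: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon matched-pairs CR6-vs-CR15 increments per type and δ index,
    mirroring the per-type z/p columns of the increment tables."""
    rows = []
    wide = dframe.pivot_table(index=["subject_id", "hrr_type"], columns="condition",
                              values=["d_hi", "d_vsi", "d_br_lf", "d_br_hf"])
    for hrr_type, sub in wide.groupby(level="hrr_type", sort=True):
        for col in ("d_hi", "d_vsi", "d_br_lf", "d_br_hf"):
            pair = sub[col].dropna()
            try:
                res = stats.wilcoxon_signed(pair["CR6"], pair["CR15"])
            except ValueError as e:
                log.warning("wilcoxon %s type %s: %s", col, hrr_type, e)
                continue
            rows.append({"variable": col, "hrr_type": hrr_type,
                         "n": res.n, "z": res.z, "p": res.p})
    return pd.DataFrame(rows)


def between_group_tests(dframe: pd.DataFrame) -> pd.DataFrame:
    """Pairwise between-type Mann–Whitney p-values for each δ index and condition."""
    rows = []
    types = sorted(dframe["hrr_type"].unique())
    for cond, sub in dframe.groupby("condition", sort=True):
        for col in ("d_hi", "d_vsi", "d_br_lf", "d_br_hf"):
            for i, ta in enumerate(types):
                for tb in types[i + 1:]:
                    a = sub.loc[sub["hrr_type"] == ta, col].dropna()
                    b = sub.loc[sub["hrr_type"] == tb, col].dropna()
                    if len(a) < 3 or len(b) < 3:
                        continue
                    rows.append(
                        {
                            "condition": cond, "variable": col,
                            "pair": f"{ta}-{tb}",
                            "p": stats.mannwhitney(a, b),
                        }
                    )
    return pd.DataFrame(rows)
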