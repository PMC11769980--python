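"""Heart-rhythm-regulation (HRR) typing from resting HRV indices.

The Shlyk scheme assigns one of four types from the stress index SI (c.u.),
VLF power (ms²) and total power TP (ms²) of the spontaneous-breathing record:

====  =========================  ==========================================
Type  Autonomic reading          Rule
====  =========================  ==========================================
I     moderate central           SI > 100 and VLF > 240
II    pronounced central         SI > 100 and VLF ≤ 240
III   moderate autonomous        30 ≤ SI ≤ 100 and VLF > 240
IV    pronounced autonomous      SI < 30 and VLF > 500 and TP > 8000
====  =========================  ==========================================

Boundary conventions (inclusive 30–100, VLF ≤ 240 as the complement of
> 240, the lower printed TP bound) are explicit choices of this package and
are overridable through :class:`ClassifierThresholds`.  Triples that satisfy
no rule — possible because the type IV rule demands more than just SI < 30 —
return ``UNCLASSIFIED`` with a rationale naming the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

HRR_LABELS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ClassifierThresholds:
    si_high: float = 100.0   # central predominance above this
    si_low: float = 30.0     # pronounced autonomous below this
    vlf_split: float = 240.0
    vlf_iv: float = 500.0
    tp_iv: float = 8000.0


@dataclass(frozen=True)
class HRRType:
    label: str  # I | II | III | IV | UNCLASSIFIED
    rationale: str


def classify(si: float, vlf: float, tp: float,
             thresholds: ClassifierThresholds | None = None) -> HRRType:
    """Assign an HRR type from (SI, VLF, TP); see module docstring for the rules."""
    th = thresholds or ClassifierThresholds()
    for name, v in (("si", si), ("vlf", vlf), ("tp", tp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if si > th.si_high:
        if vlf > th.vlf_split:
            return HRRType("I", f"SI {si:g} > {th.si_high:g} and VLF {vlf:g} > {th.vlf_split:g}")
        return HRRType("II", f"SI {si:g} > {th.si_high:g} and VLF {vlf:g} <= {th.vlf_split:g}")
    if th.si_low <= si <= th.si_high:
        if vlf > th.vlf_split:
            return HRRType(
                "III",
                f"{th.si_low:g} <= SI {si:g} <= {th.si_high:g} and VLF {vlf:g} > {th.vlf_split:g}",
            )
        return HRRType(
            "UNCLASSIFIED",
            f"rule gap: {th.si_low:g} <= SI {si:g} <= {th.si_high:g} but VLF {vlf:g} <= "
            f"{th.vlf_split:g} matches no type",
        )
    # si < th.si_low
    if vlf > th.vlf_iv and tp > th.tp_iv:
        return HRRType(
            "IV",
            f"SI {si:g} < {th.si_low:g}, VLF {vlf:g} > {th.vlf_iv:g}, TP {tp:g} > {th.tp_iv:g}",
        )
    return HRRType(
        "UNCLASSIFIED",
        f"rule gap: SI {si:g} < {th.si_low:g} but VLF {vlf:g} / TP {tp:g} below the "
        f"type IV power criteria",
    )
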