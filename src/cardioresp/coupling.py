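"""Cardiovascular (baroreflex) and cardiorespiratory (Hildebrandt, VSI) coupling indices.

Baroreflex sensitivity is estimated spectrally as the α-coefficient

    α = √(P_RR / P_SBP)

from the RR and systolic-pressure band powers of the same band: ``BR_LF``
from the LF powers, ``BR_HF`` from the HF powers, in ms·mmHg⁻¹.  The plain
(un-rooted) power ratio is available as an explicitly requested option but is
dimensionally a squared gain (ms²·mmHg⁻²) and is roughly an order of
magnitude larger than physiological α values.

Frequency and volume synchronization of heart and lungs:

    HI  = HR (min⁻¹) / RR_resp (min⁻¹)          [c.u.]
    VSI = CO (dm³·min⁻¹) / V_E (L·min⁻¹)        [dm³·L⁻¹]

Both are exact quotients of already-computed quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class CouplingPanel:
    """Per-phase coupling indices (see module docstring for units)."""

    br_lf: float
    br_hf: float
    hi: float
    vsi: float | None
    co: float | None
    rr_resp: float
    ve: float
    vt: float


def brs_alpha(p_rr: float, p_bp: float, formula: str = "sqrt") -> float:
    """Spectral baroreflex sensitivity from same-band RR (ms²) and SBP (mmHg²) powers.

    ``formula="sqrt"`` (default) returns the α-coefficient √(p_rr/p_bp);
    ``formula="ratio"`` returns the raw power ratio, with a warning.
    """
    if p_bp <= 0:
        raise ValueError("BRS undefined: SBP band power must be > 0")
    if p_rr < 0:
        raise ValueError("negative RR band power")
    if formula == "sqrt":
        return (p_rr / p_bp) ** 0.5
    if formula == "ratio":
        warnings.warn(
            "plain power ratio is a squared gain (ms²·mmHg⁻²), not the α-coefficient",
            stacklevel=2,
        )
        return p_rr / p_bp
    raise ValueError(f"unknown BRS formula {formula!r}; use 'sqrt' or 'ratio'")


def hildebrandt(hr: float, rr_resp: float) -> float:
    """Hildebrandt index HR/RR_resp (both min⁻¹), c.u."""
    if rr_resp <= 0:
        raise ValueError("respiratory rate must be > 0")
    return hr / rr_resp


def vsi(co: float, ve: float) -> float:
    """Volume synchronization index CO/V_E, dm³·L⁻¹."""
    if ve <= 0:
        raise ValueError("minute ventilation must be > 0")
    return co / ve


def cardiac_output(sv: float, hr: float) -> float:
    """Cardiac output SV (ml) × HR (min⁻¹) / 1000, dm³·min⁻¹."""
    if sv <= 0 or hr <= 0:
        raise ValueError("CO unavailable: need positive stroke volume and heart rate")
    return sv * hr / 1000.0
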