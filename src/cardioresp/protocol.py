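"""Breathing-maneuver protocol: an ordered list of phases with paced or free timing.

The standard maneuver is three 2-minute phases recorded back to back:

* ``SR``   — spontaneous respiration (free inspiratory/expiratory timing),
* ``CR6``  — paced breathing at 6 min⁻¹ (0.1 Hz; 5 s inhale, 5 s exhale),
* ``CR15`` — paced breathing at 15 min⁻¹ (0.25 Hz; 2 s inhale, 2 s exhale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

PHASE_LABELS = ("SR", "CR6", "CR15")


@dataclass(frozen=True)
class Phase:
    """One maneuver phase.

    ``t_insp``/``t_exp`` are the paced inspiratory/expiratory durations in
    seconds; ``None`` means free (spontaneous) timing.
    """

    label: str
    duration: float
    t_insp: float | None = None
    t_exp: float | None = None

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}")
        if self.duration <= 0:
            raise ValueError(f"phase {self.label}: duration must be > 0, got {self.duration}")
        if (self.t_insp is None) != (self.t_exp is None):
            raise ValueError(f"phase {self.label}: t_insp and t_exp must both be set or both free")
        if self.t_insp is not None and (self.t_insp <= 0 or self.t_exp <= 0):
            raise ValueError(f"phase {self.label}: paced durations must be > 0")

    @property
    def paced(self) -> bool:
        return self.t_insp is not None

    @property
    def cycle(self) -> float | None:
        """Paced breath-cycle length in seconds, or ``None`` for free breathing."""
        return None if self.t_insp is None else self.t_insp + self.t_exp


@dataclass(frozen=True)
class ManeuverProtocol:
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol must contain at least one phase")

    @property
    def span(self) -> float:
        """Total protocol duration in seconds."""
        return sum(p.duration for p in self.phases)

    def windows(self) -> Iterator[tuple[Phase, float, float]]:
        """Yield (phase, start, end) with phase windows laid end to end from t=0."""
        t = 0.0
        for p in self.phases:
            yield p, t, t + p.duration
            t += p.duration


def default_protocol(phase_duration: float = 120.0) -> ManeuverProtocol:
    """The 6-minute SR / CR6 / CR15 maneuver (three equal phases)."""
    return ManeuverProtocol(
        (
            Phase("SR", phase_duration),
            Phase("CR6", phase_duration, t_insp=5.0, t_exp=5.0),
            Phase("CR15", phase_duration, t_insp=2.0, t_exp=2.0),
        )
    )
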