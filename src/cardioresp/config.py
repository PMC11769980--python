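"""Run configuration: analysis parameters with validated defaults, loadable from YAML.

The committed defaults reproduce every documented example; a YAML file may
override any subset, and command-line flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import ClassifierThresholds
from .hrv import DEFAULT_BANDS, DEFAULT_FS, SI_BIN_MS
from .protocol import ManeuverProtocol, Phase, default_protocol


@dataclass
class RunConfig:
    fs: float = DEFAULT_FS                      # tachogram resampling rate, Hz
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    si_bin_ms: float = SI_BIN_MS
    brs_formula: str = "sqrt"                   # "sqrt" (α-coefficient) or "ratio"
    qc_threshold: float = 0.2                   # ectopy rule, fraction of local median
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    phase_duration: float = 120.0               # s, per maneuver phase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.brs_formula not in ("sqrt", "ratio"):
            raise ValueError("brs_formula must be 'sqrt' or 'ratio'")
        for band, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi:
                raise ValueError(f"band {band}: need 0 <= low < high")

    def protocol(self) -> ManeuverProtocol:
        return default_protocol(self.phase_duration)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "classifier" in raw:
            raw["classifier"] = ClassifierThresholds(**raw["classifier"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
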