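"""Pipeline configuration: every tunable constant of the analysis in one place.

Defaults follow the standard intensive-care neuromonitoring conventions this
pipeline implements: 10-s spectral windows, a 30-sample / 1-minute moving
correlation for the reactivity indices, the 40-180 cycles/min cardiac band,
10 mm Hg binning for relationship curves and the 0-25 / 25-50 / 50-150 mm Hg
ICP severity levels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A configuration field is missing, inconsistent or out of range."""


class FormatError(ValueError):
    """An input file violates the expected on-disk format."""


@dataclass
class ValidityRule:
    """Artifact screen for 10-s windows.

    The bounds bracket survivable physiology; a window failing any check is
    flagged invalid and excluded from all downstream indices.
    """

    abp_range: tuple[float, float] = (20.0, 250.0)
    icp_range: tuple[float, float] = (-10.0, 150.0)
    max_missing_frac: float = 0.10


@dataclass
class PipelineConfig:
    sampling_rate: float = 50.0           # Hz, minimum admissible for ABP/ICP
    window_seconds: float = 10.0          # spectral / averaging window
    corr_window_samples: int = 30         # 30 x 10 s = 5 min correlation window
    corr_step_samples: int = 6            # 6 x 10 s = 1 min update cadence
    cardiac_band_cpm: tuple[float, float] = (40.0, 180.0)
    bin_width_mmhg: float = 10.0
    icp_level_edges: tuple[float, float, float, float] = (0.0, 25.0, 50.0, 150.0)
    episode_high_icp: float = 40.0        # mm Hg, strict > for the refractory run
    episode_min_minutes: int = 60
    episode_low_icp: float = 25.0         # mm Hg, initial-ICP precondition
    episode_min_hours: float = 12.0       # minimum monitored span
    episode_initial_rule: str = "any_minute"  # or "first_hour_median"
    first_hours: float = 5.0              # early-monitoring comparison span
    lowess_frac: float = 0.5
    bootstrap_replicates: int = 500
    min_bin_minutes: int = 5
    min_level_minutes: int = 30
    aabp_guard_mmhg: float = 1.0          # AMP/aABP undefined below this aABP
    spline_df: int = 5                    # basis dimension for the AMP-ICP fit
    classify_eps: float = 0.01            # dead-band, mm Hg AMP per mm Hg ICP
    seed: int = 0
    validity: ValidityRule = field(default_factory=ValidityRule)

    def __post_init__(self) -> None:
        if self.sampling_rate < 50:
            raise ConfigurationError("sampling_rate must be >= 50 Hz for ABP/ICP")
        lo, hi = self.cardiac_band_cpm
        if not (0 < lo < hi):
            raise ConfigurationError("cardiac_band_cpm must be an increasing positive interval")
        if self.corr_window_samples < 3:
            raise ConfigurationError("corr_window_samples must be >= 3")
        if self.corr_step_samples < 1:
            raise ConfigurationError("corr_step_samples must be >= 1")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["validity"] = dataclasses.asdict(self.validity)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "validity" in d and isinstance(d["validity"], dict):
            d["validity"] = ValidityRule(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["validity"].items()
            })
        for key in ("cardiac_band_cpm", "icp_level_edges"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a mapping of config keys")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of all settings; recorded in every run log."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def describe(self) -> str:
        lines = []
        for k, v in self.to_dict().items():
            lines.append(f"{k} = {v}")
        return "\n".join(lines)
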