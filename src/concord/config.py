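"""Run configuration: defaults pinned to the primary analysis definition.

The defaults reproduce the primary processing rules — social day 03:00 to
02:59, non-wear as >60 consecutive minutes with fewer than 10 steps, valid
day at >=600 wear minutes, exercise day as >=24 MVPA minutes within any
consecutive 30-minute window — and the sweep over m = 15..30 with the three
intensity sets.  A TOML file can override any key; sections mirror the
dataclass fields below.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

from .bout_detection import (ALL_INTENSITIES, MVPA, VIGOROUS_ONLY,
                             BoutDefinition, intensity_set_label,
                             parse_intensity_set)
from .synthetic_data import SyntheticConfig


@dataclass
class NonwearConfig:
    min_run_minutes: int = 61
    max_run_steps: int = 10
    interpretation: str = "run_total"   # or "per_minute"


@dataclass
class ValidDayConfig:
    min_wear_minutes: int = 600


@dataclass
class BoutConfig:
    window_minutes: int = 30
    active_minutes: int = 24
    intensity_set: str = "moderate+vigorous"

    def definition(self) -> BoutDefinition:
        return BoutDefinition(self.window_minutes, self.active_minutes,
                              parse_intensity_set(self.intensity_set))


@dataclass
class SweepConfig:
    m_min: int = 15
    m_max: int = 30
    intensity_sets: tuple[str, ...] = (
        "light+moderate+vigorous", "moderate+vigorous", "vigorous")

    def m_range(self) -> range:
        return range(self.m_min, self.m_max + 1)

    def sets(self):
        return [parse_intensity_set(s) for s in self.intensity_sets]


@dataclass
class AgreementConfig:
    min_days_per_participant: int = 1


@dataclass
class CorrelatesConfig:
    mode: str = "significant_only"      # or "all_covariates"
    alpha: float = 0.05


@dataclass
class RunConfig:
    nonwear: NonwearConfig = field(default_factory=NonwearConfig)
    valid_day: ValidDayConfig = field(default_factory=ValidDayConfig)
    bout: BoutConfig = field(default_factory=BoutConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)
    correlates: CorrelatesConfig = field(default_factory=CorrelatesConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["start_date"] = str(d["synthetic"]["start_date"])
        return d


_SECTIONS = {"nonwear": NonwearConfig, "valid_day": ValidDayConfig,
             "bout": BoutConfig, "sweep": SweepConfig,
             "agreement": AgreementConfig, "correlates": CorrelatesConfig,
             "synthetic": SyntheticConfig}


def load_config(path=None) -> RunConfig:
    """Build a RunConfig from a TOML file (or pure defaults when no path).

    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    data = tomllib.loads(Path(path).read_text())
    for section, payload in data.items():
        if section == "seed":
            cfg.seed = int(payload)
            continue
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section '{section}'")
        target = getattr(cfg, section)
        valid = {f.name for f in fields(target)}
        for key, value in payload.items():
            if key not in valid:
                raise ValueError(f"unknown key '{section}.{key}'")
            if key == "intensity_sets":
                value = tuple(value)
            setattr(target, key, value)
    return cfg
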