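"""TOML run configuration.

Every tunable of the pipeline lives under a named key with its standard
default, so a run is reproducible from the config file plus a seed alone.
Sections: [species], [thresholds], [bouts], [evaluation], [sampling], [synth].
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

from .bouts import BoutConfig
from .evaluation import EvalConfig
from .segmenter import TransitionThresholds
from .synth import CorpusPlan
from .tracks import SpeciesProfile
from .units import SamplingPlan

__all__ = ["RunConfig", "load_config"]


def _build(cls, section: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**kwargs)


@dataclass
class RunConfig:
    profile: SpeciesProfile = field(default_factory=lambda: SpeciesProfile(min_f0=400.0))
    thresholds: TransitionThresholds = field(default_factory=TransitionThresholds)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    sampling: SamplingPlan = field(default_factory=SamplingPlan)
    synth: CorpusPlan = field(default_factory=CorpusPlan)
    seed: int = 0
    out_dir: str = "vocseg_out"


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration before any audio is touched."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig(
        profile=_build(SpeciesProfile, raw.get("species", {"min_f0": 400.0})),
        thresholds=_build(TransitionThresholds, raw.get("thresholds", {})),
        bouts=_build(BoutConfig, raw.get("bouts", {})),
        evaluation=_build(EvalConfig, raw.get("evaluation", {})),
        sampling=_build(SamplingPlan, raw.get("sampling", {})),
        synth=_build(CorpusPlan, raw.get("synth", {})),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "vocseg_out")),
    )
    return cfg
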