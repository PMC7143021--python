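"""Study configuration: design, noise, GA and modeling settings from YAML.

A flat YAML file can override any default, e.g.::

    noise:
      sigma_shot: 40.0
      n_shots: 100
    design:
      replicates: 3
    ga:
      n_generations: 50
    cv_folds: 10
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .peaks import DEFAULT_HALF_WINDOW_NM
from .selection import GAConfig
from .synthetic import AmplitudeConfig, MixtureDesign, NoiseConfig

__all__ = ["StudyConfig", "load_study_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Everything run_study needs besides the master seed."""

    pure_kind: str = "acacia"
    adulterant_kinds: tuple = ("hfcs55", "hfcs90", "rape")
    design: MixtureDesign = field(default_factory=MixtureDesign)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    amplitudes: AmplitudeConfig = field(default_factory=AmplitudeConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    grid_step_nm: float = 0.05
    peak_fwhm_nm: float = 0.30
    half_window_nm: float = DEFAULT_HALF_WINDOW_NM
    cv_folds: int = 10
    max_lv: int = 10


def load_study_config(path: str | Path | None = None) -> StudyConfig:
    """Build a StudyConfig from a YAML file (missing keys keep defaults)."""
    cfg = StudyConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "design" in raw:
        cfg = replace(cfg, design=MixtureDesign(**raw.pop("design")))
    if "noise" in raw:
        cfg = replace(cfg, noise=NoiseConfig(**raw.pop("noise")))
    if "ga" in raw:
        cfg = replace(cfg, ga=GAConfig(**raw.pop("ga")))
    if "amplitudes" in raw:
        amp = raw.pop("amplitudes")
        for key in ("mineral_base", "organic_base", "inert_base"):
            if key in amp:
                amp[key] = tuple(amp[key])
        cfg = replace(cfg, amplitudes=AmplitudeConfig(**amp))
    if "adulterant_kinds" in raw:
        raw["adulterant_kinds"] = tuple(raw["adulterant_kinds"])
    unknown = set(raw) - {f.name for f in cfg.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return replace(cfg, **raw)
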