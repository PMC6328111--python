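"""Pipeline configuration with the scheme's reference defaults."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the detection scheme, with the reference defaults.

    Thresholds/radii: lung window (1600/-600 HU), dot-binarization thresholds
    15/256 (vessel-tree group) and 10/256 (non-vessel group), constrained
    growth limit 5 mm, rolling-ball radius 15 mm, non-vessel volume floor
    4.19 mm^3 and rule bounds 14.14 mm^3 .. 14.14 cm^3; CV folds K=10, L=3.
    """

    window_width_hu: float = 1600.0
    window_level_hu: float = -600.0
    isotropic_spacing_mm: float = 1.0
    rolling_ball_radius_mm: float = 15.0
    airway_leak_factor: float = 1.5
    dot_scales_mm: tuple = (1.0, 1.5, 2.0, 4.0, 6.0, 10.0)
    t_vessel: float = 15.0 / 256.0
    t_nonvessel: float = 10.0 / 256.0
    growth_limit_mm: float = 5.0
    min_nonvessel_volume_mm3: float = 4.19
    rule_volume_min_mm3: float = 14.14
    rule_volume_max_mm3: float = 14.14e3
    rule_elongation_max: float = 6.0
    rule_compactness_min: float = 0.3
    rule_sphericity_min: float = 0.3
    cv_outer_folds: int = 10
    cv_inner_folds: int = 3
    rsfs_iterations: int = 600
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dot_scales_mm" in raw:
            raw["dot_scales_mm"] = tuple(raw["dot_scales_mm"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dot_scales_mm"] = list(d["dot_scales_mm"])
        return d
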