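"""Run configuration: every analysis threshold in one place.

Defaults are the study conditions: 0.2 V/mm VTA threshold, 20% coverage,
alpha 0.05, 20% fibre filter, top 30% display fraction, n = 76 patients,
20 000 streamlines.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    # analysis grid
    grid_shape: tuple = (61, 71, 61)
    grid_voxel_mm: float = 1.0
    grid_origin: tuple = (-30.0, -40.0, -30.0)
    # cohort
    n_patients: int = 76
    placement_sd_mm: float = 2.0
    # conductivity (S/m)
    sigma_grey: float = 0.33
    sigma_white: float = 0.14
    sigma_contact: float = 1e6
    sigma_insulation: float = 1e-6
    # VTA
    vta_threshold: float = 0.2
    solver_voxel_mm: float = 0.5
    solver_halfwidth_mm: float = 8.0
    # PSM
    coverage_fraction: float = 0.20
    alpha: float = 0.05
    voxel_test: str = "ranksum"
    # fibres
    n_fibres: int = 20000
    fibre_min_fraction: float = 0.20
    top_fraction: float = 0.30
    resample_step_mm: float = 0.5
    # functional connectome
    connectome_voxel_mm: float = 2.0
    connectome_subjects: int = 20
    connectome_t_points: int = 200
    rmap_method: str = "rank"
    # validation
    cv_alternative: str = "greater"
    # master seed
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.vta_threshold:
            raise ValueError("VTA threshold must be positive")
        for name in ("coverage_fraction", "fibre_min_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["grid_origin"] = list(self.grid_origin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "grid_origin"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
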