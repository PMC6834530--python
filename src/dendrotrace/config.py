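"""Pipeline configuration: one flat, human-editable file of namespaced keys.

Every tunable of every stage lives here under a ``section.key`` name
(``valley.scale_um``, ``link.max_gap_um``, ...).  Unknown keys are
rejected at load time so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .grow import GrowParams
from .validity import ValidityParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline parameters, with their defaults.

    Lengths are in micrometres unless the name says pixels or planes.
    """

    # spacing.*
    spacing_dx: float = 0.2
    spacing_dy: float = 0.2
    spacing_dz: float = 0.5
    # background.*
    background_scale_um: float = 20.0
    # slabs.*
    slabs_n: int = 1
    # valley.*
    valley_scale_um: float = 0.8
    valley_n_orientations: int = 12
    valley_tau_k: float = 6.0
    valley_delta_frac: float = 0.5
    # mask.*
    mask_min_speck_px: int = 8
    mask_closing_radius_px: int = 1
    # seam.*
    seam_max_step: int = 2
    # place.*
    place_rapid_dr_frac: float = 0.5
    # link.*
    link_max_gap_um: float = 5.0
    link_max_angle_deg: float = 100.0
    link_max_dz_um: float = 5.0
    # validity.*
    validity_sigma: float = 0.03
    validity_baseline_top_frac: float = 0.20
    validity_depth_k: float = 2.0
    validity_relaxed_k: float = 1.0
    validity_patch_floor_um: float = 4.0
    validity_patch_radius_mult: float = 4.0
    validity_r_min_um: float = 0.2
    validity_r_max_um: float = 10.0
    validity_max_shift_mult: float = 2.0
    validity_n_iter: int = 3
    # extend.*
    extend_arc_floor_um: float = 3.0
    extend_arc_span_deg: float = 60.0
    extend_relaxed: bool = True
    # connect.*
    connect_max_gap_um: float = 5.0
    # soma.*
    soma_margin: float = 0.1
    soma_exclusion_um: float = 2.0
    # prune.*
    prune_min_component_um: float = 20.0
    prune_min_twig_points: int = 5
    # run.*
    run_workers: int = 1
    run_darkfield: bool = False

    # -- derived parameter bundles ------------------------------------

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.spacing_dx, self.spacing_dy, self.spacing_dz)

    @property
    def n_workers(self) -> int:
        return self.run_workers

    @property
    def darkfield(self) -> bool:
        return self.run_darkfield

    def validity_params(self) -> ValidityParams:
        return ValidityParams(
            sigma=self.validity_sigma,
            baseline_top_frac=self.validity_baseline_top_frac,
            depth_k=self.validity_depth_k,
            relaxed_k=self.validity_relaxed_k,
            patch_floor_um=self.validity_patch_floor_um,
            patch_radius_mult=self.validity_patch_radius_mult,
            r_min_um=self.validity_r_min_um,
            r_max_um=self.validity_r_max_um,
            max_shift_mult=self.validity_max_shift_mult,
            n_iter=self.validity_n_iter,
        )

    def grow_params(self) -> GrowParams:
        return GrowParams(
            arc_floor_um=self.extend_arc_floor_um,
            arc_span_deg=self.extend_arc_span_deg,
            seam_max_step=self.seam_max_step,
            connect_max_gap_um=self.connect_max_gap_um,
            max_angle_deg=self.link_max_angle_deg,
            max_dz_um=self.link_max_dz_um,
            soma_margin=self.soma_margin,
            soma_exclusion_um=self.soma_exclusion_um,
            validity=self.validity_params(),
        )

    # -- (de)serialization --------------------------------------------

    def to_flat_dict(self) -> dict[str, object]:
        return {f.name.replace("_", ".", 1): getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_flat_dict(cls, flat: dict[str, object]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        unknown = []
        for key, value in flat.items():
            name = key.replace(".", "_")
            if name not in known:
                unknown.append(key)
            else:
                kwargs[name] = value
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_flat_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a mapping of key: value")
        return cls.from_flat_dict(data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
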