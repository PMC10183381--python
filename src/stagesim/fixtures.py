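"""Deterministic miniature test scenes (coarse meshes, desk-scale)."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .aligner import AlignerModel, build_aligner
from .arch import (ArchCurve, ArchModel, FrameDefinition, ToothModel, ToothSpec,
                   _crown_mesh, _root_mesh, build_pdl_foundation, compute_landmarks)
from .config import ArchConfig, ToothSpecConfig
from .errors import StageSimError
from .mechanics import PDLFoundation
from .transforms import RigidTransform


@dataclass
class FixtureScene:
    name: str
    arch: ArchModel
    foundations: Dict[int, PDLFoundation]
    aligner: Optional[AlignerModel] = None


_MESH = 1.2     # coarse target edge length, mm


def _make_tooth(spec: ToothSpec, pose: RigidTransform, exponent: float = 0.85) -> ToothModel:
    crown = _crown_mesh(spec, exponent, _MESH)
    root, furcation = _root_mesh(spec, _MESH)
    tooth = ToothModel(spec, crown, root, pose, None, furcation,
                       distal_dir=np.array([1.0, 0.0, 0.0]))
    tooth.landmarks = compute_landmarks(tooth)
    return tooth


def _identity_frame() -> FrameDefinition:
    return FrameDefinition(np.zeros(3), np.array([1.0, 0.0, 0.0]),
                           np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
                           (np.zeros(3), np.array([0.0, 0.0, 1.0])))


def _coarse_config() -> ArchConfig:
    return ArchConfig(mesh_size=_MESH)


def _single_tooth(seed: int) -> FixtureScene:
    rng = np.random.default_rng(seed)
    spec = ToothSpec(15, 8.0, 6.8 * (1 + 0.02 * rng.uniform(-1, 1)), 9.0, 14.0)
    tooth = _make_tooth(spec, RigidTransform.identity())
    arch = ArchModel([tooth], (np.array([-20.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
                     _identity_frame(), _coarse_config())
    aligner = build_aligner(arch, trim_fraction=0.4)
    return FixtureScene("single-tooth", arch, {15: build_pdl_foundation(tooth)}, aligner)


def _two_teeth(seed: int) -> FixtureScene:
    rng = np.random.default_rng(seed)
    jitter = 1 + 0.02 * rng.uniform(-1, 1)
    s16 = ToothSpec(16, 7.5, 10.0 * jitter, 11.0, 13.0, 3, 3.5)
    s17 = ToothSpec(17, 7.0, 9.5, 11.0, 12.0, 3, 3.5)
    t16 = _make_tooth(s16, RigidTransform.identity())
    gap = 0.005
    t17 = _make_tooth(s17, RigidTransform(np.eye(3),
                                          [s16.crown_md_width / 2 + s17.crown_md_width / 2 + gap, 0, 0]))
    arch = ArchModel([t16, t17], (np.array([-20.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
                     _identity_frame(), _coarse_config())
    founds = {16: build_pdl_foundation(t16), 17: build_pdl_foundation(t17)}
    aligner = build_aligner(arch, trim_fraction=0.4)
    return FixtureScene("two-teeth", arch, founds, aligner)


def _coarse_arch(seed: int) -> FixtureScene:
    from .arch import build_arch
    arch = build_arch(_coarse_config(), seed=seed)
    founds = {t.fdi_id: build_pdl_foundation(t) for t in arch.teeth}
    return FixtureScene("coarse-arch", arch, founds, build_aligner(arch))


_REGISTRY = {
    "single-tooth": _single_tooth,
    "two-teeth": _two_teeth,
    "coarse-arch": _coarse_arch,
}


def fixture_names() -> List[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str, seed: int = 0) -> FixtureScene:
    """Build a registered miniature scene, deterministic for (name, seed)."""
    if name not in _REGISTRY:
        raise StageSimError(f"unknown fixture {name!r}; known: {fixture_names()}")
    return _REGISTRY[name](seed)
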