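"""Mesh and landmark export (ASCII STL + JSON tables)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np

from .aligner import AlignerModel
from .arch import ArchModel


def _write_stl(mesh, path: Path) -> None:
    path.write_bytes(mesh.export(file_type="stl_ascii").encode()
                     if isinstance(mesh.export(file_type="stl_ascii"), str)
                     else mesh.export(file_type="stl_ascii"))


def export_arch(arch: ArchModel, out_dir, prefix: str = "tooth") -> Dict[str, Path]:
    """One STL per tooth body plus a JSON landmark table (frame in the header)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    landmarks = {}
    for tooth in arch.teeth:
        fdi = tooth.fdi_id
        crown = tooth.crown_world()
        root = tooth.root_world()
        for kind, mesh in (("crown", crown), ("root", root)):
            p = out / f"{prefix}_{fdi}_{kind}.stl"
            _write_stl(mesh, p)
            written[f"{fdi}_{kind}"] = p
        lm = tooth.world_landmarks()
        entry = {
            "crown_point": lm.crown_point.tolist(),
            "root_point": lm.root_point.tolist(),
            "CR": lm.CR.tolist(),
            "LA": lm.LA.tolist(),
        }
        entry.update({f"cusp_{k}": v.tolist() for k, v in lm.cusp_points.items()})
        landmarks[str(fdi)] = entry
    header = {}
    if arch.frame is not None:
        f = arch.frame
        header = {"origin": f.origin.tolist(), "x_axis": f.x_axis.tolist(),
                  "y_axis": f.y_axis.tolist(), "z_axis": f.z_axis.tolist()}
    table = {"frame": header, "units": "mm", "landmarks": landmarks}
    lm_path = out / f"{prefix}_landmarks.json"
    lm_path.write_text(json.dumps(table, indent=2))
    written["landmarks"] = lm_path
    return written


def export_aligner(aligner: AlignerModel, out_dir, stem: str = "aligner") -> Dict[str, Path]:
    """Inner-surface STL plus band metadata / delta-sum history as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stl_path = out / f"{stem}_inner.stl"
    _write_stl(aligner.as_mesh(), stl_path)
    bands = []
    for b in aligner.bands:
        bands.append({
            "mesial_tooth": b.mesial_tooth, "distal_tooth": b.distal_tooth,
            "C_i": b.C_i.tolist(), "C_j": b.C_j.tolist(),
            "P_i": b.P_i.tolist(), "P_j": b.P_j.tolist(), "P_c": b.P_c.tolist(),
            "direction": b.direction.tolist(), "d_mm": b.d,
            "delta_sum_mm": b.delta_sum, "kt_history": b.kt_history,
        })
    meta = {"thickness_mm": aligner.thickness,
            "elastic_modulus_MPa": aligner.elastic_modulus,
            "poisson": aligner.poisson, "bands": bands}
    json_path = out / f"{stem}_bands.json"
    json_path.write_text(json.dumps(meta, indent=2))
    return {"stl": stl_path, "bands": json_path}
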