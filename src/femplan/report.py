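"""End-to-end planning pipeline and structured reports.

``plan`` runs the full chain on an in-memory mesh: anatomical frame ->
axes -> ridge profile and cortex points -> initial AP sizing -> FRAC
search -> overhang/underhang size refinement -> resection planes,
thicknesses and notching.  ``run_plan`` wraps it with file I/O;
``compare_configs`` tabulates several alignment configurations against
each other the way planning studies do (axis choice changes resected
bone in predictable directions).

Left femurs are mirrored to the internal right-handed convention before
processing and every reported 3D point is mirrored back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .axes import AxisSet, anatomical_frame, angle_report, build_axis_set
from .cortex import CortexPoints, compute_frac_point, compute_sizing_point, extract_ridge_profile
from .implant import ImplantFamily, load_family, select_initial_size
from .mesh_io import read_mesh, validate_watertight
from .placement import PlacementConfig, build_resection_planes, compute_bone_ap_height
from .resection import (
    detect_notching,
    evaluate_cut_fits,
    measure_thicknesses,
    refine_size,
)

__all__ = ["PlanReport", "StageError", "plan", "run_plan", "compare_configs",
           "load_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PlanReport:
    mesh_id: str
    side: str
    config: PlacementConfig
    axes: AxisSet
    angles: dict
    cortex: CortexPoints
    family_name: str
    initial_size: str
    final_size: str
    out_of_range: bool
    refinement: dict
    thicknesses: dict
    fits: dict
    notch: dict
    version: str = __version__

    def to_dict(self) -> dict:
        mirror = self.side == "left"

        def pt(p):
            p = np.asarray(p, float).copy()
            if mirror:
                p[0] = -p[0]
            return [round(float(x), 4) for x in p]

        axes_d = self.axes.to_dict()

        def mirror_tree(obj):
            if isinstance(obj, dict):
                return {k: mirror_tree(v) for k, v in obj.items()}
            if isinstance(obj, list) and len(obj) == 3 and all(isinstance(x, float) for x in obj):
                return pt(obj)
            return obj

        cortex_d = self.cortex.to_dict()
        cortex_d.pop("frac_search_trace", None)
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "software_version": self.version,
            "mesh_id": self.mesh_id,
            "side": self.side,
            "config": self.config.to_dict(),
            "axes": mirror_tree(axes_d),
            "angles": self.angles,
            "cortex_points": mirror_tree(cortex_d),
            "family": self.family_name,
            "initial_size": self.initial_size,
            "final_size": self.final_size,
            "size_out_of_range": self.out_of_range,
            "refinement": self.refinement,
            "thicknesses": self.thicknesses,
            "fits": self.fits,
            "notch": self.notch,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _fit_summary(fits: dict) -> dict:
    return {
        cut: {
            "max_overhang": round(rep.max_overhang, 3),
            "max_underhang": round(rep.max_underhang, 3),
            "zones": {z: {k: round(v, 3) for k, v in d.items()}
                      for z, d in rep.zones.items()},
        }
        for cut, rep in fits.items()
    }


def plan(mesh: trimesh.Trimesh, family: ImplantFamily,
         config: PlacementConfig | None = None, side: str = "right",
         mesh_id: str = "<memory>") -> PlanReport:
    """Run the full planning pipeline on a validated femur mesh."""
    config = config or PlacementConfig()
    work = mesh
    if side == "left":
        work = trimesh.Trimesh(vertices=mesh.vertices * [-1.0, 1.0, 1.0],
                               faces=mesh.faces[:, ::-1], process=False)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    wt = stage("mesh_io", validate_watertight, work)
    if not wt.watertight:
        raise StageError("mesh_io", RuntimeError(
            f"mesh not watertight ({len(wt.boundary_edges)} boundary edges)"))
    frame = stage("frames_axes", anatomical_frame, work, "right")
    axes = stage("frames_axes", build_axis_set, work, frame)
    angles = angle_report(axes)
    profile = stage("cortex_points", extract_ridge_profile, work, axes.frame, axes.landmarks)
    sizing_pt = stage("cortex_points", compute_sizing_point, profile)

    posterior = (axes.landmarks.posterior_medial, axes.landmarks.posterior_lateral)
    ap0 = compute_bone_ap_height(axes.frame, sizing_pt, posterior)
    size_probe, _ = stage("implant_model", select_initial_size, ap0, family)

    def cortex_for(size) -> CortexPoints:
        return stage("cortex_points", compute_frac_point, work, axes.frame, axes,
                     size, config, profile=profile, landmarks=axes.landmarks)

    cortex = cortex_for(size_probe)
    ref = cortex.reference(config.anterior_reference)
    ap1 = compute_bone_ap_height(axes.frame, ref, posterior)
    initial, out_of_range = stage("implant_model", select_initial_size, ap1, family)

    def evaluator(size):
        cx = cortex_for(size) if config.anterior_reference.upper() == "FRAC" else cortex
        planes = stage("placement", build_resection_planes, work, axes, size,
                       cx.reference(config.anterior_reference), config)
        return stage("resection_analysis", evaluate_cut_fits, work, planes, size)["distal"]

    final, refinement = stage("resection_analysis", refine_size,
                              family, initial, evaluator, config)
    cortex = cortex_for(final) if config.anterior_reference.upper() == "FRAC" else cortex
    planes = stage("placement", build_resection_planes, work, axes, final,
                   cortex.reference(config.anterior_reference), config)
    fits = stage("resection_analysis", evaluate_cut_fits, work, planes, final)
    th = stage("resection_analysis", measure_thicknesses, planes, axes.landmarks)
    notch = stage("resection_analysis", detect_notching, work, planes.anterior,
                  planes.flange_proximal_pd, axes.frame)

    return PlanReport(
        mesh_id=mesh_id,
        side=side,
        config=config,
        axes=axes,
        angles=angles.to_dict(),
        cortex=cortex,
        family_name=family.name,
        initial_size=initial.label,
        final_size=final.label,
        out_of_range=out_of_range,
        refinement={
            "steps": [{"size": s, "action": a,
                       "max_overhang": round(r.max_overhang, 3),
                       "max_underhang": round(r.max_underhang, 3)}
                      for s, r, a in refinement["steps"]],
            "unsatisfiable": refinement["unsatisfiable"],
        },
        thicknesses=th.to_dict(),
        fits=_fit_summary(fits),
        notch={
            "notched": bool(notch.notched),
            "notch_depth": round(float(notch.notch_depth), 3),
        },
    )


def run_plan(mesh_path: str | Path, family_path: str | Path,
             config: PlacementConfig | dict | None = None,
             side: str = "right", out_dir: str | Path | None = None) -> PlanReport:
    """File-based entry point: read inputs, plan, optionally write outputs.

    Writes ``plan.json`` and ``thicknesses.csv`` into ``out_dir`` when
    given.  Re-running with identical inputs produces identical files.
    """
    if isinstance(config, dict):
        config = PlacementConfig.from_dict(config)
    try:
        mesh = read_mesh(mesh_path)
    except Exception as exc:
        raise StageError("mesh_io", exc) from exc
    try:
        family = load_family(family_path)
    except Exception as exc:
        raise StageError("implant_model", exc) from exc
    report = plan(mesh, family, config, side=side, mesh_id=str(mesh_path))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "plan.json").write_text(report.to_json())
        row = dict(report.thicknesses)
        row["final_size"] = report.final_size
        pd.DataFrame([row]).to_csv(out / "thicknesses.csv", index=False)
        trace = pd.DataFrame([
            {"s": r["s"], "h": r["h"], "notch_depth": r["notch_depth"],
             "undercut_area": r["undercut_area"], "balance": r["balance"]}
            for r in report.cortex.frac_search_trace
        ])
        trace.to_csv(out / "trace.csv", index=False)
    return report


def load_report(path: str | Path) -> dict:
    """Load a previously written plan.json, enforcing the schema version."""
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"plan report schema version {version!r} is not supported by this "
            f"femplan (expects {REPORT_SCHEMA_VERSION})")
    return data


def compare_configs(mesh: trimesh.Trimesh | str | Path, family: ImplantFamily | str | Path,
                    configs: list[PlacementConfig], side: str = "right") -> pd.DataFrame:
    """Plan the same bone under several configurations and tabulate.

    Rows are configurations; columns are the six thickness variables,
    totals, fit maxima and the notch flag, plus paired differences
    against the first configuration.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    if not isinstance(mesh, trimesh.Trimesh):
        mesh = read_mesh(mesh)
    if not isinstance(family, ImplantFamily):
        family = load_family(family)
    rows = []
    for cfg in configs:
        rep = plan(mesh, family, cfg, side=side)
        row = {
            "axis": cfg.longitudinal_axis,
            "rotation": cfg.rotation_reference,
            "anterior_ref": cfg.anterior_reference,
            "final_size": rep.final_size,
            **rep.thicknesses,
            "max_overhang": rep.fits["distal"]["max_overhang"],
            "max_underhang": rep.fits["distal"]["max_underhang"],
            "notched": rep.notch["notched"],
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    num = [c for c in ("FACL", "FPCL", "FACM", "FPCM", "FDCL", "FDCM",
                       "total_lateral", "total_medial")]
    for c in num:
        df[f"d_{c}"] = df[c] - df[c].iloc[0]
    return df
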