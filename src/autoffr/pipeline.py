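"""End-to-end orchestration: CT volume in, cFFR out.

Stages: load -> crop -> aorta landmark -> multi-threshold DBSCAN
segmentation -> per-side centreline/radius geometry -> 1D mesh -> coupled
1D-0D solve -> cFFR.  Every stage records status, timing and artefact
paths in a run manifest that is written even when a stage fails.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from ._version import __version__
from .aorta import ReferencePoint, detect_aorta_center
from .centerline import (
    CenterlineTree,
    clean_voxel_volume,
    estimate_radii,
    extract_skeleton,
    extract_surface,
    prune_spurs,
    regularize_mask,
    split_branches,
)
from .clustering import segment_coronary
from .config import PipelineConfig
from .constitutive import MMHG
from .ffr import FFRResult, compute_cffr, min_radius_location
from .filtering import preprocess_volume
from .mesh import Mesh1D, build_mesh1d, centerline_to_csv, mesh_to_vtk
from .solver import CoronarySolver, Solution
from .volume import BinaryVolume, ImageVolume, crop_cardiac_region, load_nifti, read_dicom_series
from .waveforms import InflowWaveform, scaled_plv
from .windkessel import distribute_terminals, total_resistance

log = logging.getLogger(__name__)

STAGES = ("load", "crop", "aorta", "segment", "geometry", "solve", "ffr")


@dataclass
class RunManifest:
    """Per-stage record of an end-to-end run."""

    input_path: str
    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float, outputs=None, error=None):
        self.stages[stage] = {
            "status": status,
            "seconds": round(seconds, 3),
            "outputs": outputs or [],
            "error": error,
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_volume(path: str, config: PipelineConfig) -> ImageVolume:
    """Read a DICOM series directory or a NIfTI volume."""
    if os.path.isdir(path):
        return read_dicom_series(path, config.window_center, config.window_width)
    return load_nifti(path)


def geometry_for_side(
    mask: BinaryVolume, ref_world: np.ndarray, config: PipelineConfig
) -> tuple[Mesh1D, CenterlineTree]:
    """Voxel mask of one coronary side -> radius-annotated tree -> 1D mesh."""
    cl = config.cleaning
    cleaned = clean_voxel_volume(
        mask, cl.root_eps, cl.root_min_pts, cl.vessel_eps, cl.vessel_min_pts
    )
    if cl.regularize:
        cleaned = regularize_mask(cleaned)
    skel = extract_skeleton(cleaned)
    tree = prune_spurs(split_branches(skel), cl.spur_min_length_mm)
    verts, _ = extract_surface(cleaned)
    tree = estimate_radii(tree, verts, method=config.geometry.radius_method)
    mesh = build_mesh1d(
        tree,
        spacing=config.geometry.mesh_spacing_cm,
        trim_nodes=config.geometry.trim_nodes,
        root_point=ref_world,
    )
    return mesh, tree


def solve_side(mesh: Mesh1D, side: str, config: PipelineConfig) -> Solution:
    """Build boundary conditions for one coronary side and run the solver."""
    wk = config.windkessel
    inf = config.inflow
    q_mean = inf.q_mean_left if side == "left" else inf.q_mean_right
    if (inf.table_left if side == "left" else inf.table_right) is not None:
        import pandas as pd

        tbl = pd.read_csv(inf.table_left if side == "left" else inf.table_right)
        inflow = InflowWaveform.from_samples(
            tbl.iloc[:, 0].to_numpy(), tbl.iloc[:, 1].to_numpy(), inf.period_s, side
        )
    else:
        inflow = InflowWaveform.default(side, q_mean, inf.period_s)
    targets = config.perfusion
    rcor = total_resistance(targets, side)
    plv = scaled_plv(
        side, inf.period_s, wk.plv_scale_left if side == "left" else wk.plv_scale_right
    )
    beds = distribute_terminals(
        mesh,
        rcor,
        config.blood,
        config.wall,
        power=wk.murray_power,
        total_compliance=wk.total_compliance,
        c1_fraction=wk.c1_fraction,
        plv=plv,
        pven=wk.pven_mmhg * MMHG,
    )
    solver = CoronarySolver(mesh, inflow, beds, config.blood, config.wall, config.solver)
    return solver.solve()


def _ref_world(ref: ReferencePoint, vol: ImageVolume) -> np.ndarray:
    return vol.index_to_world([ref.mean_slice, ref.center[0], ref.center[1]])[0]


def run_pipeline(
    input_path: str,
    config: PipelineConfig | None = None,
    outdir: str | None = None,
    stop_after: str | None = None,
    location: tuple[str, int, float] | None = None,
    overwrite: bool = False,
) -> tuple[dict[str, FFRResult], RunManifest]:
    """Execute the full workflow on a CT volume.

    ``location`` is (side, vessel_id, arc_length_cm) for the cFFR query; by
    default cFFR is reported at the minimum-radius node of each side.
    ``stop_after`` names a stage for early exit.  Returns per-side results
    and the run manifest; intermediate artefacts are persisted to
    ``outdir`` when given.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(input_path, config.snapshot(), config.seed)
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    state: dict = {}
    results: dict[str, FFRResult] = {}

    def stage(name):
        def deco(fn):
            def wrapped():
                t0 = time.perf_counter()
                try:
                    out = fn()
                except Exception as err:
                    manifest.record(name, "failed", time.perf_counter() - t0, error=str(err))
                    if outdir:
                        manifest.write(os.path.join(outdir, "manifest.json"))
                    raise StageFailure(name, err) from err
                manifest.record(name, "ok", time.perf_counter() - t0,
                                outputs=state.get(f"{name}_outputs"))
                return out
            return wrapped
        return deco

    @stage("load")
    def _load():
        state["vol"] = load_volume(input_path, config)
        log.info("loaded volume %s spacing %s", state["vol"].shape, state["vol"].spacing)

    @stage("crop")
    def _crop():
        state["cropped"] = crop_cardiac_region(state["vol"], config.crop)
        log.info("cropped to %s", state["cropped"].shape)

    @stage("aorta")
    def _aorta():
        a = config.aorta
        try:
            state["ref"] = detect_aorta_center(
                state["cropped"], (a.slice_start, a.slice_stop), a.r_min, a.r_max,
                a.canny_low, a.canny_high,
            )
        except Exception:
            if outdir:  # diagnostic dump of the searched slices
                np.savetxt(
                    os.path.join(outdir, "aorta_search_slice.txt"),
                    state["cropped"].voxels[a.slice_start],
                    fmt="%.1f",
                )
            raise
        log.info("aorta reference %s radius %.1f px", state["ref"].center, state["ref"].radius)

    @stage("segment")
    def _segment():
        cropped = state["cropped"]
        pre = preprocess_volume(cropped, config.filters)
        left, right = segment_coronary(
            cropped, config.filters, config.clustering, state["ref"], precomputed=pre
        )
        state["masks"] = {"left": left, "right": right}
        log.info("segmented: left %d voxels, right %d voxels",
                 left.mask.sum(), right.mask.sum())

    @stage("geometry")
    def _geometry():
        ref_w = _ref_world(state["ref"], state["cropped"])
        meshes, trees = {}, {}
        for side, mask in state["masks"].items():
            meshes[side], trees[side] = geometry_for_side(mask, ref_w, config)
            log.info("%s side: %d vessels, %d nodes", side, len(meshes[side].vessels),
                     sum(v.n_nodes for v in meshes[side].vessels))
        state["meshes"], state["trees"] = meshes, trees

    @stage("solve")
    def _solve():
        state["solutions"] = {
            side: solve_side(mesh, side, config) for side, mesh in state["meshes"].items()
        }

    @stage("ffr")
    def _ffr():
        for side, sol in state["solutions"].items():
            if location is not None and location[0] == side:
                vid, x = location[1], location[2]
            else:
                vid, x = min_radius_location(sol)
            results[side] = compute_cffr(sol, vid, x)
            log.info("%s cFFR = %.3f at vessel %d x=%.2f cm", side, results[side].cffr, vid, x)

    for name, fn in zip(STAGES, (_load, _crop, _aorta, _segment, _geometry, _solve, _ffr)):
        fn()
        if stop_after == name:
            break

    if outdir:
        write_outputs(results, state, manifest, outdir, overwrite=overwrite)
    return results, manifest


def write_outputs(results, state, manifest: RunManifest, outdir: str, overwrite: bool = False):
    """Persist result JSON, centreline CSV, mesh JSON, VTK polyline, manifest."""
    os.makedirs(outdir, exist_ok=True)
    result_path = os.path.join(outdir, "ffr_result.json")
    if os.path.exists(result_path) and not overwrite:
        raise FileExistsError(f"{result_path} exists (pass overwrite=True to replace)")
    with open(result_path, "w") as fh:
        json.dump({side: r.to_dict() for side, r in results.items()}, fh, indent=1)
    for side, tree in state.get("trees", {}).items():
        centerline_to_csv(tree, os.path.join(outdir, f"centreline_{side}.csv"))
    for side, mesh in state.get("meshes", {}).items():
        mesh.to_json(os.path.join(outdir, f"mesh1d_{side}.json"))
        mesh_to_vtk(mesh, os.path.join(outdir, f"centreline_{side}.vtk"))
    manifest.write(os.path.join(outdir, "manifest.json"))
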