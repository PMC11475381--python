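"""Shared fixtures: blood/wall properties and cached heavy phantom runs."""

from __future__ import annotations

import os

import numpy as np
import pytest
from hypothesis import settings

import autoffr as af
from autoffr.config import PipelineConfig
from autoffr.pipeline import run_pipeline
from autoffr.volume import save_nifti

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood():
    return af.BloodProperties()


@pytest.fixture(scope="session")
def wall():
    return af.WallLaw()


@pytest.fixture(scope="session")
def rigid_wall():
    # wave speed scaled x1000: wall stiffness up x1e6, area effectively frozen
    return af.WallLaw(k1=2.0e13, k3=8.65e11)


def steady_tube_solution(r0, blood, wall, q=1.0, length=10.0, spacing=0.01, severity=0.0,
                         mu=None):
    """Steady 1D-0D solve of a (possibly stenosed) tube; returns Solution."""
    b = af.BloodProperties(mu=mu) if mu is not None else blood
    mesh, _, _ = af.make_stenosed_mesh1d(r0=r0, severity=severity, length=length,
                                         spacing=spacing)
    rcor = af.total_resistance(af.PerfusionTargets(), "left")
    beds = af.distribute_terminals(mesh, rcor, b, af.WallLaw())
    solver = af.CoronarySolver(mesh, af.InflowWaveform.constant(q), beds, b, wall,
                               af.SolverConfig(steady=True))
    return solver.solve()


def run_geometry_chain(noise_sigma, seed=3, severity=0.5, mesh_spacing=0.05):
    """Stenosed-tube phantom -> (mesh, skeleton, truth helpers).

    With noise, the full filtering chain is applied at the lowest standard
    grey threshold (the multi-threshold union is bounded by it); noise-free
    phantoms feed the exact truth mask forward.
    """
    from scipy import ndimage as ndi

    from autoffr.filtering import FilterParams, candidate_mask, preprocess_volume

    spec = af.stenosed_tube_spec(severity=severity, noise_sigma=noise_sigma, seed=seed)
    vol, truth, axes, radii, _ = af.make_tube_phantom(spec)
    if noise_sigma > 0:
        fp = FilterParams()
        den, ves = preprocess_volume(vol, fp)
        mask = candidate_mask(den, ves, fp.grey_thresholds[0], fp, vol.spacing)
        mask = af.clean_voxel_volume(mask)
        mask = af.regularize_mask(mask)
    else:
        mask = truth
    skel = af.extract_skeleton(mask)
    tree = af.prune_spurs(af.split_branches(skel))
    verts, _ = af.extract_surface(mask)
    tree = af.estimate_radii(tree, verts)
    mesh = af.build_mesh1d(tree, spacing=mesh_spacing, trim_nodes=5)
    return {"mesh": mesh, "skeleton": skel, "truth": truth, "spec": spec,
            "axes": axes, "radii": radii, "vol": vol}


def true_radius_profile_mm(z_mm):
    """Analytic r(z) of the standard stenosed-tube phantom (severity 0.5)."""
    ks = np.linspace(4, 135, 41)
    centre = 0.5 * (ks[0] + ks[-1])
    width = 0.33 * (ks[-1] - ks[0])
    u = (np.asarray(z_mm) / 0.625 - centre) / (width / 2.0)
    dip = np.where(np.abs(u) < 1, 0.5 * (1 + np.cos(np.pi * u)), 0.0)
    return 4 * 0.458 * (1 - 0.5 * dip)


STENOSED_THROAT_Z_MM = 0.5 * (4 + 135) * 0.625


@pytest.fixture(scope="session")
def geometry_noisefree():
    return run_geometry_chain(0.0)


@pytest.fixture(scope="session")
def geometry_noisy():
    return run_geometry_chain(10.0)


def pipeline_config_fast() -> PipelineConfig:
    """Desk-scale pipeline settings: steady haemodynamics, 0.05 cm mesh."""
    cfg = PipelineConfig()
    cfg.solver.steady = True
    cfg.geometry.mesh_spacing_cm = 0.05
    return cfg


def run_coronary_pipeline(tmpdir, seed=5, outname="out"):
    vol, labels = af.make_coronary_phantom(seed=seed)
    path = os.path.join(tmpdir, "phantom.nii")
    save_nifti(vol, path)
    outdir = os.path.join(tmpdir, outname)
    res, man = run_pipeline(path, pipeline_config_fast(), outdir=outdir)
    return {"results": res, "manifest": man, "outdir": outdir, "labels": labels,
            "volume_path": path}


@pytest.fixture(scope="session")
def coronary_run(tmp_path_factory):
    """One full end-to-end run on the standard coronary phantom."""
    d = tmp_path_factory.mktemp("coronary")
    return run_coronary_pipeline(str(d))


@pytest.fixture(scope="session")
def coronary_segmentation():
    """Aorta landmark + multi-threshold segmentation of the standard phantom."""
    vol, labels = af.make_coronary_phantom(seed=5)
    cvol = af.crop_cardiac_region(vol, ((0, 1), (0.2, 0.8), (0.2, 0.8)))
    ref = af.detect_aorta_center(cvol)
    left, right = af.segment_coronary(cvol, ref=ref)
    return {"labels": labels, "ref": ref, "left": left, "right": right}


def crop_label(mask):
    """Apply the default central-60% in-plane crop to a full-volume label."""
    return mask[:, 51:205, 51:205]
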