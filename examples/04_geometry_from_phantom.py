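"""Lumen geometry recovery from a noisy CT-like tube phantom.

Renders a stenosed tube (radius 4 in-plane voxels narrowing to 2) with
sigma = 10 Gaussian noise, pushes it through the filtering chain, thinning
and radius estimation, and compares the recovered radius profile with the
phantom's analytic ground truth.
"""

import numpy as np

import autoffr as af
from autoffr.filtering import FilterParams, candidate_mask, preprocess_volume

spec = af.stenosed_tube_spec(severity=0.5, noise_sigma=10.0, seed=3)
vol, truth, axes, radii, _ = af.make_tube_phantom(spec)
print(f"phantom {vol.shape}, lumen {truth.mask.sum()} voxels, noise sigma 10")

fp = FilterParams()
den, ves = preprocess_volume(vol, fp)
mask = candidate_mask(den, ves, fp.grey_thresholds[0], fp, vol.spacing)
mask = af.regularize_mask(af.clean_voxel_volume(mask))
print(f"candidate mask: {mask.mask.sum()} voxels "
      f"({(mask.mask & truth.mask).sum() / truth.mask.sum():.1%} of true lumen)")

skel = af.extract_skeleton(mask)
tree = af.prune_spurs(af.split_branches(skel))
verts, _ = af.extract_surface(mask)
tree = af.estimate_radii(tree, verts)
mesh = af.build_mesh1d(tree, spacing=0.05, trim_nodes=5)

v = max(mesh.vessels, key=lambda q: q.n_nodes)
r_true = np.interp(v.points[:, 2], axes[0][:, 0], radii[0])
err = np.abs(v.r0 * 10 - r_true)
vid, x = af.min_radius_location(mesh)
vv = mesh.vessel(vid)
z_throat = vv.points[int(np.argmin(np.abs(vv.x - x)))][2]

print(f"1D mesh: {v.n_nodes} nodes at {mesh.spacing * 10:.1f} mm spacing")
print(f"radius profile error: max {err.max():.2f} mm, mean {err.mean():.2f} mm")
print(f"throat located at z = {z_throat:.1f} mm (truth {0.5 * (4 + 135) * 0.625:.1f} mm)")

# Errors stay below about half a voxel: the ring-median radius estimator and
# the short running median absorb the staircase quantisation of the
# binarised lumen boundary.
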