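"""Computed fractional flow reserve (cFFR) from a solved pressure field.

cFFR at a location is the ratio of the cycle-mean pressure there to the
cycle-mean pressure at the inlet of the same coronary tree.  The ratio of
cycle means (rather than a single cycle phase) is the implemented
convention; it reduces to the plain pressure ratio for steady solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import MMHG
from .solver import Solution


@dataclass
class FFRResult:
    """cFFR at one vessel location, with the underlying mean pressures."""

    vessel_id: int
    x_cm: float
    Pa_mean_mmhg: float
    Pd_mean_mmhg: float
    cffr: float

    def to_dict(self) -> dict:
        return {
            "vessel_id": self.vessel_id,
            "x_cm": self.x_cm,
            "Pa_mean_mmHg": self.Pa_mean_mmhg,
            "Pd_mean_mmHg": self.Pd_mean_mmhg,
            "cFFR": self.cffr,
        }


def compute_cffr(sol: Solution, vessel_id: int, x: float) -> FFRResult:
    """cFFR = mean distal pressure / mean inlet pressure of that tree."""
    node = sol.node_index(vessel_id, x)  # raises KeyError listing valid ids
    inlet = sol.root_inlet_node(vessel_id)
    pd = sol.mean_pressure(node)
    pa = sol.mean_pressure(inlet)
    if pa <= 0:
        raise ValueError("non-positive mean inlet pressure; solution unusable")
    v = sol.mesh.vessel(vessel_id)
    i = int(np.argmin(np.abs(v.x - x)))
    return FFRResult(vessel_id, float(v.x[i]), pa / MMHG, pd / MMHG, pd / pa)


def min_radius_location(sol_or_mesh, band: float = 0.005) -> tuple[int, float]:
    """Default query point: the minimum-radius node of the tree.

    Radii recovered from voxel data are quantised, so the raw argmin lands
    at an arbitrary edge of the near-minimum plateau; the throat is taken
    as the node nearest the centroid of all nodes within ``band`` (cm) of
    the minimum radius.
    """
    mesh = sol_or_mesh.mesh if isinstance(sol_or_mesh, Solution) else sol_or_mesh
    best = None
    for v in mesh.vessels:
        i = int(np.argmin(v.r0))
        if best is None or v.r0[i] < best[1]:
            best = (v, float(v.r0[i]))
    v, rmin = best
    sel = v.r0 <= rmin + band
    xc = float(v.x[sel].mean())
    i = int(np.argmin(np.abs(v.x - xc)))
    return v.vessel_id, float(v.x[i])
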