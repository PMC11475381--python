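"""One-dimensional vessel mesh: equidistant nodes with reference radii.

A :class:`Mesh1D` is a rooted tree of vessels.  Each vessel carries node
arc-lengths ``x`` (cm, equidistant), reference radii ``r0`` (cm) and the
derived reference areas ``A0 = pi r0^2`` (cm^2); connectivity is a parent
index per vessel.  Radii along each branch are resampled from the
centreline with PCHIP (shape-preserving, no overshoot).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .centerline import Branch, CenterlineTree

log = logging.getLogger(__name__)

MM_TO_CM = 0.1
DEFAULT_SPACING_CM = 0.01  # 0.1 mm nodes


@dataclass
class Vessel1D:
    """A single 1D vessel: equidistant nodes along the centreline arc."""

    vessel_id: int
    x: np.ndarray  # arc length from vessel inlet, cm
    r0: np.ndarray  # reference radius per node, cm
    parent: int | None = None
    name: str = ""
    points: np.ndarray | None = None  # optional (n,3) world mm for export

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        if len(self.x) != len(self.r0):
            raise ValueError("x and r0 must have the same length")
        if np.any(self.r0 <= 0):
            raise ValueError("reference radii must be > 0")

    @property
    def A0(self) -> np.ndarray:
        return np.pi * self.r0**2

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else 0.0


@dataclass
class Mesh1D:
    """Rooted tree of 1D vessels with a common target node spacing (cm)."""

    vessels: list[Vessel1D]
    spacing: float = DEFAULT_SPACING_CM

    def __post_init__(self) -> None:
        ids = [v.vessel_id for v in self.vessels]
        if len(set(ids)) != len(ids):
            raise ValueError("vessel ids must be unique")

    def vessel(self, vid: int) -> Vessel1D:
        for v in self.vessels:
            if v.vessel_id == vid:
                return v
        raise KeyError(f"no vessel with id {vid}; valid ids: {sorted(v.vessel_id for v in self.vessels)}")

    def children(self, vid: int) -> list[Vessel1D]:
        return [v for v in self.vessels if v.parent == vid]

    def roots(self) -> list[Vessel1D]:
        return [v for v in self.vessels if v.parent is None]

    def terminals(self) -> list[Vessel1D]:
        child_of = {v.parent for v in self.vessels if v.parent is not None}
        return [v for v in self.vessels if v.vessel_id not in child_of]

    def is_terminal(self, vid: int) -> bool:
        return not self.children(vid)

    def to_json(self, path: str | None = None) -> str:
        obj = {
            "spacing_cm": self.spacing,
            "vessels": [
                {
                    "id": v.vessel_id,
                    "parent": v.parent,
                    "name": v.name,
                    "x_cm": v.x.tolist(),
                    "r0_cm": v.r0.tolist(),
                    "points_mm": None if v.points is None else np.asarray(v.points).tolist(),
                }
                for v in self.vessels
            ],
        }
        text = json.dumps(obj, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "Mesh1D":
        """Load from a JSON string or file path."""
        try:
            obj = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source) as fh:
                obj = json.load(fh)
        vessels = [
            Vessel1D(
                d["id"],
                np.array(d["x_cm"]),
                np.array(d["r0_cm"]),
                d.get("parent"),
                d.get("name", ""),
                None if d.get("points_mm") is None else np.array(d["points_mm"]),
            )
            for d in obj["vessels"]
        ]
        return cls(vessels, obj.get("spacing_cm", DEFAULT_SPACING_CM))


def _resample_branch(
    branch: Branch, spacing_cm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """PCHIP-resample one branch to equidistant nodes; None if too short."""
    s_mm = branch.arc_length()
    # drop duplicate arc-length samples (degenerate steps)
    keep = np.concatenate([[True], np.diff(s_mm) > 1e-12])
    s = s_mm[keep] * MM_TO_CM
    r = branch.radii[keep] * MM_TO_CM
    p = branch.points[keep]
    if len(s) < 2 or s[-1] < spacing_cm:
        return None
    n = max(int(round(s[-1] / spacing_cm)) + 1, 2)
    x = np.linspace(0.0, s[-1], n)
    r_i = PchipInterpolator(s, r)(x)
    pts = np.column_stack([PchipInterpolator(s, p[:, d])(x) for d in range(3)])
    return x, r_i, pts


def build_mesh1d(
    tree: CenterlineTree,
    spacing: float = DEFAULT_SPACING_CM,
    trim_nodes: int = 5,
    root_point: np.ndarray | None = None,
) -> Mesh1D:
    """Resample a radius-annotated centreline tree to an equidistant 1D mesh.

    The root branch is the one with a free end nearest ``root_point`` (world
    mm; e.g. the aortic reference) and vessels are oriented away from it.
    Radius vs arc-length uses monotone shape-preserving (PCHIP)
    interpolation, so interpolated radii never overshoot the sampled range.
    The first ``trim_nodes`` nodes of the root vessel are discarded: the
    ostial region is unreliable after aortic-root cleaning.
    """
    branches = [b for b in tree.branches if b.radii is not None and len(b) >= 2]
    if not branches:
        raise ValueError("tree has no branches with radii")

    # free ends (not attached to a junction) are root candidates
    candidates: list[tuple[int, bool]] = []  # (branch index, use_start_end)
    for bi, b in enumerate(branches):
        if b.start_junction is None:
            candidates.append((bi, True))
        if b.end_junction is None:
            candidates.append((bi, False))
    if not candidates:
        candidates = [(0, True)]
    if root_point is None:
        bi, at_start = candidates[0]
    else:
        rp = np.asarray(root_point, dtype=float)

        def dist(c):
            b = branches[c[0]]
            pt = b.points[0] if c[1] else b.points[-1]
            return float(np.linalg.norm(pt - rp))

        bi, at_start = min(candidates, key=dist)

    # orient the whole tree by BFS from the root branch
    oriented: list[tuple[Branch, int | None]] = []  # (branch, parent_vessel_id)
    root_branch = branches[bi] if at_start else branches[bi].reversed()
    visited = {bi}
    queue: list[tuple[Branch, int | None]] = [(root_branch, None)]
    order: list[tuple[Branch, int | None, int]] = []  # branch, parent vid, own vid
    next_id = 0
    id_of_branch: dict[int, int] = {}
    frontier = [(root_branch, None, bi)]
    while frontier:
        br, parent_vid, orig_idx = frontier.pop(0)
        vid = next_id
        next_id += 1
        order.append((br, parent_vid, vid))
        end_j = br.end_junction
        if end_j is None:
            continue
        for cj, cb in enumerate(branches):
            if cj in visited:
                continue
            if cb.start_junction == end_j:
                visited.add(cj)
                frontier.append((cb, vid, cj))
            elif cb.end_junction == end_j:
                visited.add(cj)
                frontier.append((cb.reversed(), vid, cj))

    vessels: list[Vessel1D] = []
    collapsed: dict[int, int | None] = {}  # vid -> surviving parent vid
    for br, parent_vid, vid in order:
        res = _resample_branch(br, spacing)
        if parent_vid in collapsed:
            parent_vid = collapsed[parent_vid]
        if res is None:
            log.warning("branch %d shorter than node spacing: collapsed into parent", vid)
            collapsed[vid] = parent_vid
            continue
        x, r, pts = res
        if parent_vid is None and trim_nodes > 0:
            if len(x) <= trim_nodes + 2:
                raise ValueError("root vessel too short to trim its ostial nodes")
            x, r, pts = x[trim_nodes:] - x[trim_nodes], r[trim_nodes:], pts[trim_nodes:]
        if len(x) < 3:
            log.warning("branch %d has <3 nodes after resampling: collapsed", vid)
            collapsed[vid] = parent_vid
            continue
        vessels.append(Vessel1D(vid, x, r, parent_vid, points=pts))
    if not vessels:
        raise ValueError("no vessel survived resampling")
    return Mesh1D(vessels, spacing)


def centerline_to_csv(tree: CenterlineTree, path: str) -> None:
    """Write branch points and radii as CSV (branch_id, x,y,z mm, radius mm)."""
    import pandas as pd

    rows = []
    for bid, b in enumerate(tree.branches):
        r = b.radii if b.radii is not None else np.full(len(b), np.nan)
        for p, rad in zip(b.points, r):
            rows.append((bid, p[0], p[1], p[2], rad))
    pd.DataFrame(rows, columns=["branch_id", "x_mm", "y_mm", "z_mm", "radius_mm"]).to_csv(
        path, index=False
    )


def mesh_to_vtk(mesh: Mesh1D, path: str) -> None:
    """Write mesh polylines as a legacy-ASCII VTK file (viewable in ParaView)."""
    pts, lines = [], []
    for v in mesh.vessels:
        if v.points is None:
            continue
        base = len(pts)
        pts.extend(v.points.tolist())
        lines.append(list(range(base, base + len(v.points))))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoronary centreline\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(map(str, [len(l), *l])) + "\n")
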