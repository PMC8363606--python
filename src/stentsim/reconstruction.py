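"""3D bifurcation reconstruction from biplane projections and OCT pullbacks.

The backbone centerline is fused from two angiographic projection curves
(parallel-projection model, solved by per-sample least squares).  OCT
frames are completed (missing outer-border arcs under 180 degrees are
interpolated, larger ones discard the frame), aligned along the
centerline using the carina as the reference point, lofted into inner
and outer surfaces, and the two branches are merged into one watertight
bifurcation lumen/wall by an implicit union remeshed with marching
cubes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .geometry import Centerline, cumulative_arclength, resample_polyline
from .synthetic import N_THETA, OCTFrame, OCTPullback

__all__ = [
    "ProjectionCurve",
    "BifurcationGeometry",
    "PositionedFrame",
    "TubeField",
    "centerline_from_biplane",
    "complete_outer_contour",
    "align_pullback",
    "loft_branch",
    "merge_branches",
    "slice_profile",
]

DISCARD_THRESHOLD_DEG = 180.0  # missing-arc rule; exactly 180 is interpolated


@dataclass
class ProjectionCurve:
    """A planar projection of a vessel centerline from one angiographic view."""

    points: np.ndarray  # (N, 2) in-plane coordinates, mm
    view_angle: float  # degrees
    normal: np.ndarray  # viewing direction (3,)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    silhouette_halfwidth: np.ndarray | None = None  # local vessel half-width, mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("projection curve needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("projection curve has non-finite coordinates")

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        phi = np.deg2rad(self.view_angle)
        u = np.array([-np.sin(phi), np.cos(phi), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return u, v

    @property
    def length(self) -> float:
        return float(cumulative_arclength(self.points)[-1])


def centerline_from_biplane(
    curve_a: ProjectionCurve, curve_b: ProjectionCurve, n: int = 200, branch: str = "MV"
) -> Centerline:
    """Fuse two projection curves into a 3D centerline.

    Correspondence between the two images uses the shared image axis:
    both views look along horizontal directions, so the vertical image
    coordinate v equals the world z axis in either view.  When both
    curves are monotone in v, samples are paired at equal v (the
    parallel-projection analogue of epipolar matching) and the fusion
    is exact for noiseless projections of the same curve; otherwise the
    pairing falls back to common arclength fraction (best fit).  Each
    3D point is the least-squares solution of the four in-plane
    projection equations of its two images.
    """
    if abs(curve_a.view_angle - curve_b.view_angle) < 30.0:
        raise ValueError("views closer than 30 degrees cannot be fused reliably")
    la, lb = curve_a.length, curve_b.length
    if la <= 0 or lb <= 0:
        raise ValueError("degenerate projection curve")
    if abs(la - lb) / max(la, lb) > 0.20:
        warnings.warn(
            f"projected curve lengths differ by more than 20% ({la:.1f} vs {lb:.1f} mm); "
            "best-fit fusion proceeds",
            stacklevel=2,
        )
    va, vb = curve_a.points[:, 1], curve_b.points[:, 1]
    if _strictly_monotone(va) and _strictly_monotone(vb):
        sa = np.sort(va)
        sb = np.sort(vb)
        lo, hi = max(sa[0], sb[0]), min(sa[-1], sb[-1])
        if hi <= lo:
            raise ValueError("projection curves do not overlap along the shared axis")
        grid = np.linspace(lo, hi, n)
        pa = np.column_stack([_interp_by_v(grid, curve_a.points), grid])
        pb = np.column_stack([_interp_by_v(grid, curve_b.points), grid])
    else:
        pa = resample_polyline(curve_a.points, n)
        pb = resample_polyline(curve_b.points, n)
    ua, va = curve_a.basis
    ub, vb = curve_b.basis
    m = np.vstack([ua, va, ub, vb])  # (4, 3)
    rhs = np.column_stack([pa[:, 0], pa[:, 1], pb[:, 0], pb[:, 1]])  # (n, 4)
    sol, *_ = np.linalg.lstsq(m, rhs.T, rcond=None)
    return Centerline(sol.T, branch=branch)


def _strictly_monotone(v: np.ndarray) -> bool:
    d = np.diff(v)
    return bool(np.all(d > 0) or np.all(d < 0))


def _interp_by_v(grid: np.ndarray, points: np.ndarray) -> np.ndarray:
    v, u = points[:, 1], points[:, 0]
    if v[0] > v[-1]:
        v, u = v[::-1], u[::-1]
    return np.interp(grid, v, u)


def complete_outer_contour(frame: OCTFrame) -> tuple[OCTFrame, bool]:
    """Fill missing outer-border arcs, or flag the frame for discarding.

    If the outer border is missing over less than 180 degrees of the
    circumference the gap is interpolated from the visible border with a
    periodic cubic spline; if more than 180 degrees are missing the
    frame is discarded.  Exactly 180 degrees is treated as interpolable.
    Returns ``(frame, discard_flag)``; a frame with no missing arcs is
    returned unchanged.
    """
    missing = frame.total_missing_deg
    if missing == 0.0:
        return frame, False
    if missing > DISCARD_THRESHOLD_DEG:
        return frame, True
    visible = ~np.isnan(frame.outer_radius)
    if visible.sum() < 4:
        return frame, True
    ang = frame.angles_deg[visible]
    rad = frame.outer_radius[visible]
    # periodic cubic spline over [0, 360)
    ang_ext = np.concatenate([ang, [ang[0] + 360.0]])
    rad_ext = np.concatenate([rad, [rad[0]]])
    spline = CubicSpline(ang_ext, rad_ext, bc_type="periodic")
    filled = frame.outer_radius.copy()
    gap = ~visible
    query = frame.angles_deg[gap]
    # wrap queries into the spline's domain
    query = np.where(query < ang_ext[0], query + 360.0, query)
    filled[gap] = spline(query)
    return replace(frame, outer_radius=filled, missing_arcs=()), False


@dataclass
class PositionedFrame:
    """An OCT frame placed in 3D: origin + in-plane axes + contours."""

    arclength: float
    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    frame: OCTFrame
    discarded: bool = False

    def lumen_ring(self) -> np.ndarray:
        th = np.deg2rad(self.frame.angles_deg)
        r = self.frame.lumen_radius
        return (
            self.origin
            + np.outer(r * np.cos(th), self.e1)
            + np.outer(r * np.sin(th), self.e2)
        )

    def outer_ring(self) -> np.ndarray:
        th = np.deg2rad(self.frame.angles_deg)
        r = self.frame.outer_radius
        return (
            self.origin
            + np.outer(r * np.cos(th), self.e1)
            + np.outer(r * np.sin(th), self.e2)
        )


def align_pullback(
    pullback: OCTPullback,
    centerline: Centerline,
    sb_direction: np.ndarray | None = None,
) -> list[PositionedFrame]:
    """Place pullback frames along the centerline, carina as reference.

    Frame ``i`` lands at arclength ``carina + (carina_index - i) * spacing``
    for a distal-to-proximal pullback (``direction=-1``).  Orientation
    follows a rotation-minimizing frame whose absolute twist is fixed by
    the SB-ostium direction at the carina frame (angle zero points at
    the ostium); missing-border frames are completed first and flagged
    discarded when beyond the 180-degree rule.  Frames whose target
    arclength falls off the centerline are truncated with a warning.
    """
    if centerline.carina_arclength is None:
        raise ValueError("centerline must carry a carina arclength")
    carina_s = centerline.carina_arclength
    e1_start = sb_direction if sb_direction is not None else None
    frames_axes = centerline.frames(e1_start=_project_normal(e1_start, centerline))
    s_min, s_max = centerline.arclength[0], centerline.arclength[-1]
    placed: list[PositionedFrame] = []
    truncated = 0
    for i, f in enumerate(pullback.frames):
        s = carina_s + pullback.direction * (i - pullback.carina_frame_index) * pullback.frame_spacing
        if s < s_min - 1e-9 or s > s_max + 1e-9:
            truncated += 1
            continue
        completed, discard = complete_outer_contour(f)
        p, _t, e1, e2 = centerline.frame_at(float(np.clip(s, s_min, s_max)), frames=frames_axes)
        placed.append(
            PositionedFrame(arclength=float(s), origin=p, e1=e1, e2=e2, frame=completed, discarded=discard)
        )
    if truncated:
        warnings.warn(f"{truncated} frames extended beyond the centerline and were truncated", stacklevel=2)
    placed.sort(key=lambda pf: pf.arclength)
    return placed


def _project_normal(v: np.ndarray | None, centerline: Centerline) -> np.ndarray | None:
    if v is None:
        return None
    t0 = centerline.points[1] - centerline.points[0]
    t0 = t0 / np.linalg.norm(t0)
    w = np.asarray(v, float) - (np.asarray(v, float) @ t0) * t0
    n = np.linalg.norm(w)
    return None if n < 1e-9 else w / n


def loft_branch(
    positioned: list[PositionedFrame], which: str = "lumen"
) -> trimesh.Trimesh:
    """Loft positioned frames into a capped triangulated surface.

    Discarded frames are skipped and the loft spans the longer gap.
    Requires at least two usable frames.
    """
    usable = [p for p in positioned if not p.discarded]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable (non-discarded) frames to loft")
    rings = [p.lumen_ring() if which == "lumen" else p.outer_ring() for p in usable]
    n_theta = rings[0].shape[0]
    verts = np.vstack(rings)
    faces = []
    for i in range(len(rings) - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    centers = np.array([r.mean(axis=0) for r in (rings[0], rings[-1])])
    verts = np.vstack([verts, centers])
    c0, c1 = len(verts) - 2, len(verts) - 1
    base = (len(rings) - 1) * n_theta
    for j in range(n_theta):
        faces.append([c0, (j + 1) % n_theta, j])
        faces.append([c1, base + j, base + (j + 1) % n_theta])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


@dataclass
class BifurcationGeometry:
    """Reconstructed bifurcation: merged surfaces plus per-branch slice rings."""

    lumen: trimesh.Trimesh
    wall: trimesh.Trimesh | None
    mv_centerline: Centerline
    sb_centerline: Centerline | None
    mv_frames: list[PositionedFrame]
    sb_frames: list[PositionedFrame] = field(default_factory=list)
    carina_point: np.ndarray | None = None
    sb_ostium_area: float | None = None
    discard_log: dict = field(default_factory=dict)

    def frames_for(self, branch: str) -> list[PositionedFrame]:
        return self.mv_frames if branch == "MV" else self.sb_frames


class TubeField:
    """Analytic "inside" field of a tube: centerline points + radii.

    A point lies inside when its distance to the nearest centerline
    sample is below that sample's radius.  Used for implicit boolean
    union without any mesh ray-casting.
    """

    def __init__(self, centerline_points: np.ndarray, radii: np.ndarray):
        from scipy.spatial import cKDTree

        self.points = np.asarray(centerline_points, float)
        self.radii = np.asarray(radii, float)
        if len(self.points) != len(self.radii):
            raise ValueError("one radius per centerline point required")
        self._tree = cKDTree(self.points)

    @classmethod
    def from_frames(cls, frames: list[PositionedFrame]) -> "TubeField":
        usable = [p for p in frames if not p.discarded]
        centers = np.array([p.origin for p in usable])
        radii = np.array([np.sqrt(p.frame.lumen_area() / np.pi) for p in usable])
        return cls(centers, radii)

    def signed(self, pts: np.ndarray) -> np.ndarray:
        """Positive inside: r(nearest) - distance-to-centerline."""
        d, idx = self._tree.query(np.asarray(pts, float))
        return self.radii[idx] - d


def merge_branches(
    mv_field: TubeField,
    sb_field: TubeField,
    carina_point: np.ndarray,
    mv_frames: list[PositionedFrame] | None = None,
    sb_frames: list[PositionedFrame] | None = None,
    mv_centerline: Centerline | None = None,
    sb_centerline: Centerline | None = None,
    mv_wall_field: TubeField | None = None,
    sb_wall_field: TubeField | None = None,
    pitch: float = 0.15,
    bifurcation_angle_deg: float | None = None,
    sb_radius: float | None = None,
) -> BifurcationGeometry:
    """Union the MV and SB tubes into one watertight bifurcation.

    The union is computed implicitly: the maximum of the two signed
    tube fields is sampled on a regular grid and its zero level set is
    remeshed with marching cubes, which guarantees a watertight result.
    The SB ostium area is estimated analytically as the ellipse cut by
    the oblique SB cylinder (pi * r_sb^2 / sin(angle)) when angle and
    radius are given.
    """
    if isinstance(mv_field, trimesh.Trimesh) or isinstance(sb_field, trimesh.Trimesh):
        raise TypeError("merge_branches takes TubeField branch descriptions")
    if not _fields_intersect(mv_field, sb_field):
        raise ValueError("branch surfaces do not intersect near the carina; cannot merge")
    merged = _implicit_union([mv_field, sb_field], pitch=pitch)
    wall = None
    if mv_wall_field is not None and sb_wall_field is not None:
        wall = _implicit_union([mv_wall_field, sb_wall_field], pitch=pitch)
    ostium_area = None
    if bifurcation_angle_deg is not None and sb_radius is not None:
        ostium_area = float(np.pi * sb_radius**2 / abs(np.sin(np.deg2rad(bifurcation_angle_deg))))
    return BifurcationGeometry(
        lumen=merged,
        wall=wall,
        mv_centerline=mv_centerline,
        sb_centerline=sb_centerline,
        mv_frames=mv_frames or [],
        sb_frames=sb_frames or [],
        carina_point=np.asarray(carina_point, float),
        sb_ostium_area=ostium_area,
    )


def _fields_intersect(a: TubeField, b: TubeField) -> bool:
    return bool(np.any(a.signed(b.points) > -b.radii) and np.any(b.signed(a.points) > -a.radii))


def _implicit_union(fields: list[TubeField], pitch: float) -> trimesh.Trimesh:
    from skimage import measure

    pts = np.vstack([f.points for f in fields])
    rmax = max(float(f.radii.max()) for f in fields)
    lo = pts.min(axis=0) - rmax - 3 * pitch
    hi = pts.max(axis=0) + rmax + 3 * pitch
    nx, ny, nz = [max(8, int(np.ceil((hi[k] - lo[k]) / pitch)) + 1) for k in range(3)]
    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], ny)
    zs = np.linspace(lo[2], hi[2], nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    field = np.full(len(grid), -np.inf)
    for f in fields:
        field = np.maximum(field, f.signed(grid))
    vol = field.reshape(nx, ny, nz)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0)
    scale = np.array([xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0]])
    verts = lo + verts * scale
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh


def slice_profile(
    frames_or_geometry,
    spacing: float = 0.5,
    branch: str = "MV",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-slice lumen area and area-equivalent diameter vs arclength.

    Accepts a list of positioned frames or a BifurcationGeometry (whose
    per-branch frames are used).  Slice planes are perpendicular to the
    centerline; area comes from the frame contour polygon and the
    diameter is 2*sqrt(A/pi).  Output is interpolated to a uniform grid
    at the requested spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if isinstance(frames_or_geometry, BifurcationGeometry):
        frames = frames_or_geometry.frames_for(branch)
    else:
        frames = frames_or_geometry
    usable = [p for p in frames if not p.discarded]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable frames for a profile")
    s = np.array([p.arclength for p in usable])
    areas = np.array([p.frame.lumen_area() for p in usable])
    order = np.argsort(s)
    s, areas = s[order], areas[order]
    grid = np.arange(s[0], s[-1] + 1e-9, spacing)
    a_grid = np.interp(grid, s, areas)
    d_grid = 2.0 * np.sqrt(a_grid / np.pi)
    return grid, a_grid, d_grid
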