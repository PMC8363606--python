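"""3D stent reconstruction from OCT strut-point detections.

Pipeline: per-frame strut detections (angle, radial distance) are
flattened to a 2D axial/circumferential chart (unrolling the lumen
cylinder), registered rigidly (axial shift + periodic circumferential
rotation) against the unrolled 2D design pattern, matched one-to-one to
pattern nodes by minimum-cost bipartite assignment with a distance
gate, wrapped back onto the 3D lumen centerline, and finally given
strut volume by sweeping the strut cross-section along each edge.

Strut detection itself is simulated here (sampling a deployed stent at
OCT frame planes); image-based segmentation is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .geometry import Centerline
from .devices import StentDesign, StentGeometry, build_nominal_stent

__all__ = [
    "StrutPointCloud",
    "UnrolledCloud",
    "StentGraphMatch",
    "simulate_detections",
    "unroll",
    "register_pattern",
    "wrap_to_3d",
    "add_strut_volume",
]

ASSIGNMENT_GATE_MM = 0.3  # max unrolled distance for a point-node match


@dataclass
class StrutPointCloud:
    """Strut detections: per frame a list of (angle deg, radial mm)."""

    frame_arclengths: np.ndarray  # (F,) axial positions, mm
    detections: list[np.ndarray]  # per frame (k, 2): angle_deg, radius_mm

    def __post_init__(self) -> None:
        for det in self.detections:
            if len(det) and (np.any(det[:, 1] <= 0) or np.any((det[:, 0] < 0) | (det[:, 0] >= 360))):
                raise ValueError("detections need radius > 0 and angle in [0, 360)")

    @property
    def n_points(self) -> int:
        return sum(len(d) for d in self.detections)

    def export_csv(self, path) -> None:
        rows = ["frame,arclength_mm,angle_deg,radius_mm"]
        for i, (s, det) in enumerate(zip(self.frame_arclengths, self.detections)):
            for a, r in det:
                rows.append(f"{i},{s},{a},{r}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


@dataclass
class UnrolledCloud:
    """Detections flattened to (axial mm, circumferential arc mm)."""

    points: np.ndarray  # (N, 2)
    period: float  # mean local circumference, mm
    frame_of_point: np.ndarray  # (N,) frame index
    radii_of_point: np.ndarray  # (N,) lumen radius used per point


@dataclass
class StentGraphMatch:
    design: StentDesign
    pattern: StentGeometry
    node_positions: np.ndarray  # (M, 2) matched unrolled coordinates per pattern node (NaN = unmatched)
    matched: np.ndarray  # (M,) bool
    residuals: np.ndarray  # (M,) distance per matched node, NaN otherwise
    rotation_mm: float = 0.0
    axial_shift_mm: float = 0.0
    period: float = 0.0
    low_confidence: bool = False

    @property
    def mean_residual(self) -> float:
        r = self.residuals[self.matched]
        return float(np.mean(r)) if len(r) else float("nan")

    def missing_nodes(self) -> np.ndarray:
        return np.nonzero(~self.matched)[0]


def simulate_detections(
    stent: StentGeometry,
    frame_spacing: float = 0.2,
    arclength_offset: float = 0.0,
    seed: int | None = None,
    drop_fraction: float = 0.0,
    snap_to_frames: bool = True,
) -> StrutPointCloud:
    """Sample node-like strut detections of a (deployed) stent.

    Each stent node is snapped to its nearest OCT frame plane
    (``snap_to_frames=False`` keeps exact axial positions, emulating
    sub-frame interpolation); its (angle, radius) are kept exact,
    emulating sharp strut blooms.  An optional seeded fraction of
    points is dropped to emulate missed detections.
    """
    z = stent.nodes_zthr[:, 0] + arclength_offset
    th = np.rad2deg(stent.nodes_zthr[:, 1]) % 360.0
    r = stent.nodes_zthr[:, 2]
    z0, z1 = z.min(), z.max()
    frames = np.arange(z0, z1 + frame_spacing, frame_spacing)
    keep = np.ones(len(z), dtype=bool)
    if drop_fraction > 0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(z)) >= drop_fraction
    dets: list[np.ndarray] = [np.empty((0, 2)) for _ in frames]
    axials = frames.copy()
    fi = np.clip(np.round((z - z0) / frame_spacing).astype(int), 0, len(frames) - 1)
    if snap_to_frames:
        for i in range(len(frames)):
            mask = (fi == i) & keep
            dets[i] = np.column_stack([th[mask], r[mask]])
        return StrutPointCloud(frame_arclengths=axials, detections=dets)
    # exact axial positions: one pseudo-frame per node
    order = np.argsort(z[keep])
    zk, thk, rk = z[keep][order], th[keep][order], r[keep][order]
    return StrutPointCloud(
        frame_arclengths=zk,
        detections=[np.array([[a, rr]]) for a, rr in zip(thk, rk)],
    )


def unroll(cloud: StrutPointCloud, lumen_radii: np.ndarray | None = None) -> UnrolledCloud:
    """Flatten detections to (z, theta * r_mean) with a stored period.

    ``lumen_radii`` gives the lumen radius per frame; when omitted the
    detection radii themselves are used.  The map is invertible given
    the same radii.
    """
    pts, frames, radii = [], [], []
    for i, (s, det) in enumerate(zip(cloud.frame_arclengths, cloud.detections)):
        if len(det) == 0:
            continue
        if lumen_radii is not None:
            r_frame = lumen_radii[i]
            if not np.isfinite(r_frame):
                raise ValueError(f"missing lumen radius for frame {i}")
            r_use = np.full(len(det), float(r_frame))
        else:
            r_use = det[:, 1]
        for (a, _r), ru in zip(det, r_use):
            pts.append([s, np.deg2rad(a) * ru])
            frames.append(i)
            radii.append(ru)
    if not pts:
        raise ValueError("no detections to unroll")
    radii = np.asarray(radii)
    return UnrolledCloud(
        points=np.asarray(pts),
        period=float(2.0 * np.pi * radii.mean()),
        frame_of_point=np.asarray(frames),
        radii_of_point=radii,
    )


def _pattern_unrolled(design: StentDesign, radius: float) -> tuple[StentGeometry, np.ndarray]:
    pattern = build_nominal_stent(design)
    z = pattern.nodes_zthr[:, 0]
    arc = pattern.nodes_zthr[:, 1] * radius
    return pattern, np.column_stack([z, arc])


def _periodic_nn_cost(points: np.ndarray, nodes: np.ndarray, period: float) -> float:
    dz = points[:, 0][:, None] - nodes[:, 0][None, :]
    da = points[:, 1][:, None] - nodes[:, 1][None, :]
    da = (da + period / 2.0) % period - period / 2.0
    d = np.sqrt(dz**2 + da**2)
    return float(d.min(axis=1).mean())


def register_pattern(
    cloud2d: UnrolledCloud,
    design: StentDesign,
    n_rot: int = 64,
    gate_mm: float = ASSIGNMENT_GATE_MM,
) -> StentGraphMatch:
    """Rigid 2D registration + one-to-one assignment of points to nodes.

    The registration searches circumferential rotations (periodic) and
    axial shifts minimizing the mean nearest-neighbor distance, then
    solves a minimum-cost bipartite matching with a distance gate.
    Edges are inherited from the pattern topology.  A mean residual
    above half the gate flags the match as low-confidence (never a
    silent failure).
    """
    mean_r = cloud2d.period / (2.0 * np.pi)
    pattern, nodes = _pattern_unrolled(design, mean_r)
    if cloud2d.points.shape[0] < 0.5 * len(nodes):
        raise ValueError(
            f"only {cloud2d.points.shape[0]} detections for {len(nodes)} pattern nodes "
            "(< 50%): too sparse to register"
        )
    period = cloud2d.period
    pts = cloud2d.points
    # coarse grid search: rotation x axial shift
    rot_grid = np.linspace(0.0, period, n_rot, endpoint=False)
    z_span = pts[:, 0].min() - nodes[:, 0].min()
    shift_grid = z_span + np.linspace(-1.0, 1.0, 21)
    best = (np.inf, 0.0, 0.0)
    for rot in rot_grid:
        for shift in shift_grid:
            moved = nodes + [shift, rot]
            moved[:, 1] %= period
            wrapped_pts = pts.copy()
            wrapped_pts[:, 1] %= period
            cost = _periodic_nn_cost(wrapped_pts, moved, period)
            if cost < best[0]:
                best = (cost, rot, shift)
    _, rot, shift = best
    # refine axial shift locally
    for shift2 in shift + np.linspace(-0.1, 0.1, 21):
        moved = nodes + [shift2, rot]
        moved[:, 1] %= period
        cost = _periodic_nn_cost(pts % [np.inf, period], moved, period)
        if cost < best[0]:
            best = (cost, rot, shift2)
    _, rot, shift = best

    moved = nodes + [shift, rot]
    moved[:, 1] %= period
    wrapped = pts.copy()
    wrapped[:, 1] %= period
    dz = wrapped[:, 0][:, None] - moved[:, 0][None, :]
    da = wrapped[:, 1][:, None] - moved[:, 1][None, :]
    da = (da + period / 2.0) % period - period / 2.0
    dist = np.sqrt(dz**2 + da**2)
    cost_m = np.where(dist <= gate_mm, dist, 1e6)
    row, col = linear_sum_assignment(cost_m)
    m = len(nodes)
    node_pos = np.full((m, 2), np.nan)
    matched = np.zeros(m, dtype=bool)
    residuals = np.full(m, np.nan)
    for pi, ni in zip(row, col):
        if dist[pi, ni] <= gate_mm:
            matched[ni] = True
            node_pos[ni] = wrapped[pi]
            residuals[ni] = dist[pi, ni]
    low_conf = (np.nanmean(residuals) if matched.any() else np.inf) > gate_mm / 2.0
    if low_conf:
        warnings.warn("registration residual high: match flagged low-confidence", stacklevel=2)
    return StentGraphMatch(
        design=design,
        pattern=pattern,
        node_positions=node_pos,
        matched=matched,
        residuals=residuals,
        rotation_mm=float(rot),
        axial_shift_mm=float(shift),
        period=period,
        low_confidence=bool(low_conf),
    )


def wrap_to_3d(
    match: StentGraphMatch,
    centerline: Centerline,
    lumen_radius_at: callable = None,
    arclength_offset: float = 0.0,
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Map matched nodes back onto the 3D lumen along the centerline.

    Unmatched nodes are filled from the registered pattern position so
    the output graph stays complete; each node sits on the lumen
    surface pulled inward by half the strut thickness.  Returns
    (node_xyz, typed edges) with the pattern's topology.
    """
    period = match.period
    mean_r = period / (2.0 * np.pi)
    half_strut = match.design.strut_section.radial_thickness / 2.0
    frames = centerline.frames()
    pos2d = match.node_positions.copy()
    # fill unmatched nodes from the registered pattern
    pattern_nodes = match.pattern.nodes_zthr
    for ni in match.missing_nodes():
        z = pattern_nodes[ni, 0] + match.axial_shift_mm
        arc = (pattern_nodes[ni, 1] * mean_r + match.rotation_mm) % period
        pos2d[ni] = [z, arc]
    xyz = np.empty((len(pos2d), 3))
    for i, (z, arc) in enumerate(pos2d):
        s = float(np.clip(z + arclength_offset, centerline.arclength[0], centerline.arclength[-1]))
        p, _t, e1, e2 = centerline.frame_at(s, frames=frames)
        r_lumen = mean_r if lumen_radius_at is None else float(lumen_radius_at(s))
        theta = arc / mean_r
        r_node = r_lumen - half_strut
        xyz[i] = p + r_node * (np.cos(theta) * e1 + np.sin(theta) * e2)
    edges = list(match.pattern.edges)
    return xyz, edges


def add_strut_volume(
    node_xyz: np.ndarray,
    edges: list[tuple[int, int, str]],
    section,
    sides: int = 12,
) -> trimesh.Trimesh:
    """Sweep the strut cross-section along each edge (capped tubes).

    Zero-length edges are skipped with a warning.  The result is the
    union-free concatenation of per-strut watertight tubes.
    """
    radius = (
        section.diameter / 2.0
        if section.shape == "circular"
        else float(np.sqrt(section.area / np.pi))
    )
    tubes = []
    skipped = 0
    for i, j, _kind in edges:
        a, b = node_xyz[i], node_xyz[j]
        length = float(np.linalg.norm(b - a))
        if length < 1e-9:
            skipped += 1
            continue
        tube = trimesh.creation.cylinder(
            radius=radius, segment=np.vstack([a, b]), sections=sides
        )
        tubes.append(tube)
    if skipped:
        warnings.warn(f"skipped {skipped} zero-length strut edges", stacklevel=2)
    if not tubes:
        raise ValueError("no non-degenerate edges to sweep")
    return trimesh.util.concatenate(tubes)
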