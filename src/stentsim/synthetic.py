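"""Synthetic coronary bifurcation anatomies and OCT-like pullbacks.

No public dataset exists for the imaging this pipeline consumes, so this
module generates every input analytically: tapered bifurcations with
cosine-shaped stenoses, per-frame OCT lumen/outer contours with plaque
composition arcs and optional signal-dropout arcs, parallel biplane
projections, uniform-wall bench silicone variants, and procedure tables
following the provisional / TAP / culotte step grammar.

Everything is deterministic for a fixed seed; randomness enters only
through explicit ``numpy.random.Generator`` objects derived from the
seed parameters — there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import trimesh

from .geometry import Centerline, rotation_minimizing_frames
from .procedures import TEMPLATES, DeviceRef, Placement, ProcedureStep, ProcedureTable

__all__ = [
    "Stenosis",
    "CompositionZone",
    "AnatomyParams",
    "Branch",
    "BifurcationAnatomy",
    "OCTFrame",
    "OCTPullback",
    "BenchModel",
    "generate_bifurcation",
    "generate_oct_pullback",
    "project_to_planes",
    "generate_bench_variant",
    "generate_procedure",
    "default_devices",
]

N_THETA = 64  # angular samples per contour / surface ring
DS = 0.25  # centerline sampling step, mm


@dataclass(frozen=True)
class Stenosis:
    """A cosine-tapered diameter reduction on one branch."""

    branch: str  # "MV" | "SB"
    center_arclength: float  # mm, from the proximal MV inlet
    diameter_stenosis: float  # fractional reduction, 0 <= ds < 1
    length: float  # mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.diameter_stenosis < 1.0):
            raise ValueError("diameter stenosis fraction must be in [0, 1)")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")


@dataclass(frozen=True)
class CompositionZone:
    """Plaque composition fractions (lipid, fibrous, calcified) over an arclength span."""

    branch: str
    start: float
    end: float
    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("composition fractions must be non-negative")


@dataclass(frozen=True)
class AnatomyParams:
    proximal_mv_diameter: float = 3.5
    distal_mv_diameter: float = 3.0
    sb_diameter: float = 2.5
    bifurcation_angle: float = 60.0  # degrees between MV and SB axes
    mv_length: float = 40.0
    sb_length: float = 20.0
    carina_arclength: float | None = None  # default: mid-MV
    wall_thickness: float = 0.9
    stenoses: tuple[Stenosis, ...] = ()
    composition_zones: tuple[CompositionZone, ...] = ()
    curvature_radius: float | None = None  # mm; None = straight MV
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.proximal_mv_diameter, self.distal_mv_diameter, self.sb_diameter) <= 0:
            raise ValueError("diameters must be positive")
        if self.distal_mv_diameter > self.proximal_mv_diameter:
            raise ValueError("distal MV diameter must not exceed proximal")
        if self.mv_length <= 0 or self.sb_length <= 0:
            raise ValueError("branch lengths must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")

    @property
    def carina(self) -> float:
        return self.mv_length / 2.0 if self.carina_arclength is None else self.carina_arclength


@dataclass
class Branch:
    """One branch: centerline plus analytic per-slice profiles."""

    centerline: Centerline
    diameter: np.ndarray  # lumen diameter per centerline sample, mm
    wall_thickness: np.ndarray  # mm
    composition: np.ndarray  # (N, 3) lipid / fibrous / calcified fractions
    healthy_diameter: np.ndarray | None = None  # disease-free taper profile, mm

    @property
    def label(self) -> str:
        return self.centerline.branch

    @property
    def arclength(self) -> np.ndarray:
        return self.centerline.arclength

    def diameter_at(self, s) -> np.ndarray | float:
        return np.interp(s, self.arclength, self.diameter)

    def healthy_diameter_at(self, s) -> np.ndarray | float:
        ref = self.diameter if self.healthy_diameter is None else self.healthy_diameter
        return np.interp(s, self.arclength, ref)

    def thickness_at(self, s) -> np.ndarray | float:
        return np.interp(s, self.arclength, self.wall_thickness)

    def composition_at(self, s) -> np.ndarray:
        s = np.atleast_1d(s)
        out = np.column_stack(
            [np.interp(s, self.arclength, self.composition[:, k]) for k in range(3)]
        )
        return out[0] if out.shape[0] == 1 else out


@dataclass
class BifurcationAnatomy:
    """Ground-truth bifurcation: MV and SB branches meeting at the carina."""

    mv: Branch
    sb: Branch
    carina_arclength: float
    sb_direction: np.ndarray  # unit vector of the SB axis at its ostium
    params: AnatomyParams

    def branch(self, label: str) -> Branch:
        if label == "MV":
            return self.mv
        if label == "SB":
            return self.sb
        raise KeyError(f"unknown branch {label!r}")

    @property
    def carina_point(self) -> np.ndarray:
        return self.mv.centerline.point_at(self.carina_arclength)

    def surface(self, branch: str, which: str = "lumen", n_theta: int = N_THETA) -> trimesh.Trimesh:
        """Watertight capped tube mesh of one branch (lumen or outer wall)."""
        b = self.branch(branch)
        radii = b.diameter / 2.0
        if which == "outer":
            radii = radii + b.wall_thickness
        elif which != "lumen":
            raise ValueError("which must be 'lumen' or 'outer'")
        return tube_mesh(b.centerline.points, radii, n_theta=n_theta)

    def export(self, directory) -> None:
        """STL surfaces, centerline CSVs and a JSON parameter echo."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for label in ("MV", "SB"):
            for which in ("lumen", "outer"):
                self.surface(label, which).export(d / f"{label.lower()}_{which}.stl")
            b = self.branch(label)
            arr = np.column_stack([b.centerline.points, b.arclength])
            np.savetxt(
                d / f"{label.lower()}_centerline.csv",
                arr,
                delimiter=",",
                header="x,y,z,arclength",
                comments="",
            )
        with open(d / "params.json", "w") as fh:
            json.dump(_params_to_dict(self.params), fh, indent=1)


@dataclass
class OCTFrame:
    """One OCT cross-section in frame polar coordinates.

    ``outer_radius`` is NaN inside missing (signal-dropout) arcs; the
    contours are star-shaped, hence simple, by construction.
    """

    angles_deg: np.ndarray  # (N,), in [0, 360)
    lumen_radius: np.ndarray  # (N,), mm
    outer_radius: np.ndarray  # (N,), mm, NaN where the border is missing
    missing_arcs: tuple[tuple[float, float], ...] = ()
    composition_arcs: tuple[tuple[float, float, str, float], ...] = ()
    arclength: float | None = None  # generator ground truth, mm

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, float)
        if np.any(a < 0) or np.any(a >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.asarray(self.lumen_radius) <= 0):
            raise ValueError("lumen radii must be positive")
        for i, (s0, e0) in enumerate(self.missing_arcs):
            for s1, e1 in self.missing_arcs[i + 1 :]:
                if _arcs_overlap((s0, e0), (s1, e1)):
                    raise ValueError("missing arcs must be disjoint")

    @property
    def total_missing_deg(self) -> float:
        return float(sum((e - s) % 360.0 or (360.0 if e != s else 0.0) for s, e in self.missing_arcs))

    def lumen_xy(self) -> np.ndarray:
        th = np.deg2rad(self.angles_deg)
        return np.column_stack([self.lumen_radius * np.cos(th), self.lumen_radius * np.sin(th)])

    def lumen_area(self) -> float:
        xy = self.lumen_xy()
        x, y = xy[:, 0], xy[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class OCTPullback:
    frames: list[OCTFrame]  # ordered distal -> proximal
    frame_spacing: float  # mm
    branch: str
    carina_frame_index: int
    direction: int = -1  # arclength change per frame index: -1 = decreasing

    def __post_init__(self) -> None:
        if self.frame_spacing <= 0:
            raise ValueError("frame spacing must be positive")
        if not (0 <= self.carina_frame_index < len(self.frames)):
            raise ValueError("carina frame index out of range")

    def export(self, directory) -> None:
        """One CSV per frame plus a JSON manifest."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(self.frames):
            tissue = _tissue_labels(f)
            rows = []
            for a, rl, ro, tl in zip(f.angles_deg, f.lumen_radius, f.outer_radius, tissue):
                ro_s = "NA" if np.isnan(ro) else f"{ro:.6f}"
                rows.append(f"{a:.4f},{rl:.6f},{ro_s},{tl}")
            (d / f"frame_{i:04d}.csv").write_text(
                "angle_deg,lumen_radius_mm,outer_radius_mm,tissue_label\n" + "\n".join(rows) + "\n"
            )
        manifest = {
            "frame_spacing_mm": self.frame_spacing,
            "branch": self.branch,
            "carina_frame_index": self.carina_frame_index,
            "direction": self.direction,
            "n_frames": len(self.frames),
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


@dataclass
class BenchModel:
    """Uniform-wall silicone variant of an anatomy (no plaque zones)."""

    anatomy: BifurcationAnatomy
    silicone_thickness: float
    material: str = "silicone"

    def plaque_score(self, branch: str, s: float) -> None:
        """Bench walls carry no plaque; the score is undefined (None sentinel)."""
        return None

    def c10(self) -> float:
        from .materials import default_table

        return default_table().hyperelastic[self.material].c[0]


# ---------------------------------------------------------------------------
# generation


def _stenosis_factor(s: np.ndarray, stenoses: Sequence[Stenosis], branch: str) -> np.ndarray:
    """Multiplicative diameter factor: cosine-tapered dips, 1 elsewhere."""
    f = np.ones_like(s)
    for st in stenoses:
        if st.branch != branch:
            continue
        u = (s - st.center_arclength) / st.length  # +-0.5 at the shoulders
        mask = np.abs(u) <= 0.5
        reduction = st.diameter_stenosis * 0.5 * (1.0 + np.cos(2.0 * np.pi * u[mask]))
        f[mask] *= 1.0 - reduction
    return f


def _mv_centerline_points(params: AnatomyParams) -> np.ndarray:
    n = int(round(params.mv_length / DS)) + 1
    s = np.linspace(0.0, params.mv_length, n)
    if params.curvature_radius is None or np.isinf(params.curvature_radius):
        return np.column_stack([np.zeros(n), np.zeros(n), s])
    r = params.curvature_radius
    phi = s / r
    return np.column_stack([r * (1.0 - np.cos(phi)), np.zeros(n), r * np.sin(phi)])


def generate_bifurcation(params: AnatomyParams) -> BifurcationAnatomy:
    """Build the analytic ground-truth bifurcation from parameters.

    Slice diameters equal the taper profile times the cosine stenosis
    factor; surfaces are lofted circular tubes.  A stenosis whose span
    comes within one local diameter of the carina is rejected: the
    carina is the fixed co-registration landmark and must stay clean.
    """
    carina = params.carina
    if not (0.0 < carina < params.mv_length):
        raise ValueError("carina arclength must lie inside the MV")
    for st in params.stenoses:
        ref = params.proximal_mv_diameter
        near = abs(st.center_arclength - carina) < st.length / 2.0 + ref
        if st.branch == "MV" and near:
            raise ValueError(
                f"stenosis at {st.center_arclength} mm overlaps the carina "
                f"(at {carina} mm) within one diameter"
            )
        if st.branch == "SB" and st.center_arclength - carina < ref:
            raise ValueError("SB stenosis too close to the ostium/carina")

    mv_pts = _mv_centerline_points(params)
    mv_cl = Centerline(mv_pts, branch="MV", carina_arclength=carina)
    s_mv = mv_cl.arclength
    taper = params.proximal_mv_diameter + (
        params.distal_mv_diameter - params.proximal_mv_diameter
    ) * (s_mv / params.mv_length)
    d_mv = taper * _stenosis_factor(s_mv, params.stenoses, "MV")

    # SB: straight, leaving the carina point at the bifurcation angle,
    # rotated from the MV tangent within the x-z plane.
    t_mv, e1, _ = mv_cl.frames(e1_start=np.array([1.0, 0.0, 0.0]))
    idx = int(np.argmin(np.abs(s_mv - carina)))
    t_c, n_c = t_mv[idx], e1[idx]
    ang = np.deg2rad(params.bifurcation_angle)
    sb_dir = np.cos(ang) * t_c + np.sin(ang) * n_c
    sb_dir /= np.linalg.norm(sb_dir)
    n_sb = int(round(params.sb_length / DS)) + 1
    s_loc = np.linspace(0.0, params.sb_length, n_sb)
    sb_pts = mv_cl.point_at(carina) + np.outer(s_loc, sb_dir)
    sb_cl = Centerline(sb_pts, branch="SB", carina_arclength=carina, arclength_offset=carina)
    d_sb = np.full(n_sb, params.sb_diameter) * _stenosis_factor(
        sb_cl.arclength, params.stenoses, "SB"
    )

    def comp_profile(s: np.ndarray, branch: str) -> np.ndarray:
        comp = np.tile([0.0, 1.0, 0.0], (len(s), 1))  # default: fibrous
        for z in params.composition_zones:
            if z.branch != branch:
                continue
            mask = (s >= z.start) & (s <= z.end)
            comp[mask] = z.fractions
        return comp

    mv = Branch(
        centerline=mv_cl,
        diameter=d_mv,
        wall_thickness=np.full_like(s_mv, params.wall_thickness),
        composition=comp_profile(s_mv, "MV"),
        healthy_diameter=taper.copy(),
    )
    sb = Branch(
        centerline=sb_cl,
        diameter=d_sb,
        wall_thickness=np.full(n_sb, params.wall_thickness),
        composition=comp_profile(sb_cl.arclength, "SB"),
        healthy_diameter=np.full(n_sb, params.sb_diameter),
    )
    return BifurcationAnatomy(
        mv=mv, sb=sb, carina_arclength=carina, sb_direction=sb_dir, params=params
    )


def tube_mesh(points: np.ndarray, radii: np.ndarray, n_theta: int = N_THETA) -> trimesh.Trimesh:
    """Capped, watertight tube around a polyline with per-point radii."""
    t, e1, e2 = rotation_minimizing_frames(points)
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rings = (
        points[:, None, :]
        + radii[:, None, None] * (np.cos(th)[None, :, None] * e1[:, None, :]
        + np.sin(th)[None, :, None] * e2[:, None, :])
    )
    n = len(points)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps (fans around ring centroids)
    verts = np.vstack([verts, points[0], points[-1]])
    c0, c1 = len(verts) - 2, len(verts) - 1
    for j in range(n_theta):
        faces.append([c0, (j + 1) % n_theta, j])
        base = (n - 1) * n_theta
        faces.append([c1, base + j, base + (j + 1) % n_theta])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    return mesh


def generate_oct_pullback(
    anatomy: BifurcationAnatomy,
    branch: str = "MV",
    frame_spacing: float = 0.5,
    dropout_arcs: Callable[[np.random.Generator, int], list[tuple[float, float]]] | None = None,
    seed: int = 0,
    n_theta: int = N_THETA,
) -> OCTPullback:
    """Sample an OCT-like pullback from the analytic anatomy.

    Frames are planar sections perpendicular to the branch centerline,
    ordered distal to proximal.  Composition arcs partition the
    circumference in proportion to the anatomy's composition fractions
    at each frame; ``dropout_arcs(rng, i)`` may inject missing outer-
    border arcs per frame.
    """
    b = anatomy.branch(branch)
    s0, s1 = b.arclength[0], b.arclength[-1]
    length = s1 - s0
    if frame_spacing > length:
        raise ValueError(f"frame spacing {frame_spacing} mm exceeds branch length {length} mm")
    n_frames = int(np.floor(length / frame_spacing + 1e-9)) + 1
    rng = np.random.default_rng(seed)
    angles = np.arange(n_theta) * (360.0 / n_theta)
    frames: list[OCTFrame] = []
    positions = s1 - frame_spacing * np.arange(n_frames)  # distal -> proximal
    for i, s in enumerate(positions):
        r = float(b.diameter_at(s)) / 2.0
        t = float(b.thickness_at(s))
        comp = b.composition_at(s)
        start = rng.uniform(0.0, 360.0)
        comp_arcs = []
        a = start
        for frac, tissue in zip(comp, ("lipid", "fibrous", "calcified")):
            if frac <= 1e-12:
                continue
            span = 360.0 * float(frac)
            comp_arcs.append((a % 360.0, (a + span) % 360.0, tissue, t))
            a += span
        missing = tuple(dropout_arcs(rng, i)) if dropout_arcs is not None else ()
        outer = np.full(n_theta, r + t)
        for ms, me in missing:
            outer[_arc_mask(angles, ms, me)] = np.nan
        frames.append(
            OCTFrame(
                angles_deg=angles.copy(),
                lumen_radius=np.full(n_theta, r),
                outer_radius=outer,
                missing_arcs=missing,
                composition_arcs=tuple(comp_arcs),
                arclength=float(s),
            )
        )
    if branch == "MV":
        carina_idx = int(np.argmin(np.abs(positions - anatomy.carina_arclength)))
    else:
        carina_idx = n_frames - 1  # SB ostium is the most proximal frame
    return OCTPullback(
        frames=frames,
        frame_spacing=frame_spacing,
        branch=branch,
        carina_frame_index=carina_idx,
    )


def _arc_mask(angles_deg: np.ndarray, start: float, end: float) -> np.ndarray:
    start, end = start % 360.0, end % 360.0
    if start <= end:
        return (angles_deg >= start) & (angles_deg < end)
    return (angles_deg >= start) | (angles_deg < end)


def _arcs_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    grid = np.arange(0.0, 360.0, 0.25)
    return bool(np.any(_arc_mask(grid, *a) & _arc_mask(grid, *b)))


def _tissue_labels(frame: OCTFrame) -> list[str]:
    labels = ["none"] * len(frame.angles_deg)
    for s, e, tissue, _t in frame.composition_arcs:
        for k in np.nonzero(_arc_mask(frame.angles_deg, s, e))[0]:
            labels[k] = tissue
    return labels


# ---------------------------------------------------------------------------
# biplane projection


def project_to_planes(
    anatomy_or_points,
    view_angle_a: float,
    view_angle_b: float,
    branch: str = "MV",
):
    """Parallel projection of a centerline onto two angiographic planes.

    A view at angle phi looks along the direction
    (cos phi, sin phi, 0); its image plane is spanned by
    u = (-sin phi, cos phi, 0) and v = (0, 0, 1).  Views closer than 30
    degrees give a poorly conditioned reconstruction and are rejected,
    matching standard biplane acquisition practice.
    """
    from .reconstruction import ProjectionCurve

    if abs(view_angle_a - view_angle_b) < 30.0:
        raise ValueError(
            "angiographic views must be at least 30 degrees apart for biplane reconstruction"
        )
    if isinstance(anatomy_or_points, BifurcationAnatomy):
        pts = anatomy_or_points.branch(branch).centerline.points
        radii = anatomy_or_points.branch(branch).diameter / 2.0
    else:
        pts = np.asarray(anatomy_or_points, dtype=float)
        radii = None

    curves = []
    for phi_deg in (view_angle_a, view_angle_b):
        phi = np.deg2rad(phi_deg)
        normal = np.array([np.cos(phi), np.sin(phi), 0.0])
        u = np.array([-np.sin(phi), np.cos(phi), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        xy = np.column_stack([pts @ u, pts @ v])
        curves.append(
            ProjectionCurve(
                points=xy,
                view_angle=float(phi_deg),
                normal=normal,
                origin=np.zeros(3),
                silhouette_halfwidth=None if radii is None else radii.copy(),
            )
        )
    return curves[0], curves[1]


# ---------------------------------------------------------------------------
# bench variant and procedures


def generate_bench_variant(anatomy: BifurcationAnatomy, silicone_thickness: float = 1.0) -> BenchModel:
    """Silicone bench twin: uniform wall, Neo-Hookean material, no plaque."""
    if silicone_thickness <= 0:
        raise ValueError("silicone thickness must be positive")
    n_mv = len(anatomy.mv.arclength)
    n_sb = len(anatomy.sb.arclength)
    mv = replace(
        anatomy.mv,
        wall_thickness=np.full(n_mv, float(silicone_thickness)),
        composition=np.tile([0.0, 1.0, 0.0], (n_mv, 1)),
    )
    sb = replace(
        anatomy.sb,
        wall_thickness=np.full(n_sb, float(silicone_thickness)),
        composition=np.tile([0.0, 1.0, 0.0], (n_sb, 1)),
    )
    bench_anatomy = BifurcationAnatomy(
        mv=mv,
        sb=sb,
        carina_arclength=anatomy.carina_arclength,
        sb_direction=anatomy.sb_direction,
        params=anatomy.params,
    )
    return BenchModel(anatomy=bench_anatomy, silicone_thickness=float(silicone_thickness))


def default_devices() -> dict[str, dict]:
    """A representative provisional-case device set (stent + balloons)."""
    return {
        "mv_stent": {
            "stent": DeviceRef("stent", preset="integrity_like", diameter_mm=3.0, length_mm=26.0),
            "balloon": DeviceRef("balloon", diameter_mm=3.0, length_mm=26.0, compliance_class="semi_compliant"),
            "pressure_atm": 16.0,
        },
        "sb_stent": {
            "stent": DeviceRef("stent", preset="integrity_like", diameter_mm=2.75, length_mm=8.0),
            "balloon": DeviceRef("balloon", diameter_mm=2.75, length_mm=8.0, compliance_class="semi_compliant"),
            "pressure_atm": 18.0,
        },
        "pot_balloon": {
            "balloon": DeviceRef("balloon", diameter_mm=3.5, length_mm=15.0, compliance_class="compliant"),
            "pressure_atm": 16.0,
        },
        "sb_balloon": {
            "balloon": DeviceRef("balloon", diameter_mm=2.5, length_mm=12.0, compliance_class="compliant"),
            "pressure_atm": 14.0,
        },
        "kbi_balloons": {
            "balloon": DeviceRef("balloon", diameter_mm=3.5, length_mm=15.0, compliance_class="compliant"),
            "balloon_sb": DeviceRef("balloon", diameter_mm=2.75, length_mm=8.0, compliance_class="semi_compliant"),
            "pressure_atm": 12.0,
            "pressure_sb_atm": 14.0,
        },
    }


def generate_procedure(template: str, devices: dict[str, dict]) -> ProcedureTable:
    """Instantiate a named technique template with concrete devices.

    ``devices`` maps role names (mv_stent, pot_balloon, sb_balloon,
    sb_stent, kbi_balloons) to dicts holding DeviceRef objects and
    pressures; see :func:`default_devices` for the layout.
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(TEMPLATES)}")
    if not devices:
        raise ValueError("empty device list: a procedure needs devices")
    steps: list[ProcedureStep] = []
    for action, branch, role in TEMPLATES[template]:
        if role not in devices:
            if action == "kbi":
                continue  # KBI is optional when no kissing balloons are given
            raise ValueError(f"device role {role!r} required by template {template!r} is missing")
        spec = devices[role]
        if action == "stent":
            protrusion = 0.0
            if branch == "SB":
                # TAP/culotte: the SB stent protrudes into the proximal MV
                protrusion = {"TAP": 2.0, "TAP_long_protrusion": 5.0, "culotte": 5.0}.get(
                    template, 0.0
                )
            steps.append(
                ProcedureStep(
                    action="stent",
                    branch=branch,
                    device=spec["stent"],
                    pressure_atm=spec["pressure_atm"],
                    protrusion_mm=protrusion,
                )
            )
        elif action == "kbi":
            steps.append(
                ProcedureStep(
                    action="kbi",
                    branch="MV",
                    device=spec["balloon"],
                    pressure_atm=spec["pressure_atm"],
                    device_sb=spec["balloon_sb"],
                    pressure_sb_atm=spec["pressure_sb_atm"],
                )
            )
        else:
            steps.append(
                ProcedureStep(
                    action=action,
                    branch=branch,
                    device=spec["balloon"],
                    pressure_atm=spec["pressure_atm"],
                )
            )
    return ProcedureTable(name=template, steps=steps)


def _params_to_dict(params: AnatomyParams) -> dict:
    from dataclasses import asdict

    return asdict(params)
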