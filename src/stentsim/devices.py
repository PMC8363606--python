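"""Parametric stent and balloon device models.

Stents are ring-and-link patterns: zig-zag rings of crowns (peaks and
valleys on a cylinder) joined by longitudinal links.  Commercial
patterns are proprietary, so presets ("integrity_like", "onyx_like",
"synergy_like") encode only the device family, strut cross-section and
alloy.  Geometry transforms — radial crimping and positioning/bending
along a centerline via rotation-minimizing frames — are kinematic maps
acting on the node graph; the mechanics lives in :mod:`.deployment`.

Balloons are closed-form compliant membranes: folded below an unfolding
threshold, nominal diameter at nominal pressure, and linear-elastic
growth above it with modulus fixed by compliance class (300 / 900 /
1500 MPa for compliant / semi-compliant / non-compliant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import networkx as nx
import numpy as np
import yaml

from .geometry import Centerline
from .materials import AlloyModel, default_table

__all__ = [
    "StrutSection",
    "StentDesign",
    "StentGeometry",
    "BalloonSpec",
    "load_presets",
    "design_from_preset",
    "build_nominal_stent",
    "crimp",
    "position_and_bend",
    "balloon_diameter_at_pressure",
    "atm_to_mpa",
]

ATM_TO_MPA = 0.101325


def atm_to_mpa(pressure_atm: float) -> float:
    """Convert a balloon pressure from atm (as printed) to MPa."""
    return float(pressure_atm) * ATM_TO_MPA


@dataclass(frozen=True)
class StrutSection:
    shape: str  # "circular" | "rectangular"
    diameter: float | None = None  # mm, circular
    width: float | None = None  # mm, rectangular
    thickness: float | None = None  # mm, rectangular

    def __post_init__(self) -> None:
        if self.shape == "circular":
            if not self.diameter or self.diameter <= 0:
                raise ValueError("circular section needs a positive diameter")
        elif self.shape == "rectangular":
            if not (self.width and self.thickness) or min(self.width, self.thickness) <= 0:
                raise ValueError("rectangular section needs positive width and thickness")
        else:
            raise ValueError(f"unknown section shape {self.shape!r}")

    @property
    def area(self) -> float:
        if self.shape == "circular":
            return float(np.pi * self.diameter**2 / 4.0)
        return float(self.width * self.thickness)

    @property
    def radial_thickness(self) -> float:
        return float(self.diameter if self.shape == "circular" else self.thickness)


@dataclass(frozen=True)
class StentDesign:
    name: str
    rings: int
    crowns_per_ring: int
    links_per_ring_pair: int
    strut_section: StrutSection
    alloy: str
    nominal_diameter: float  # mm
    nominal_length: float  # mm
    family: str = "wire"  # "wire" | "laser_cut"
    core_alloy: str | None = None  # shell-core wire (e.g. Pt-Ir core)
    core_area_fraction: float = 0.25

    def __post_init__(self) -> None:
        if min(self.rings, self.crowns_per_ring, self.links_per_ring_pair) < 1:
            raise ValueError("ring, crown and link counts must be >= 1")
        if self.nominal_diameter <= 0 or self.nominal_length <= 0:
            raise ValueError("nominal dimensions must be positive")
        if self.family not in ("wire", "laser_cut"):
            raise ValueError(f"unknown stent family {self.family!r}")

    def effective_alloy(self) -> AlloyModel:
        """The strut alloy; shell-core wires get an area-weighted modulus."""
        table = default_table()
        shell = table.alloys[self.alloy]
        if self.core_alloy is None:
            return shell
        core = table.alloys[self.core_alloy]
        f = self.core_area_fraction
        return AlloyModel(
            name=f"{shell.name}+{core.name}core",
            elastic_modulus=(1 - f) * shell.elastic_modulus + f * core.elastic_modulus,
            yield_strength=(1 - f) * shell.yield_strength + f * core.yield_strength,
            tensile_strength=shell.tensile_strength,
            elongation=shell.elongation,
            density=None,
            hardening=shell.hardening,
        )


@dataclass
class StentGeometry:
    """A stent as a typed node graph on (or bent around) a cylinder axis.

    Nodes carry cylindrical coordinates (axial z from the proximal edge,
    angle theta, radius r) plus 3D positions; edges are typed crown_arm
    or link.  All kinematic transforms preserve the topology and the
    per-ring angular ordering.
    """

    design: StentDesign
    nodes_zthr: np.ndarray  # (N, 3): axial z (mm), theta (rad), radius (mm)
    edges: list[tuple[int, int, str]]  # (i, j, "crown_arm" | "link")
    ring_index: np.ndarray  # (N,)
    state: str = "nominal"  # nominal | crimped | placed | deployed
    nodes_xyz: np.ndarray | None = None  # set once placed in 3D

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_zthr)

    @property
    def length(self) -> float:
        return float(self.nodes_zthr[:, 0].max() - self.nodes_zthr[:, 0].min())

    @property
    def radii(self) -> np.ndarray:
        return self.nodes_zthr[:, 2]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((i, j, {"kind": k}) for i, j, k in self.edges)
        return g

    def edge_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, k in self.edges:
            out[k] = out.get(k, 0) + 1
        return out

    def cylinder_xyz(self) -> np.ndarray:
        """3D positions on the straight cylinder (axis = z)."""
        z, th, r = self.nodes_zthr.T
        return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def load_presets() -> dict:
    raw = yaml.safe_load(
        resources.files("stentsim.data").joinpath("device_presets.yaml").read_text()
    )
    return raw["stents"]


def design_from_preset(
    name: str, diameter_mm: float | None = None, length_mm: float | None = None
) -> StentDesign:
    """Instantiate a preset, optionally resized to a catalog diameter/length."""
    presets = load_presets()
    if name not in presets:
        raise ValueError(f"unknown stent preset {name!r}; choose from {sorted(presets)}")
    p = presets[name]
    sec = p["strut_section"]
    section = StrutSection(
        shape=sec["shape"],
        diameter=sec.get("diameter_mm"),
        width=sec.get("width_mm"),
        thickness=sec.get("thickness_mm"),
    )
    length = length_mm if length_mm is not None else p["nominal_length_mm"]
    rings = max(2, int(round(p["rings"] * length / p["nominal_length_mm"])))
    return StentDesign(
        name=name,
        rings=rings,
        crowns_per_ring=p["crowns_per_ring"],
        links_per_ring_pair=p["links_per_ring_pair"],
        strut_section=section,
        alloy=p["alloy"],
        nominal_diameter=diameter_mm if diameter_mm is not None else p["nominal_diameter_mm"],
        nominal_length=length,
        family=p["family"],
        core_alloy=p.get("core_alloy"),
        core_area_fraction=p.get("core_area_fraction", 0.25),
    )


def build_nominal_stent(design: StentDesign) -> StentGeometry:
    """Synthesize the nominal-geometry node graph of a ring-and-link stent.

    Each ring has ``2 * crowns_per_ring`` nodes alternating valley
    (proximal) and peak (distal); consecutive in-ring nodes are joined
    by crown arms and selected peak/valley pairs of adjacent rings by
    links.  All nodes sit at the nominal radius; the total length equals
    the nominal length to within one crown height.
    """
    c = design.crowns_per_ring
    n_per_ring = 2 * c
    gap_frac = 0.3  # link gap as a fraction of ring height
    h = design.nominal_length / (design.rings + gap_frac * (design.rings - 1))
    gap = gap_frac * h
    r = design.nominal_diameter / 2.0
    dtheta = 2.0 * np.pi / n_per_ring

    nodes = []
    ring_idx = []
    for j in range(design.rings):
        z0 = j * (h + gap)
        for k in range(n_per_ring):
            z = z0 if k % 2 == 0 else z0 + h  # even = valley, odd = peak
            nodes.append([z, k * dtheta, r])
            ring_idx.append(j)
    nodes = np.asarray(nodes, dtype=float)

    edges: list[tuple[int, int, str]] = []
    for j in range(design.rings):
        base = j * n_per_ring
        for k in range(n_per_ring):
            edges.append((base + k, base + (k + 1) % n_per_ring, "crown_arm"))
    # links: connect peaks of ring j to the adjacent valley of ring j+1
    step = max(1, c // design.links_per_ring_pair)
    for j in range(design.rings - 1):
        base, nxt = j * n_per_ring, (j + 1) * n_per_ring
        peaks = [k for k in range(n_per_ring) if k % 2 == 1]
        for li, k in enumerate(peaks[:: step][: design.links_per_ring_pair]):
            edges.append((base + k, nxt + (k + 1) % n_per_ring, "link"))
    geom = StentGeometry(
        design=design,
        nodes_zthr=nodes,
        edges=edges,
        ring_index=np.asarray(ring_idx),
        state="nominal",
    )
    assert nx.is_connected(geom.graph())
    return geom


def crimp(geometry: StentGeometry, target_diameter: float) -> StentGeometry:
    """Radial-displacement crimp: scale every node radius to the target.

    Axial coordinates, angular ordering and topology are untouched, so
    the map is exactly invertible by re-expansion to the nominal radius.
    """
    if not (0.0 < target_diameter < geometry.design.nominal_diameter):
        raise ValueError("crimp target must be positive and below the nominal diameter")
    nodes = geometry.nodes_zthr.copy()
    nodes[:, 2] = nodes[:, 2] * (target_diameter / 2.0) / nodes[:, 2].max()
    return replace(geometry, nodes_zthr=nodes, state="crimped", nodes_xyz=None)


def expand_to(geometry: StentGeometry, diameter: float) -> StentGeometry:
    """Kinematic re-expansion (inverse of crimp) to a given diameter."""
    nodes = geometry.nodes_zthr.copy()
    nodes[:, 2] = nodes[:, 2] * (diameter / 2.0) / nodes[:, 2].max()
    state = "nominal" if abs(diameter - geometry.design.nominal_diameter) < 1e-12 else geometry.state
    return replace(geometry, nodes_zthr=nodes, state=state, nodes_xyz=None)


def position_and_bend(
    geometry: StentGeometry,
    centerline: Centerline,
    proximal_edge_arclength: float,
    rotation: float = 0.0,
) -> StentGeometry:
    """Bend the stent along a centerline with rotation-minimizing frames.

    Node (z, theta, r) maps to C(s) + r cos(theta+rot) e1(s) +
    r sin(theta+rot) e2(s) with s = proximal edge arclength + z.  On a
    straight centerline this reduces to a rigid motion.
    """
    s0 = proximal_edge_arclength
    z = geometry.nodes_zthr[:, 0]
    s_end = s0 + z.max()
    if s0 < centerline.arclength[0] - 1e-9 or s_end > centerline.arclength[-1] + 1e-9:
        raise ValueError(
            f"stent span [{s0:.2f}, {s_end:.2f}] mm exceeds the centerline range "
            f"[{centerline.arclength[0]:.2f}, {centerline.arclength[-1]:.2f}] mm"
        )
    frames = centerline.frames()
    xyz = np.empty((geometry.n_nodes, 3))
    for i, (zi, th, r) in enumerate(geometry.nodes_zthr):
        p, _t, e1, e2 = centerline.frame_at(s0 + zi, frames=frames)
        a = th + rotation
        xyz[i] = p + r * (np.cos(a) * e1 + np.sin(a) * e2)
    return replace(geometry, nodes_xyz=xyz, state="placed")


@dataclass(frozen=True)
class BalloonSpec:
    nominal_diameter: float  # mm
    length: float  # mm
    compliance_class: str = "semi_compliant"
    wings: int = 3
    nominal_pressure: float = 8.0  # atm
    membrane_thickness: float = 0.03  # mm
    unfold_pressure: float = 2.0  # atm
    marker_arclengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.nominal_diameter <= 0 or self.length <= 0:
            raise ValueError("balloon dimensions must be positive")
        if self.wings < 2:
            raise ValueError("a folded balloon needs at least 2 wings")

    @property
    def folded_diameter(self) -> float:
        return self.nominal_diameter / 4.0


def balloon_from_ref(ref) -> BalloonSpec:
    """BalloonSpec from a procedure-table DeviceRef."""
    return BalloonSpec(
        nominal_diameter=ref.diameter_mm,
        length=ref.length_mm,
        compliance_class=ref.compliance_class or "semi_compliant",
    )


def balloon_diameter_at_pressure(spec: BalloonSpec, pressure_atm: float) -> float:
    """Closed-form membrane compliance curve, monotone in pressure.

    Folded below the unfolding threshold, linear ramp to the nominal
    diameter at nominal pressure, then thin-membrane elastic growth
    d_nom * (1 + dP * d_nom / (2 t_b E)) with dP in MPa and the class
    modulus E (300/900/1500 MPa).
    """
    if pressure_atm < 0:
        raise ValueError("pressure must be non-negative")
    d_nom = spec.nominal_diameter
    if pressure_atm <= spec.unfold_pressure:
        return spec.folded_diameter
    if pressure_atm <= spec.nominal_pressure:
        w = (pressure_atm - spec.unfold_pressure) / (spec.nominal_pressure - spec.unfold_pressure)
        return spec.folded_diameter + w * (d_nom - spec.folded_diameter)
    e = default_table().balloon_moduli[spec.compliance_class]
    dp_mpa = atm_to_mpa(pressure_atm - spec.nominal_pressure)
    return d_nom * (1.0 + dp_mpa * d_nom / (2.0 * spec.membrane_thickness * e))
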