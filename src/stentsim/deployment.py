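"""Quasi-static slice-wise deployment surrogate.

The continuum finite-element stenting problem is reduced to a chain of
independent cross-sectional (slice) equilibria: at each slice the
applied balloon pressure balances the hyperelastic thin-walled vessel
response and the elastoplastic hoop response of any stent ring layers,

    P_balloon = p_wall(r) + sum_layers p_ring(r),

with the radius clamped above by the balloon compliance curve.  The
wall term uses the thin-wall relation p = (t/r) * sigma_theta(r/r0)
with the slice's material curve (normal wall, silicone, or a plaque
score).  Stent layers are 1-D elastoplastic hoop springs: elastic
from their stress-free (plastic-set) radius, yielding per the alloy
law, with the plastic set updated on unloading — so stents retain
expansion after balloon deflation (recoil) while unstented slices
return to their reference radius.

Procedure steps (stenting, POT, SB strut opening, KBI, pre/post-
dilatation) replay the clinical step grammar; each step starts from the
previous step's final state and snapshots are kept per step.  This is a
deliberate surrogate for 3-D explicit FEA with contact: frictional
contact constants are carried as provenance metadata only.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import materials as mat
from .devices import (
    BalloonSpec,
    StentDesign,
    StentGeometry,
    atm_to_mpa,
    balloon_diameter_at_pressure,
    balloon_from_ref,
    build_nominal_stent,
    crimp,
    design_from_preset,
)
from .procedures import ProcedureStep, ProcedureTable
from .synthetic import BifurcationAnatomy

__all__ = [
    "RingLayer",
    "SliceState",
    "DeploymentConfig",
    "DeploymentState",
    "initial_state",
    "wall_pressure",
    "ring_pressure",
    "inflate",
    "deflate_recoil",
    "deploy_stent",
    "pot",
    "sb_open",
    "kbi",
    "malapposition_map",
    "run_procedure",
]

#: Provenance constants of the full-physics workflow this surrogate
#: replaces; recorded, never used by the slice equilibrium.
PROVENANCE = {
    "friction_coefficient": 0.2,
    "inflation_duration_s": 0.05,
    "target_time_increment_s": 5e-8,
    "note": "recorded-not-simulated",
}


@dataclass
class RingLayer:
    """One stent ring crossing a slice: a 1-D elastoplastic hoop spring."""

    stent_id: str
    alloy: str  # key into the material table (effective alloys registered ad hoc)
    section_area: float  # mm^2
    strut_thickness: float  # mm
    r_ref: float  # initial (crimped, as-placed) radius, mm
    r_ring: float  # current ring radius, mm
    eps_p: float = 0.0  # plastic hoop strain
    alpha: float = 0.0  # accumulated plastic strain (hardening variable)

    @property
    def r_set(self) -> float:
        """Stress-free (plastic-set) radius."""
        return self.r_ref * (1.0 + self.eps_p)


@dataclass
class SliceState:
    arclength: float  # mm, from the proximal MV inlet
    r0: float  # reference (pre-procedure) lumen radius, mm
    r: float  # current lumen radius, mm
    wall_thickness: float  # mm
    material: str | float = "normal_wall"  # material label or plaque score
    branch: str = "MV"
    r_healthy: float | None = None  # disease-free vessel radius (taper profile), mm
    r_plaque_max: float | None = None  # largest lumen radius reached (plaque set)
    layers: list[RingLayer] = field(default_factory=list)
    jailed: bool = False  # SB slice jailed by MV struts across the ostium

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.r <= 0:
            raise ValueError("slice radii must be positive")
        if self.r_healthy is None:
            self.r_healthy = self.r0
        if self.r_plaque_max is None:
            self.r_plaque_max = self.r0
        if len(self.layers) > 2:
            raise ValueError("at most two stent layers per slice (culotte)")

    @property
    def plaque_burden(self) -> float:
        """Radial plaque depth: healthy radius minus diseased lumen radius."""
        return max(0.0, self.r_healthy - self.r0)


@dataclass(frozen=True)
class DeploymentConfig:
    slice_spacing: float = 0.25  # mm (the element size of the full model)
    #: dimensionless hoop-stiffness scale; < 1 because a zig-zag ring
    #: expands by crown bending, much softer than hoop wire stretch
    ring_constant: float = 0.1
    solver_tol: float = 1e-6  # mm, bisection tolerance on radius
    ostium_zone: float = 2.0  # mm of SB adjacent to the carina
    provenance: dict = field(default_factory=lambda: dict(PROVENANCE))


@dataclass
class DeploymentState:
    mv: list[SliceState]
    sb: list[SliceState]
    carina_arclength: float
    config: DeploymentConfig = field(default_factory=DeploymentConfig)
    stents: dict[str, StentGeometry] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)  # per-step snapshots
    recross_cell: str | None = None
    _alloys: dict[str, mat.AlloyModel] = field(default_factory=dict)

    def slices(self, branch: str) -> list[SliceState]:
        return self.mv if branch == "MV" else self.sb

    def alloy(self, name: str) -> mat.AlloyModel:
        if name in self._alloys:
            return self._alloys[name]
        return mat.default_table().alloys[name]

    def register_alloy(self, model: mat.AlloyModel) -> None:
        self._alloys[model.name] = model

    # -- serialization (bit-stable: repr round-trips floats exactly) --
    def to_dict(self) -> dict:
        def slc(s: SliceState) -> dict:
            d = asdict(s)
            return d

        return {
            "carina_arclength": self.carina_arclength,
            "mv": [slc(s) for s in self.mv],
            "sb": [slc(s) for s in self.sb],
        }

    def serialize(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def snapshot(self, label: str) -> None:
        self.history.append({"label": label, "state": self.to_dict()})

    def sb_ostium_area(self) -> float:
        zone = [s for s in self.sb if s.arclength - self.carina_arclength <= self.config.ostium_zone]
        if not zone:
            return 0.0
        return float(np.mean([np.pi * s.r**2 for s in zone]))

    def profile(self, branch: str = "MV") -> tuple[np.ndarray, np.ndarray]:
        """(arclength, lumen diameter) along a branch."""
        sl = self.slices(branch)
        return (
            np.array([s.arclength for s in sl]),
            np.array([2.0 * s.r for s in sl]),
        )

    def stent_profile(self, branch: str = "MV") -> tuple[np.ndarray, np.ndarray]:
        """(arclength, stent diameter) over stented slices of a branch."""
        sl = [s for s in self.slices(branch) if s.layers]
        return (
            np.array([s.arclength for s in sl]),
            np.array([2.0 * max(l.r_ring for l in s.layers) for s in sl]),
        )

    def export_csv(self, path, branch: str = "MV") -> None:
        rows = ["arclength_mm,lumen_radius_mm,n_layers,gap_mm"]
        gaps = malapposition_map(self)
        gap_by_s = {(b, round(s, 6)): g for (b, s), g in gaps.items()}
        for s in self.slices(branch):
            g = gap_by_s.get((branch, round(s.arclength, 6)), "")
            rows.append(f"{s.arclength},{s.r},{len(s.layers)},{g}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def initial_state(
    anatomy: BifurcationAnatomy, config: DeploymentConfig | None = None
) -> DeploymentState:
    """Discretize an anatomy into per-slice states at the config spacing."""
    config = config or DeploymentConfig()

    def build(branch: str) -> list[SliceState]:
        b = anatomy.branch(branch)
        s_grid = np.arange(b.arclength[0], b.arclength[-1] + 1e-9, config.slice_spacing)
        out = []
        for s in s_grid:
            comp = b.composition_at(float(s))
            lipid, fibrous, calcified = (float(c) for c in comp)
            r = float(b.diameter_at(float(s))) / 2.0
            r_h = float(b.healthy_diameter_at(float(s))) / 2.0
            diseased = r < r_h * (1.0 - 1e-6) or fibrous < 1.0 - 1e-9
            # a fibrous-only, unnarrowed slice is normal wall, not plaque
            material: str | float
            material = mat.score_composition(lipid, fibrous, calcified) if diseased else "normal_wall"
            out.append(
                SliceState(
                    arclength=float(s),
                    r0=r,
                    r=r,
                    wall_thickness=float(b.thickness_at(float(s))),
                    material=material,
                    branch=branch,
                    r_healthy=r_h,
                )
            )
        return out

    return DeploymentState(
        mv=build("MV"),
        sb=build("SB"),
        carina_arclength=anatomy.carina_arclength,
        config=config,
    )


def bench_state(bench, config: DeploymentConfig | None = None) -> DeploymentState:
    """Initial state for a silicone bench model (uniform Neo-Hookean wall)."""
    st = initial_state(bench.anatomy, config)
    for s in st.mv + st.sb:
        s.material = "silicone"
        s.wall_thickness = bench.silicone_thickness
    return st


# ---------------------------------------------------------------------------
# constitutive slice responses


def _wall_stress(state: DeploymentState, slc: SliceState, stretch: float) -> float:
    table = mat.default_table()
    label = slc.material if isinstance(slc.material, str) else "normal_wall"
    return float(mat.uniaxial_stress(table.hyperelastic[label], stretch))


def wall_pressure(state: DeploymentState, slc: SliceState, r: float) -> float:
    """Slice wall pressure (MPa): thin-walled hoop response + plaque term.

    The wall layer contributes p = (t/r) * sigma_theta(r/r0) with the
    slice material curve; zero at the reference radius.  Diseased
    slices (lumen narrowed below the healthy taper radius) additionally
    resist expansion through their plaque burden: the plaque depth acts
    as a second thin layer loaded at the lumen stretch r/r0 with the
    plaque-score stress curve, so calcified lesions oppose ballooning
    far more than lipid ones.  Plaque deformation is permanent: the
    plaque term acts only while loading past the largest radius the
    slice has reached (``r_plaque_max``); below it the yielded plaque
    exerts no restoring force, so balloon-acquired lumen gain is not
    clawed back during recoil.  Yield caps make both terms flatten at
    large stretch.
    """
    if r < 0.5 * slc.r0:
        raise ValueError("radius below half the reference radius: outside model validity")
    p = 0.0
    lam_w = r / slc.r_healthy
    if slc.plaque_burden <= 1e-9:
        # healthy (or bench) slice: single-layer thin wall, signed response
        return (slc.wall_thickness / r) * _wall_stress(state, slc, lam_w)
    if lam_w > 1.0:
        p += (slc.wall_thickness / r) * _wall_stress(state, slc, lam_w)
    lam_c = r / slc.r0
    loading = r >= slc.r_plaque_max * (1.0 - 1e-12)
    if lam_c > 1.0 and loading and isinstance(slc.material, float):
        table = mat.default_table()
        p += (slc.plaque_burden / r) * mat.score_stress(float(slc.material), lam_c, table)
    return p


def _ring_trial(
    state: DeploymentState, layer: RingLayer, r: float
) -> tuple[float, float, float]:
    """Trial hoop stress and (uncommitted) plastic update at radius r.

    Returns (sigma, eps_p_new, alpha_new): 1-D return-mapping
    elastoplasticity with isotropic linear hardening on the alloy law.
    """
    alloy = state.alloy(layer.alloy)
    e = alloy.modulus_mpa
    h = alloy.hardening_modulus
    eps = (r - layer.r_ref) / layer.r_ref
    sig_trial = e * (eps - layer.eps_p)
    flow = alloy.yield_strength + h * layer.alpha
    f = abs(sig_trial) - flow
    if f <= 0.0:
        return sig_trial, layer.eps_p, layer.alpha
    dgamma = f / (e + h)
    sign = 1.0 if sig_trial > 0 else -1.0
    sigma = sig_trial - sign * e * dgamma
    return sigma, layer.eps_p + sign * dgamma, layer.alpha + dgamma


def ring_pressure(state: DeploymentState, layer: RingLayer, r: float) -> float:
    """Resisting pressure of one stent ring layer at radius r (MPa).

    Positive values resist expansion (ring stretched past its set);
    negative values push outward (ring compressed below its set).
    p = k * A * sigma / r^2, with elastic slope proportional to
    E * A / r^3 as for a thin hoop.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    sigma, _, _ = _ring_trial(state, layer, r)
    return state.config.ring_constant * layer.section_area * sigma / r**2


def _commit_ring(state: DeploymentState, layer: RingLayer, r: float) -> None:
    _, eps_p, alpha = _ring_trial(state, layer, r)
    layer.eps_p, layer.alpha = eps_p, alpha
    layer.r_ring = r


def _total_resistance(state: DeploymentState, slc: SliceState, r: float) -> float:
    """Inflation resistance: engaged wall (no suction below r0) + rings."""
    p = max(0.0, wall_pressure(state, slc, r)) if r >= slc.r0 else 0.0
    for layer in slc.layers:
        p += ring_pressure(state, layer, r)
    return p


def _solve_last_crossing(fn, lo: float, hi: float, target: float, tol: float) -> float:
    """Largest r in [lo, hi] with fn(r) = target (scan + bisection).

    fn need not be globally monotone (yield caps flatten the wall
    curve), so the bracket is located on a scan first.
    """
    if hi <= lo:
        return lo
    rs = np.linspace(lo, hi, 128)
    vals = np.array([fn(r) for r in rs]) - target
    if vals[-1] <= 0.0:
        return hi
    # last index where the function is still at/below the target
    below = np.nonzero(vals <= 0.0)[0]
    if len(below) == 0:
        return lo
    a, b = rs[below[-1]], rs[min(below[-1] + 1, len(rs) - 1)]
    for _ in range(200):
        if b - a <= tol:
            break
        m = 0.5 * (a + b)
        if fn(m) - target <= 0.0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def inflate(
    state: DeploymentState,
    balloon: BalloonSpec,
    pressure_atm: float,
    window: tuple[float, float],
    branch: str = "MV",
    clamp_radius: float | None = None,
    drive_pressure_atm: float | None = None,
) -> DeploymentState:
    """Balloon inflation over an arclength window (in place, returns state).

    Each slice in the window moves to the largest radius where the
    applied pressure balances wall + ring resistance, clamped above by
    the balloon compliance diameter; radii never decrease during
    inflation, and slices outside the window are untouched.
    """
    p_mpa = atm_to_mpa(drive_pressure_atm if drive_pressure_atm is not None else pressure_atm)
    r_clamp = (
        clamp_radius
        if clamp_radius is not None
        else balloon_diameter_at_pressure(balloon, pressure_atm) / 2.0
    )
    tol = state.config.solver_tol
    lo_w, hi_w = window
    for slc in state.slices(branch):
        if not (lo_w - 1e-9 <= slc.arclength <= hi_w + 1e-9):
            continue
        if r_clamp <= slc.r + tol:
            # balloon smaller than the current lumen: it may still expand rings
            if slc.layers and r_clamp > max(l.r_ring for l in slc.layers):
                r_f = _solve_last_crossing(
                    lambda r: sum(ring_pressure(state, l, r) for l in slc.layers),
                    max(l.r_ring for l in slc.layers),
                    r_clamp,
                    p_mpa,
                    tol,
                )
                for layer in slc.layers:
                    _commit_ring(state, layer, r_f)
            continue
        start = slc.r
        r_f = _solve_last_crossing(
            lambda r: _total_resistance(state, slc, r), start, r_clamp, p_mpa, tol
        )
        r_f = max(start, min(r_f, r_clamp))
        for layer in slc.layers:
            _commit_ring(state, layer, r_f)
        slc.r = max(slc.r, r_f)
        slc.r_plaque_max = max(slc.r_plaque_max, slc.r)
    return state


def deflate_recoil(
    state: DeploymentState, window: tuple[float, float], branch: str = "MV"
) -> DeploymentState:
    """Balloon deflation: elastic recoil of wall against the stent set.

    Unstented slices return to the reference radius exactly.  Stented
    slices settle where the wall tension balances the ring at its
    plastic set; radii never increase during recoil, and plastic set
    acquired during inflation is retained (residual expansion gain).
    """
    lo_w, hi_w = window
    tol = state.config.solver_tol
    for slc in state.slices(branch):
        if not (lo_w - 1e-9 <= slc.arclength <= hi_w + 1e-9):
            continue
        r_peak = slc.r
        if not slc.layers:
            slc.r = slc.r0
            continue
        r_set = max(layer.r_set for layer in slc.layers)
        if r_set <= slc.r0 + tol:
            # stent free inside the resting lumen: no contact force
            slc.r = slc.r0
            for layer in slc.layers:
                _commit_ring(state, layer, min(layer.r_set, r_peak))
            continue

        def balance(r: float) -> float:
            return wall_pressure(state, slc, r) + sum(
                ring_pressure(state, layer, r) for layer in slc.layers
            )

        lo = max(0.51 * slc.r0, min(slc.r0, r_set))
        hi = min(r_peak, r_set)
        if hi <= lo:
            r_eq = hi
        else:
            # balance is increasing in r (wall stiffens, ring compresses);
            # find the zero crossing
            r_eq = _solve_last_crossing(balance, lo, hi, 0.0, tol)
        r_eq = min(r_eq, r_peak)
        for layer in slc.layers:
            _commit_ring(state, layer, r_eq)
        slc.r = min(r_peak, max(r_eq, 0.5 * slc.r0))
    return state


def _branch_window(state: DeploymentState, branch: str) -> tuple[float, float]:
    sl = state.slices(branch)
    return sl[0].arclength, sl[-1].arclength


def _stent_window(step_placement, state, branch, length, history_windows) -> tuple[float, float]:
    """Resolve a placement rule to an arclength window."""
    carina = state.carina_arclength
    lo_b, hi_b = _branch_window(state, branch)
    if step_placement.mode == "arclength":
        start = step_placement.value_mm
    elif step_placement.mode == "relative_to_step":
        ref = history_windows.get(step_placement.reference_step)
        if ref is None:
            raise ValueError(f"placement references unknown step #{step_placement.reference_step}")
        start = ref[0] - step_placement.value_mm  # "more proximally than step #k"
    else:  # auto: center on the carina (MV) or start at the ostium (SB)
        start = carina - length / 2.0 if branch == "MV" else carina
    start = float(np.clip(start, lo_b, hi_b - length)) if hi_b - lo_b > length else lo_b
    return start, start + length


def deploy_stent(
    state: DeploymentState,
    design: StentDesign,
    balloon: BalloonSpec,
    pressure_atm: float,
    window: tuple[float, float],
    branch: str = "MV",
    stent_id: str | None = None,
    mv_protrusion_mm: float = 0.0,
) -> DeploymentState:
    """Register a crimped stent over a window, inflate and recoil.

    Adds a ring layer to every covered slice and marks SB slices jailed
    when an MV stent crosses the ostium, then runs the inflation/
    deflation pair.  ``mv_protrusion_mm`` extends an SB stent into the
    proximal MV (TAP/culotte), creating two-layer overlap there.
    """
    stent_id = stent_id or f"{design.name}-{len(state.stents) + 1}"
    geom = crimp(build_nominal_stent(design), target_diameter=min(1.2, design.nominal_diameter / 2.5))
    r_crimp = float(geom.radii.max())
    alloy = design.effective_alloy()
    state.register_alloy(alloy)

    def add_layer(slc: SliceState) -> None:
        slc.layers.append(
            RingLayer(
                stent_id=stent_id,
                alloy=alloy.name,
                section_area=design.strut_section.area,
                strut_thickness=design.strut_section.radial_thickness,
                r_ref=r_crimp,
                r_ring=r_crimp,
            )
        )

    lo_w, hi_w = window
    for slc in state.slices(branch):
        if lo_w - 1e-9 <= slc.arclength <= hi_w + 1e-9 and len(slc.layers) < 2:
            add_layer(slc)
    mv_window = None
    if branch == "SB" and mv_protrusion_mm > 0.0:
        mv_window = (state.carina_arclength - mv_protrusion_mm, state.carina_arclength)
        for slc in state.mv:
            if mv_window[0] - 1e-9 <= slc.arclength <= mv_window[1] + 1e-9 and len(slc.layers) < 2:
                add_layer(slc)
    if branch == "MV" and lo_w <= state.carina_arclength <= hi_w:
        for slc in state.sb:
            if slc.arclength - state.carina_arclength <= state.config.ostium_zone:
                slc.jailed = True
    state.stents[stent_id] = geom
    inflate(state, balloon, pressure_atm, window, branch)
    deflate_recoil(state, window, branch)
    if mv_window is not None:
        inflate(state, balloon, pressure_atm, mv_window, "MV")
        deflate_recoil(state, mv_window, "MV")
    return state


def pot(
    state: DeploymentState,
    balloon: BalloonSpec,
    pressure_atm: float,
    window: tuple[float, float] | None = None,
) -> DeploymentState:
    """Proximal optimization: inflation confined to the proximal MV.

    The window ends at (or before) the carina; distal MV and SB slices
    are untouched.
    """
    if window is None:
        window = (state.carina_arclength - balloon.length, state.carina_arclength)
    lo_w, hi_w = window
    hi_w = min(hi_w, state.carina_arclength)
    lo_w = min(lo_w, hi_w)
    inflate(state, balloon, pressure_atm, (lo_w, hi_w), "MV")
    deflate_recoil(state, (lo_w, hi_w), "MV")
    return state


def sb_open(
    state: DeploymentState, balloon: BalloonSpec, pressure_atm: float
) -> DeploymentState:
    """Open jailing struts toward the side branch through the distal cell.

    Ostium-adjacent SB slices are dilated and the jailed markers
    cleared (the recrossing cell is always the distal cell).  A jailed
    slice gains a scaffold layer from the opened stent cell — the
    deformed struts hold the dilated ostium — so the effective ostium
    area increases and is retained after deflation.
    """
    carina = state.carina_arclength
    window = (carina, carina + min(balloon.length, state.config.ostium_zone + balloon.length))
    jailing = [
        (sid, g) for sid, g in state.stents.items() if g.design is not None
    ]
    for slc in state.sb:
        if slc.arclength - carina <= state.config.ostium_zone and slc.jailed:
            slc.jailed = False
            if jailing and len(slc.layers) < 2:
                sid, geom = jailing[-1]
                design = geom.design
                alloy = design.effective_alloy()
                state.register_alloy(alloy)
                slc.layers.append(
                    RingLayer(
                        stent_id=f"{sid}-cell",
                        alloy=alloy.name,
                        section_area=design.strut_section.area,
                        strut_thickness=design.strut_section.radial_thickness,
                        r_ref=slc.r,
                        r_ring=slc.r,
                    )
                )
    inflate(state, balloon, pressure_atm, window, "SB")
    deflate_recoil(state, window, "SB")
    state.recross_cell = "distal"  # stated procedural assumption
    return state


def kbi(
    state: DeploymentState,
    balloon_mv: BalloonSpec,
    balloon_sb: BalloonSpec,
    pressure_mv_atm: float,
    pressure_sb_atm: float,
    mv_window: tuple[float, float] | None = None,
) -> DeploymentState:
    """Kissing balloon inflation: simultaneous MV + SB balloons.

    Proximal-MV overlap slices see the combined balloon cross-section
    (area sum, hence an area-equivalent radius sqrt(r_mv^2 + r_sb^2))
    driven at the larger of the two pressures; the SB ostium segment and
    the non-overlap MV segment behave as single-balloon inflations.
    """
    carina = state.carina_arclength
    if mv_window is None:
        mv_window = (carina - balloon_mv.length, carina)
    r_mv = balloon_diameter_at_pressure(balloon_mv, pressure_mv_atm) / 2.0
    r_sb = balloon_diameter_at_pressure(balloon_sb, pressure_sb_atm) / 2.0
    r_combined = float(np.hypot(r_mv, r_sb))
    p_drive = max(pressure_mv_atm, pressure_sb_atm)
    inflate(
        state,
        balloon_mv,
        pressure_mv_atm,
        mv_window,
        "MV",
        clamp_radius=r_combined,
        drive_pressure_atm=p_drive,
    )
    deflate_recoil(state, mv_window, "MV")
    sb_window = (carina, carina + balloon_sb.length)
    inflate(state, balloon_sb, pressure_sb_atm, sb_window, "SB")
    deflate_recoil(state, sb_window, "SB")
    return state


def malapposition_map(state: DeploymentState) -> dict[tuple[str, float], float]:
    """Per stented slice: radial strut-to-wall gap (mm), >= 0.

    gap = max(0, lumen radius - ring radius - strut thickness).
    """
    out: dict[tuple[str, float], float] = {}
    for branch in ("MV", "SB"):
        for slc in state.slices(branch):
            for layer in slc.layers:
                gap = max(0.0, slc.r - layer.r_ring - layer.strut_thickness)
                key = (branch, slc.arclength)
                out[key] = max(out.get(key, 0.0), gap)
    return out


def run_procedure(
    state: DeploymentState, table: ProcedureTable, log: list | None = None
) -> DeploymentState:
    """Replay a procedure table step by step, snapshotting after each.

    Steps are applied in order; step i+1 starts from step i's final
    state.  A balloon step referencing a branch with no deployed stent
    where one is expected (POT or SB opening before any stenting)
    raises an ordering warning but proceeds.
    """
    windows: dict[int, tuple[float, float]] = {}
    any_stent = any(s.layers for s in state.mv + state.sb)
    for i, step in enumerate(table.steps, start=1):
        if step.action in ("pot", "sb_open", "kbi") and not (
            any_stent or any(s.layers for s in state.mv + state.sb)
        ):
            warnings.warn(
                f"step {i} ({step.action}) before any stent deployment: "
                "procedure ordering is unusual",
                stacklevel=2,
            )
        dev = step.device
        if step.action == "stent":
            design = design_from_preset(
                dev.preset or "integrity_like",
                diameter_mm=dev.diameter_mm,
                length_mm=dev.length_mm,
            )
            balloon = BalloonSpec(
                nominal_diameter=dev.diameter_mm,
                length=dev.length_mm,
                compliance_class="semi_compliant",
            )
            win = _stent_window(step.placement, state, step.branch, dev.length_mm, windows)
            deploy_stent(
                state,
                design,
                balloon,
                step.pressure_atm,
                win,
                step.branch,
                mv_protrusion_mm=step.protrusion_mm,
            )
            any_stent = True
        elif step.action in ("predilate", "postdilate"):
            balloon = balloon_from_ref(dev)
            win = _stent_window(step.placement, state, step.branch, dev.length_mm, windows)
            inflate(state, balloon, step.pressure_atm, win, step.branch)
            deflate_recoil(state, win, step.branch)
        elif step.action == "pot":
            balloon = balloon_from_ref(dev)
            if step.placement.mode == "relative_to_step":
                ref = windows.get(step.placement.reference_step)
                base = ref[0] if ref else state.carina_arclength - balloon.length
                win = (base - step.placement.value_mm, base - step.placement.value_mm + balloon.length)
                win = (win[0], min(win[1], state.carina_arclength))
            else:
                win = (state.carina_arclength - balloon.length, state.carina_arclength)
            pot(state, balloon, step.pressure_atm, win)
        elif step.action == "sb_open":
            sb_open(state, balloon_from_ref(dev), step.pressure_atm)
            win = (state.carina_arclength, state.carina_arclength + dev.length_mm)
        elif step.action == "kbi":
            kbi(
                state,
                balloon_from_ref(dev),
                balloon_from_ref(step.device_sb),
                step.pressure_atm,
                step.pressure_sb_atm,
            )
            win = (state.carina_arclength - dev.length_mm, state.carina_arclength)
        else:  # pragma: no cover - guarded by ProcedureStep validation
            raise ValueError(f"unknown action {step.action}")
        windows[i] = win
        state.snapshot(f"step {i}: {step.action} {step.branch}")
        if log is not None:
            log.append(
                {
                    "step": i,
                    "action": step.action,
                    "branch": step.branch,
                    "pressure_atm": step.pressure_atm,
                    "pressure_mpa": atm_to_mpa(step.pressure_atm),
                    "window_mm": [float(win[0]), float(win[1])],
                    "provenance": state.config.provenance,
                }
            )
    return state
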