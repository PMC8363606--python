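"""Reduced-order coronary hemodynamics.

A 1-D Poiseuille surrogate for transient 3-D CFD: Carreau shear-thinning
blood viscosity, a diameter-scaled pulsatile inlet waveform, a
Huo-Kassab (HK) power-law flow split at the bifurcation
(Q_mv/Q_sb = (d_mv/d_sb)^(7/3)), per-slice wall shear stress from the
Poiseuille wall shear rate, and time-averaged WSS (TAWSS) profiles for
pre- vs post-stenting comparison.

The Poiseuille wall shear rate 4Q/(pi r^3) is flow-driven and does not
depend on viscosity, so the shear-thinning closure tau = mu(gamma_w) *
gamma_w is explicit; slice WSS is exact in the Newtonian limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CarreauParams",
    "FlowConditions",
    "WSSProfile",
    "carreau_viscosity",
    "default_waveform",
    "scale_inlet_flow",
    "hk_split",
    "slice_wss",
    "tawss_profile",
]

HK_EXPONENT = 7.0 / 3.0
REFERENCE_DIAMETER_MM = 3.0


@dataclass(frozen=True)
class CarreauParams:
    """Carreau blood rheology: mu(g) = mu_inf + (mu0-mu_inf)[1+(lam g)^2]^((n-1)/2)."""

    mu_inf: float = 0.0035  # Pa s
    mu0: float = 0.25  # Pa s
    lam: float = 25.0  # s
    n: float = 0.25

    def __post_init__(self) -> None:
        # mu0 == mu_inf is allowed: the Newtonian limit
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValueError("need mu0 >= mu_inf > 0")
        if self.lam <= 0 or not (0 < self.n < 1):
            raise ValueError("need lam > 0 and 0 < n < 1")


def carreau_viscosity(shear_rate, params: CarreauParams = CarreauParams()):
    """Apparent viscosity (Pa s); monotone nonincreasing for n < 1."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** 2
    ) ** ((params.n - 1.0) / 2.0)
    return mu if mu.ndim else float(mu)


def default_waveform(
    n_samples: int = 64, period_s: float = 0.8, mean_flow_ml_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """A generic pulsatile coronary inlet waveform (t, Q).

    Smooth, strictly positive, diastolic-dominant, mean exactly
    ``mean_flow_ml_s`` at the 3.0 mm reference inlet.  Stands in for a
    measured waveform; replaceable via FlowConditions.
    """
    t = np.linspace(0.0, period_s, n_samples, endpoint=False)
    phase = 2.0 * np.pi * t / period_s
    shape = 1.0 - 0.35 * np.cos(phase) - 0.2 * np.sin(2.0 * phase)
    shape /= shape.mean()
    return t, mean_flow_ml_s * shape


@dataclass
class FlowConditions:
    """Inlet waveform, blood properties and transient settings."""

    time_s: np.ndarray = None
    inlet_flow_ml_s: np.ndarray = None
    density: float = 1060.0  # kg/m^3
    carreau: CarreauParams = field(default_factory=CarreauParams)
    cycles: int = 3  # simulated cycles; last one is analyzed (no-op for steady 1-D)
    inlet_scaling_exponent: float = HK_EXPONENT

    def __post_init__(self) -> None:
        if self.time_s is None or self.inlet_flow_ml_s is None:
            self.time_s, self.inlet_flow_ml_s = default_waveform()
        self.time_s = np.asarray(self.time_s, float)
        self.inlet_flow_ml_s = np.asarray(self.inlet_flow_ml_s, float)
        if self.time_s.shape != self.inlet_flow_ml_s.shape:
            raise ValueError("waveform time and flow arrays must match")

    @property
    def period(self) -> float:
        dt = np.diff(self.time_s)
        return float(self.time_s[-1] - self.time_s[0] + (dt[-1] if len(dt) else 0.0))


def scale_inlet_flow(flow: FlowConditions, inlet_diameter_mm: float) -> FlowConditions:
    """Scale the inlet waveform to the inlet diameter.

    Mean flow scales as (D / 3.0 mm)^(7/3) — the same power law as the
    HK branch split, keeping inlet and outlet scaling self-consistent.
    The waveform shape and period are unchanged.
    """
    if inlet_diameter_mm <= 0:
        raise ValueError("inlet diameter must be positive")
    factor = (inlet_diameter_mm / REFERENCE_DIAMETER_MM) ** flow.inlet_scaling_exponent
    return FlowConditions(
        time_s=flow.time_s.copy(),
        inlet_flow_ml_s=flow.inlet_flow_ml_s * factor,
        density=flow.density,
        carreau=flow.carreau,
        cycles=flow.cycles,
        inlet_scaling_exponent=flow.inlet_scaling_exponent,
    )


def hk_split(d_mv_distal_mm: float, d_sb_mm: float) -> tuple[float, float]:
    """Huo-Kassab flow fractions (MV, SB) from daughter diameters.

    Q_mv / Q_sb = (d_mv / d_sb)^(7/3); the fractions sum to 1.
    """
    if d_mv_distal_mm <= 0 or d_sb_mm <= 0:
        raise ValueError("daughter diameters must be positive")
    ratio = (d_mv_distal_mm / d_sb_mm) ** HK_EXPONENT
    f_mv = ratio / (1.0 + ratio)
    return float(f_mv), float(1.0 - f_mv)


def slice_wss(q_ml_s: float, radius_mm: float, params: CarreauParams = CarreauParams()) -> float:
    """Wall shear stress (Pa) of Poiseuille flow Q through radius r.

    gamma_w = 4Q/(pi r^3) (flow-driven, viscosity-independent), then
    tau = mu(gamma_w) * gamma_w.  Exact closed form in the Newtonian
    limit; the nominal fixed point tau = 4 mu(gamma_w) Q / (pi r^3)
    converges in a single iteration and is verified to 1e-8 relative.
    """
    if q_ml_s < 0:
        raise ValueError("flow must be non-negative")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if q_ml_s == 0.0:
        return 0.0
    q = q_ml_s * 1e-6  # m^3/s
    r = radius_mm * 1e-3  # m
    gamma_w = 4.0 * q / (np.pi * r**3)
    tau = float(carreau_viscosity(gamma_w, params)) * gamma_w
    check = 4.0 * float(carreau_viscosity(gamma_w, params)) * q / (np.pi * r**3)
    if abs(tau - check) > 1e-8 * max(abs(tau), 1e-30):  # pragma: no cover
        raise RuntimeError("slice WSS fixed point failed to converge")
    return tau


@dataclass
class WSSProfile:
    arclength_mm: np.ndarray
    tawss_pa: np.ndarray
    branch: str = "MV"
    tau_t: np.ndarray | None = None  # (n_slices, n_time) instantaneous WSS

    def __post_init__(self) -> None:
        if np.any(self.tawss_pa < 0):
            raise ValueError("TAWSS must be non-negative")

    def export_csv(self, path, label: str = "") -> None:
        rows = ["arclength_mm,TAWSS_Pa,label"]
        for s, t in zip(self.arclength_mm, self.tawss_pa):
            rows.append(f"{s},{t},{label}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def tawss_profile(
    arclength_mm: np.ndarray,
    diameter_mm: np.ndarray,
    flow: FlowConditions,
    branch: str = "MV",
    carina_arclength: float | None = None,
    split: tuple[float, float] | None = None,
) -> WSSProfile:
    """Per-slice TAWSS along one branch path under the pulsatile inlet.

    The inlet waveform (scaled to the proximal diameter) feeds slices
    proximal of the carina in full; distal-MV and SB slices carry their
    HK fraction.  TAWSS is the cycle mean of the instantaneous WSS;
    with a steady waveform it equals the instantaneous value.
    """
    s = np.asarray(arclength_mm, float)
    d = np.asarray(diameter_mm, float)
    scaled = scale_inlet_flow(flow, float(d[0]))
    q_t = scaled.inlet_flow_ml_s
    fractions = np.ones_like(s)
    if carina_arclength is not None and split is not None:
        f_mv, f_sb = split
        if branch == "MV":
            fractions[s > carina_arclength] = f_mv
        else:
            fractions[:] = f_sb
    tau = np.empty((len(s), len(q_t)))
    for i, (si, di, fi) in enumerate(zip(s, d, fractions)):
        for j, qj in enumerate(q_t):
            tau[i, j] = slice_wss(fi * qj, di / 2.0, flow.carreau)
    return WSSProfile(
        arclength_mm=s,
        tawss_pa=tau.mean(axis=1),
        branch=branch,
        tau_t=tau,
    )
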