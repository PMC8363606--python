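"""Constitutive models for vessel wall, plaque, stent alloys and balloons.

The soft tissues (arterial wall, plaque classes, bench silicone) are
isotropic incompressible hyperelastic solids described by a reduced
polynomial strain-energy density

    W = sum_i Ci0 * (I1 - 3)**i,        I1 = lam**2 + 2/lam  (uniaxial)

up to sixth order.  The Cauchy stress under incompressible uniaxial
loading follows by differentiation:

    sigma(lam) = 2 * (lam**2 - 1/lam) * sum_i i * Ci0 * (I1 - 3)**(i-1)

Plaque classes additionally carry a yield stress; beyond it the stress
is capped (perfect-plasticity cap), the simplest post-yield closure
consistent with a listed yield stress alone.

Plaque heterogeneity seen on OCT (lipid / fibrous / calcified arcs) is
condensed into a quarter-step stiffness score in [-2, +2]: -2 is pure
lipid (very soft), +2 is pure calcium (very stiff), and fractional
scores interpolate between the five named class curves.

Stent alloys use bilinear elastoplasticity: isotropic linear hardening
(MP35N, Pt-Cr) or perfect plasticity (Pt-Ir core wire).  Balloons are
linear elastic membranes with a modulus fixed by compliance class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "ReducedPolynomialCoeffs",
    "AlloyModel",
    "MaterialTable",
    "PLAQUE_CLASSES",
    "load_material_table",
    "strain_energy",
    "uniaxial_stress",
    "neo_hookean_stress",
    "fit_neo_hookean",
    "score_composition",
    "curve_for_score",
    "alloy_stress",
    "balloon_modulus",
]

#: Plaque classes in stiffness order, mapped to integer scores -2..+2.
PLAQUE_CLASSES = ("very_soft", "soft", "neutral", "stiff", "very_stiff")


@dataclass(frozen=True)
class ReducedPolynomialCoeffs:
    """Reduced polynomial coefficients C10..C60 (MPa); absent orders are 0."""

    label: str
    c: tuple[float, ...]
    yield_stress: float | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        if len(self.c) < 1 or len(self.c) > 6:
            raise ValueError("between 1 and 6 coefficients (C10..C60) required")
        if self.yield_stress is not None and self.yield_stress <= 0:
            raise ValueError("yield_stress must be positive when present")


@dataclass(frozen=True)
class AlloyModel:
    """Bilinear elastoplastic stent alloy."""

    name: str
    elastic_modulus: float  # GPa
    yield_strength: float  # MPa, 0.2% offset
    tensile_strength: float | None = None  # MPa
    elongation: float | None = None  # percent
    density: float | None = None  # g/cm3
    hardening: str = "isotropic"  # or "perfect"

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0 or self.yield_strength <= 0:
            raise ValueError("modulus and yield strength must be positive")
        if self.hardening not in ("isotropic", "perfect"):
            raise ValueError(f"unknown hardening law {self.hardening!r}")

    @property
    def modulus_mpa(self) -> float:
        return self.elastic_modulus * 1000.0

    @property
    def yield_strain(self) -> float:
        return self.yield_strength / self.modulus_mpa

    @property
    def hardening_modulus(self) -> float:
        """Linear hardening slope H (MPa); 0 for perfect plasticity."""
        if self.hardening == "perfect" or self.tensile_strength is None:
            return 0.0
        eps_u = (self.elongation or 0.0) / 100.0
        span = eps_u - self.yield_strain
        if span <= 0:
            return 0.0
        return (self.tensile_strength - self.yield_strength) / span


@dataclass
class MaterialTable:
    """All constitutive constants used by the pipeline, versioned."""

    version: str
    hyperelastic: dict[str, ReducedPolynomialCoeffs]
    alloys: dict[str, AlloyModel]
    balloon_moduli: dict[str, float]
    plaque_scores: dict[str, int] = field(
        default_factory=lambda: {n: i - 2 for i, n in enumerate(PLAQUE_CLASSES)}
    )

    def __post_init__(self) -> None:
        missing = [n for n in PLAQUE_CLASSES if n not in self.hyperelastic]
        if missing:
            raise ValueError(f"material table missing plaque classes: {missing}")

    def plaque_class(self, score: int) -> ReducedPolynomialCoeffs:
        return self.hyperelastic[PLAQUE_CLASSES[score + 2]]


def load_material_table() -> MaterialTable:
    """Load the packaged material table (wall, plaque, alloy, balloon constants)."""
    raw = json.loads(
        resources.files("stentsim.data").joinpath("material_table.json").read_text()
    )
    hyper = {
        name: ReducedPolynomialCoeffs(
            label=name,
            c=tuple(entry["c"]),
            yield_stress=entry["yield_stress"],
            density=entry["density"],
        )
        for name, entry in raw["hyperelastic"].items()
    }
    alloys = {
        name: AlloyModel(
            name=name,
            elastic_modulus=e["elastic_modulus_gpa"],
            yield_strength=e["yield_strength_mpa"],
            tensile_strength=e["tensile_strength_mpa"],
            elongation=e["elongation_pct"],
            density=e["density"],
            hardening=e["hardening"],
        )
        for name, e in raw["alloys"].items()
    }
    return MaterialTable(
        version=raw["version"],
        hyperelastic=hyper,
        alloys=alloys,
        balloon_moduli=dict(raw["balloon_moduli_mpa"]),
        plaque_scores=dict(raw["plaque_class_scores"]),
    )


# module-level singleton; the table is immutable in practice
_TABLE: MaterialTable | None = None


def default_table() -> MaterialTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_material_table()
    return _TABLE


def strain_energy(coeffs: ReducedPolynomialCoeffs, stretch) -> np.ndarray | float:
    """Strain-energy density W(lam) (MPa) under incompressible uniaxial loading."""
    lam = np.asarray(stretch, dtype=float)
    x = lam**2 + 2.0 / lam - 3.0
    w = np.zeros_like(lam)
    for i, ci in enumerate(coeffs.c, start=1):
        w = w + ci * x**i
    return w if w.ndim else float(w)


def uniaxial_stress(coeffs: ReducedPolynomialCoeffs, stretch) -> np.ndarray | float:
    """Uniaxial Cauchy stress (MPa) at the given stretch(es).

    sigma = 2 (lam^2 - 1/lam) sum_i i Ci0 (I1-3)^(i-1), with the stress
    magnitude capped at the yield stress when the material lists one.
    sigma(1) = 0 exactly.
    """
    lam = np.asarray(stretch, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("stretch must be finite")
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    x = lam**2 + 2.0 / lam - 3.0
    dw = np.zeros_like(lam)
    for i, ci in enumerate(coeffs.c, start=1):
        dw = dw + i * ci * x ** (i - 1)
    sigma = 2.0 * (lam**2 - 1.0 / lam) * dw
    if coeffs.yield_stress is not None:
        sigma = np.clip(sigma, -coeffs.yield_stress, coeffs.yield_stress)
    return sigma if sigma.ndim else float(sigma)


def neo_hookean_stress(c10: float, stretch) -> np.ndarray | float:
    """Neo-Hookean uniaxial Cauchy stress: the first-order special case."""
    return uniaxial_stress(ReducedPolynomialCoeffs("neo_hookean", (float(c10),)), stretch)


def fit_neo_hookean(stretch: Sequence[float], stress: Sequence[float]) -> float:
    """Least-squares C10 (MPa) from uniaxial stress-stretch samples.

    The Neo-Hookean uniaxial stress is linear in C10, so the fit is the
    closed-form projection onto the basis function 2(lam^2 - 1/lam).
    """
    lam = np.asarray(stretch, dtype=float)
    sig = np.asarray(stress, dtype=float)
    if lam.shape != sig.shape or lam.ndim != 1:
        raise ValueError("stretch and stress must be equal-length 1-D arrays")
    if lam.size < 3:
        raise ValueError("at least 3 samples required to fit C10")
    basis = 2.0 * (lam**2 - 1.0 / lam)
    denom = float(basis @ basis)
    if denom == 0.0:
        raise ValueError("degenerate samples: all stretches at the reference state")
    return float(basis @ sig) / denom


def score_composition(
    lipid: float, fibrous: float, calcified: float
) -> float:
    """Map aggregate plaque composition fractions to a quarter-step score.

    raw = 2 (f_ca - f_lipid) / (f_ca + f_fibrous + f_lipid), rounded to
    the nearest quarter with ties toward zero.  Pure calcium gives +2
    (very stiff), pure lipid -2 (very soft), pure fibrous 0 (neutral).
    """
    if lipid < 0 or fibrous < 0 or calcified < 0:
        raise ValueError("composition fractions must be non-negative")
    total = lipid + fibrous + calcified
    if total <= 0:
        raise ValueError("all-zero composition has no plaque score")
    raw = 2.0 * (calcified - lipid) / total
    q = 4.0 * raw
    qa = abs(q)
    frac = qa - math.floor(qa)
    if abs(frac - 0.5) < 1e-12:  # tie: round toward zero
        rounded = math.floor(qa)
    else:
        rounded = math.floor(qa + 0.5)
    score = math.copysign(rounded, q) / 4.0
    return float(np.clip(score, -2.0, 2.0))


def quarter_scores() -> np.ndarray:
    """All admissible plaque scores: -2.0, -1.75, ..., +2.0."""
    return np.arange(-8, 9) / 4.0


def curve_for_score(
    score: float,
    stretches: Sequence[float] | np.ndarray | None = None,
    table: MaterialTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stress-stretch curve for a (possibly fractional) plaque score.

    Integer scores return the named class curve exactly; fractional
    scores interpolate linearly in stress between the two adjacent
    class curves at each stretch sample.  Returns (stretch, stress_MPa).
    """
    if not (-2.0 <= score <= 2.0):
        raise ValueError(f"plaque score {score} outside [-2, +2]")
    if round(score * 4) != score * 4:
        raise ValueError(f"plaque score {score} is not a quarter step")
    table = table or default_table()
    lam = (
        np.linspace(0.9, 1.3, 81) if stretches is None else np.asarray(stretches, float)
    )
    lo = int(math.floor(score))
    hi = int(math.ceil(score))
    sig_lo = np.asarray(uniaxial_stress(table.plaque_class(lo), lam))
    if hi == lo:
        return lam, sig_lo
    sig_hi = np.asarray(uniaxial_stress(table.plaque_class(hi), lam))
    w = score - lo
    return lam, (1.0 - w) * sig_lo + w * sig_hi


def score_stress(score: float, stretch: float, table: MaterialTable | None = None) -> float:
    """Uniaxial stress (MPa) for a plaque score at a single stretch."""
    _, sig = curve_for_score(score, np.atleast_1d(float(stretch)), table)
    return float(sig[0])


def alloy_stress(alloy: AlloyModel, strain) -> np.ndarray | float:
    """Monotone-loading bilinear stress (MPa) at the given engineering strain.

    Elastic slope E up to the yield strain, then linear hardening (slope
    H from tensile strength and elongation) or a flat plateau for
    perfect plasticity.  Unloading (handled by callers tracking plastic
    strain) has slope E.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < 0):
        raise ValueError("strain must be non-negative for monotone loading")
    e_mpa = alloy.modulus_mpa
    eps_y = alloy.yield_strain
    h = alloy.hardening_modulus
    sigma = np.where(
        eps <= eps_y,
        e_mpa * eps,
        alloy.yield_strength + h * (eps - eps_y),
    )
    return sigma if sigma.ndim else float(sigma)


def balloon_modulus(compliance_class: str, table: MaterialTable | None = None) -> float:
    """Elastic modulus (MPa) for a balloon compliance class."""
    table = table or default_table()
    try:
        return table.balloon_moduli[compliance_class]
    except KeyError:
        raise ValueError(
            f"unknown compliance class {compliance_class!r}; "
            f"expected one of {sorted(table.balloon_moduli)}"
        ) from None


def export_curve_csv(path, coeffs: ReducedPolynomialCoeffs, stretches=None) -> None:
    """Write a (strain, stress_MPa) CSV for one material."""
    lam = np.linspace(0.9, 1.3, 81) if stretches is None else np.asarray(stretches, float)
    sig = np.asarray(uniaxial_stress(coeffs, lam))
    arr = np.column_stack([lam - 1.0, sig])
    np.savetxt(path, arr, delimiter=",", header="strain,stress_MPa", comments="")
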