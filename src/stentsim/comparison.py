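"""Validation harness: diameter profiles and Bland-Altman agreement.

Simulated and reference geometries are compared as diameter-vs-arclength
profiles: the mean lumen diameter (MLD) profile of the vessel and the
mean stent diameter (MSD) profile of the deployed stent.  Profiles are
co-registered with the carina as the fixed landmark, paired by linear
interpolation of the reference, and summarized by Bland-Altman bias and
95% limits of agreement (bias +- 1.96 * sample SD of the paired
differences).  By construction the bias is exactly the midpoint of the
limits; the per-slice diameter is area-equivalent, 2*sqrt(A/pi), with a
mean-chord alternative available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiameterProfile",
    "BlandAltmanResult",
    "mld_profile",
    "msd_profile",
    "coregister",
    "bland_altman",
    "bias_from_limits",
    "report_tables",
]


@dataclass
class DiameterProfile:
    arclength: np.ndarray  # mm, strictly increasing
    diameter: np.ndarray  # mm
    carina_arclength: float
    label: str = ""

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, float)
        self.diameter = np.asarray(self.diameter, float)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength samples must be strictly increasing")
        if np.any(self.diameter <= 0):
            raise ValueError("diameters must be positive")

    def relative_to_carina(self) -> np.ndarray:
        return self.arclength - self.carina_arclength


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mm
    sd: float  # mm, sample SD of differences
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    n: int

    def __post_init__(self) -> None:
        assert abs(self.loa_low - (self.bias - 1.96 * self.sd)) < 1e-9
        assert abs(self.loa_high - (self.bias + 1.96 * self.sd)) < 1e-9


def mld_profile(
    arclength: np.ndarray,
    area_mm2: np.ndarray | None = None,
    diameter_mm: np.ndarray | None = None,
    carina_arclength: float = 0.0,
    label: str = "MLD",
    method: str = "area",
) -> DiameterProfile:
    """Mean-lumen-diameter profile from per-slice areas or diameters.

    ``method='area'`` converts slice areas to area-equivalent diameters
    2*sqrt(A/pi); with explicit diameters (e.g. mean chord over 360
    rays) they are taken as-is.
    """
    s = np.asarray(arclength, float)
    if diameter_mm is not None:
        d = np.asarray(diameter_mm, float)
    elif area_mm2 is not None:
        if method != "area":
            raise ValueError("areas imply the area-equivalent method")
        d = 2.0 * np.sqrt(np.asarray(area_mm2, float) / np.pi)
    else:
        raise ValueError("provide either areas or diameters")
    return DiameterProfile(s, d, carina_arclength, label)


def mld_from_state(state, branch: str = "MV", label: str = "sim MLD") -> DiameterProfile:
    """MLD profile of a deployment state (lumen radii x 2)."""
    s, d = state.profile(branch)
    return DiameterProfile(s, d, state.carina_arclength, label)


def msd_profile(
    state_or_samples,
    branch: str = "MV",
    label: str = "MSD",
) -> DiameterProfile:
    """Mean-stent-diameter profile over stented slices.

    Accepts a deployment state (ring radii) or a pre-computed
    (arclength, diameter, carina) triple.  Slices without struts are
    absent from the profile, not zero.
    """
    if isinstance(state_or_samples, tuple):
        s, d, carina = state_or_samples
        return DiameterProfile(np.asarray(s, float), np.asarray(d, float), carina, label)
    state = state_or_samples
    s, d = state.stent_profile(branch)
    if len(s) == 0:
        raise ValueError(f"no stented slices on branch {branch}")
    return DiameterProfile(s, d, state.carina_arclength, label)


def coregister(
    profile_sim: DiameterProfile, profile_ref: DiameterProfile
) -> np.ndarray:
    """Carina-aligned paired differences (sim - ref), one per sim sample.

    Both profiles are shifted so the carina is at arclength zero; pairs
    form at simulated samples inside the reference range, with the
    reference linearly interpolated.
    """
    s_sim = profile_sim.relative_to_carina()
    s_ref = profile_ref.relative_to_carina()
    lo = max(s_sim[0], s_ref[0])
    hi = min(s_sim[-1], s_ref[-1])
    if hi <= lo:
        raise ValueError("profiles do not overlap after carina co-registration")
    mask = (s_sim >= lo) & (s_sim <= hi)
    ref_interp = np.interp(s_sim[mask], s_ref, profile_ref.diameter)
    return profile_sim.diameter[mask] - ref_interp


def bland_altman(differences: np.ndarray) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences.

    bias = mean(d); sd = sample standard deviation (n-1 denominator);
    limits = bias +- 1.96 sd.
    """
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(d.size),
    )


def bias_from_limits(loa_low: float, loa_high: float) -> float:
    """Recover the bias as the midpoint of the 95% limits of agreement.

    An identity of the Bland-Altman construction: limits are placed
    symmetrically (+-1.96 SD) around the bias.
    """
    return 0.5 * (loa_low + loa_high)


def report_tables(
    cases: dict[str, np.ndarray], decimals: int = 2
) -> tuple[pd.DataFrame, str]:
    """Per-case Bland-Altman table plus a pooled overall row.

    ``cases`` maps row labels (e.g. "Bench #1 MV") to arrays of paired
    differences.  The overall row pools all differences (a fresh
    Bland-Altman over the concatenation, not a mean of biases).
    Returns (DataFrame, markdown table).
    """
    if not cases:
        raise ValueError("no cases to report")
    rows = []
    for name, diffs in cases.items():
        r = bland_altman(np.asarray(diffs))
        rows.append((name, r.bias, r.loa_low, r.loa_high, r.n))
    pooled = bland_altman(np.concatenate([np.asarray(d) for d in cases.values()]))
    rows.append(("Overall", pooled.bias, pooled.loa_low, pooled.loa_high, pooled.n))
    df = pd.DataFrame(
        rows, columns=["case", "bias_mm", "loa_low_mm", "loa_high_mm", "n"]
    )
    md_lines = [
        "| Case | Bias (mm) | 95% limits of agreement (mm) | n |",
        "|---|---|---|---|",
    ]
    for _, row in df.iterrows():
        md_lines.append(
            f"| {row['case']} | {row['bias_mm']:.{decimals}f} | "
            f"{row['loa_low_mm']:.{decimals}f} to {row['loa_high_mm']:.{decimals}f} | {int(row['n'])} |"
        )
    return df, "\n".join(md_lines)
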