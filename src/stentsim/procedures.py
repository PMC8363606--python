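"""Procedure tables: the step grammar of bifurcation stenting.

A procedure is an ordered list of steps, each naming an action
(pre-dilatation, stenting, POT, SB strut opening, KBI, post-dilatation),
a branch, a device with its size, an inflation pressure in atm (as
printed on clinical procedure tables), and a placement rule.  Placement
is either an absolute arclength window or relative to an earlier step
("more proximally than step #k" by a stated offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["DeviceRef", "Placement", "ProcedureStep", "ProcedureTable", "TEMPLATES"]

ACTIONS = ("predilate", "stent", "pot", "sb_open", "kbi", "postdilate")


@dataclass(frozen=True)
class DeviceRef:
    """A stent or balloon as named in a procedure table row."""

    kind: str  # "stent" | "balloon"
    preset: str | None = None  # stent preset name, e.g. "integrity_like"
    diameter_mm: float = 3.0
    length_mm: float = 15.0
    compliance_class: str | None = None  # balloons only

    def __post_init__(self) -> None:
        if self.kind not in ("stent", "balloon"):
            raise ValueError(f"unknown device kind {self.kind!r}")
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("device dimensions must be positive")


@dataclass(frozen=True)
class Placement:
    """Placement window rule for one step."""

    mode: str = "auto"  # "auto" | "arclength" | "relative_to_step"
    value_mm: float = 0.0  # window start (arclength) or proximal offset
    reference_step: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "arclength", "relative_to_step"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.mode == "relative_to_step" and self.reference_step is None:
            raise ValueError("relative placement needs a reference step")


@dataclass(frozen=True)
class ProcedureStep:
    action: str
    branch: str  # "MV" | "SB"
    device: DeviceRef
    pressure_atm: float
    placement: Placement = field(default_factory=Placement)
    device_sb: DeviceRef | None = None  # KBI second balloon
    pressure_sb_atm: float | None = None
    protrusion_mm: float = 0.0  # SB stent protrusion into the proximal MV

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.pressure_atm <= 0:
            raise ValueError("pressure must be positive")
        if self.action == "kbi" and (self.device_sb is None or self.pressure_sb_atm is None):
            raise ValueError("KBI needs an SB balloon and pressure")


@dataclass
class ProcedureTable:
    name: str
    steps: list[ProcedureStep]

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "steps": [
                {k: v for k, v in asdict(s).items() if v is not None}
                for s in self.steps
            ],
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ProcedureTable":
        steps = []
        for raw in d["steps"]:
            raw = dict(raw)
            dev = DeviceRef(**raw.pop("device"))
            dev_sb = raw.pop("device_sb", None)
            placement = Placement(**raw.pop("placement", {}))
            steps.append(
                ProcedureStep(
                    device=dev,
                    device_sb=DeviceRef(**dev_sb) if dev_sb else None,
                    placement=placement,
                    **raw,
                )
            )
        # backward references only
        for i, s in enumerate(steps):
            ref = s.placement.reference_step
            if ref is not None and ref >= i + 1:
                raise ValueError(f"step {i + 1} references a later step #{ref}")
        return cls(name=d.get("name", "procedure"), steps=steps)

    @classmethod
    def from_yaml(cls, path) -> "ProcedureTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Step sequences of the supported stenting techniques.  Each entry is
#: (action, branch, device role); devices are looked up by role in the
#: device mapping handed to the generator.
TEMPLATES: dict[str, list[tuple[str, str, str]]] = {
    "provisional": [
        ("stent", "MV", "mv_stent"),
        ("pot", "MV", "pot_balloon"),
        ("sb_open", "SB", "sb_balloon"),
        ("kbi", "MV", "kbi_balloons"),
    ],
    "TAP": [
        ("stent", "MV", "mv_stent"),
        ("pot", "MV", "pot_balloon"),
        ("sb_open", "SB", "sb_balloon"),
        ("stent", "SB", "sb_stent"),
        ("kbi", "MV", "kbi_balloons"),
    ],
    "TAP_long_protrusion": [
        ("stent", "MV", "mv_stent"),
        ("pot", "MV", "pot_balloon"),
        ("sb_open", "SB", "sb_balloon"),
        ("stent", "SB", "sb_stent"),
        ("kbi", "MV", "kbi_balloons"),
    ],
    "culotte": [
        ("stent", "SB", "sb_stent"),
        ("pot", "MV", "pot_balloon"),
        ("sb_open", "SB", "sb_balloon"),
        ("stent", "MV", "mv_stent"),
        ("pot", "MV", "pot_balloon"),
        ("kbi", "MV", "kbi_balloons"),
    ],
}
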