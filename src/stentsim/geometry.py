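"""Centerlines, arclength parameterization and rotation-minimizing frames.

Conventions used throughout the package: right-handed coordinates in mm;
centerline arclength measured from the proximal main-vessel (MV) inlet;
the carina sits at a stored arclength; circumferential angles are
counter-clockwise from the side-branch (SB) ostium direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Centerline", "cumulative_arclength", "rotation_minimizing_frames", "resample_polyline"]


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n points uniform in arclength fraction."""
    pts = np.asarray(points, dtype=float)
    s = cumulative_arclength(pts)
    if s[-1] <= 0:
        raise ValueError("degenerate polyline with zero length")
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, k]) for k in range(pts.shape[1])])


def rotation_minimizing_frames(
    points: np.ndarray, e1_start: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent and two normal fields along a polyline (double-reflection method).

    Returns (t, e1, e2), each (N, 3).  The frame is propagated without
    spurious twist; the absolute rotation is fixed by ``e1_start``
    (projected to the first normal plane) when given.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    # tangents: central differences
    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)

    e1 = np.zeros_like(pts)
    # initial normal
    if e1_start is not None:
        v = np.asarray(e1_start, dtype=float)
        v = v - (v @ t[0]) * t[0]
        if np.linalg.norm(v) < 1e-12:
            raise ValueError("e1_start parallel to the initial tangent")
    else:
        trial = np.array([0.0, 0.0, 1.0])
        if abs(trial @ t[0]) > 0.9:
            trial = np.array([1.0, 0.0, 0.0])
        v = trial - (trial @ t[0]) * t[0]
    e1[0] = v / np.linalg.norm(v)

    for i in range(n - 1):
        d = pts[i + 1] - pts[i]
        c1 = d @ d
        if c1 < 1e-30:
            e1[i + 1] = e1[i]
            continue
        rL = e1[i] - (2.0 / c1) * (d @ e1[i]) * d
        tL = t[i] - (2.0 / c1) * (d @ t[i]) * d
        v2 = t[i + 1] - tL
        c2 = v2 @ v2
        e1[i + 1] = rL if c2 < 1e-30 else rL - (2.0 / c2) * (v2 @ rL) * v2
        e1[i + 1] -= (e1[i + 1] @ t[i + 1]) * t[i + 1]
        e1[i + 1] /= np.linalg.norm(e1[i + 1])
    e2 = np.cross(t, e1)
    return t, e1, e2


@dataclass
class Centerline:
    """An arclength-parameterized 3D branch centerline."""

    points: np.ndarray
    branch: str = "MV"
    carina_arclength: float | None = None
    arclength_offset: float = 0.0  # arclength of points[0] from the MV inlet
    arclength: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        s = cumulative_arclength(self.points)
        if np.any(np.diff(s) <= 0):
            raise ValueError("duplicate consecutive centerline points")
        self.arclength = s + self.arclength_offset

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])

    def point_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)]
        )
        return out[0] if out.shape[0] == 1 else out

    def frames(self, e1_start: np.ndarray | None = None):
        return rotation_minimizing_frames(self.points, e1_start)

    def frame_at(self, s: float, frames=None, e1_start=None):
        """Interpolated (point, t, e1, e2) at arclength s."""
        if frames is None:
            frames = self.frames(e1_start)
        t, e1, e2 = frames
        idx = np.clip(np.searchsorted(self.arclength, s) - 1, 0, len(self.arclength) - 2)
        s0, s1 = self.arclength[idx], self.arclength[idx + 1]
        w = 0.0 if s1 == s0 else (s - s0) / (s1 - s0)

        def lerp(a):
            v = (1 - w) * a[idx] + w * a[idx + 1]
            return v / np.linalg.norm(v)

        p = (1 - w) * self.points[idx] + w * self.points[idx + 1]
        return p, lerp(t), lerp(e1), lerp(e2)
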