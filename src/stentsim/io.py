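"""Export helpers: legacy ASCII VTK polylines, STL via trimesh, CSV."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_polylines", "write_stent_vtk"]


def write_vtk_polylines(path, points: np.ndarray, lines: list[list[int]]) -> None:
    """Write polylines in legacy ASCII VTK (POLYDATA) format."""
    points = np.asarray(points, float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npolylines\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(v) for v in [len(l), *l]) + "\n")


def write_stent_vtk(path, node_xyz: np.ndarray, edges) -> None:
    """Export a stent node graph as VTK line segments."""
    write_vtk_polylines(path, node_xyz, [[i, j] for i, j, *_ in edges])


def write_stent_csv(path, node_xyz: np.ndarray, edges) -> None:
    """Edge-list CSV: i,j,kind plus node coordinates header block."""
    rows = ["# nodes: index,x,y,z"]
    for k, p in enumerate(np.asarray(node_xyz, float)):
        rows.append(f"n,{k},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
    rows.append("# edges: i,j,kind")
    for i, j, *kind in edges:
        rows.append(f"e,{i},{j},{kind[0] if kind else 'edge'}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
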