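"""Ternary (barycentric) mapping and plotting of DRQ compositions.

Each assemblage's (D, R, Q) triplet sums to one and is therefore a point
in a triangle whose corners are the pure compositions: a corner means the
respective component equals 1, and component values decrease linearly
with distance from their corner. Default orientation puts dominance D at
the top vertex, redundancy R bottom-left and Rao diversity Q
bottom-right; plots are accompanied by a plain-text coordinate dump so
results can be checked without comparing pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TernaryPoint", "ternary_xy", "ternary_inverse", "ternary_table", "render_ternary"]

_H = math.sqrt(3.0) / 2.0
# vertex positions for the default orientation
VERTICES = {"D": (0.5, _H), "R": (0.0, 0.0), "Q": (1.0, 0.0)}


@dataclass(frozen=True)
class TernaryPoint:
    x: float
    y: float
    group: str = ""
    composition: tuple[float, float, float] | None = None


def ternary_xy(composition, group: str = "") -> TernaryPoint:
    """Map a (D, R, Q) composition to Cartesian plot coordinates.

    x = Q + D/2, y = D·√3/2 — the barycentric combination of the three
    vertex positions.
    """
    d, r, q = (
        composition.as_tuple() if hasattr(composition, "as_tuple") else tuple(composition)
    )
    if abs(d + r + q - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    return TernaryPoint(x=q + d / 2.0, y=d * _H, group=group, composition=(d, r, q))


def ternary_inverse(x: float, y: float) -> tuple[float, float, float]:
    """Recover (D, R, Q) from plot coordinates (exact barycentric inverse)."""
    d = y / _H
    q = x - d / 2.0
    return (d, 1.0 - d - q, q)


def ternary_table(compositions: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Attach plot coordinates (and a group column) to a compositions table.

    ``compositions`` is indexed by (host_species, unit) with D/R/Q columns,
    as produced by :func:`drqdiv.drq.compose_table`; ``group_by`` may be
    ``"host_species"``, ``"unit"`` or an existing column.
    """
    out = compositions.copy()
    out["x"] = out["Q"] + out["D"] / 2.0
    out["y"] = out["D"] * _H
    if group_by is None:
        out["group"] = ""
    elif group_by in out.index.names:
        out["group"] = out.index.get_level_values(group_by)
    elif group_by in out.columns:
        out["group"] = out[group_by].astype(str)
    else:
        raise KeyError(f"unknown grouping column {group_by!r}")
    return out


def _triangle_frame(ax, grid_steps: int = 5) -> None:
    tri = np.array([VERTICES["R"], VERTICES["Q"], VERTICES["D"], VERTICES["R"]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1.2, zorder=1)
    for i in range(1, grid_steps):
        t = i / grid_steps
        for comp in ("D", "R", "Q"):
            # line of constant `comp` = t: connect the two edge points
            others = [k for k in "DRQ" if k != comp]
            pts = []
            for other in others:
                bary = {comp: t, other: 1 - t, ({"D", "R", "Q"} - {comp, other}).pop(): 0.0}
                pt = ternary_xy((bary["D"], bary["R"], bary["Q"]))
                pts.append((pt.x, pt.y))
            (x0, y0), (x1, y1) = pts
            ax.plot([x0, x1], [y0, y1], color="0.85", lw=0.5, zorder=0)
    offs = {"D": (0, 0.04), "R": (-0.04, -0.05), "Q": (0.04, -0.05)}
    for name, (vx, vy) in VERTICES.items():
        dx, dy = offs[name]
        ax.annotate(name, (vx + dx, vy + dy), ha="center", va="center", fontsize=12)
    ax.set_xlim(-0.1, 1.1)
    ax.set_ylim(-0.12, _H + 0.12)
    ax.set_aspect("equal")
    ax.axis("off")


def render_ternary(
    points: pd.DataFrame,
    path: str | Path,
    title: str | None = None,
    grid_steps: int = 5,
    point_size: float = 30.0,
) -> Path:
    """Render a DRQ ternary diagram and write a coordinate dump beside it.

    ``points`` must carry columns ``x, y, group`` (see
    :func:`ternary_table`); the figure format follows the file suffix
    (.svg or .png) and ``<stem>_coords.csv`` is written next to it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(points) == 0:
        raise ValueError("no points to plot")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.6))
    _triangle_frame(ax, grid_steps=grid_steps)
    groups = list(dict.fromkeys(points["group"]))
    markers = "osD^v<>Pp*Xh"
    cmap = plt.get_cmap("tab10")
    for i, g in enumerate(groups):
        sub = points[points["group"] == g]
        ax.scatter(
            sub["x"], sub["y"], s=point_size,
            marker=markers[i % len(markers)], color=cmap(i % 10),
            edgecolor="black", linewidth=0.3,
            label=str(g) if g != "" else None, zorder=2,
        )
    if any(g != "" for g in groups):
        ax.legend(loc="upper left", bbox_to_anchor=(0.98, 1.0), fontsize=8, frameon=False)
    if title:
        ax.set_title(title, fontsize=11)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)

    dump_cols = [c for c in ("group", "D", "R", "Q", "x", "y") if c in points.columns]
    dump = points.reset_index()[
        [c for c in ("host_species", "unit") if c in points.reset_index().columns] + dump_cols
    ]
    dump.to_csv(path.with_name(path.stem + "_coords.csv"), index=False, float_format="%.12g")
    return path
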