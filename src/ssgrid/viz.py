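"""State space grid plots and cumulative frame sequences.

A grid plot shows one node per event, placed inside its cell with seeded
random jitter, sized so that node *area* is proportional to event duration
(with a minimum radius floor for visibility), connected by arrows in event
order, with the first node highlighted. The :class:`PlotSpec` holding all
geometry is pure data: it serializes to JSON, supports manual node
repositioning, and rendering it twice produces identical images.

An optional padding row and column can be drawn around the grid, visually
muted; the padding is decoration only and never enters the state space or
any measure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Rectangle

from .errors import ValidationError
from .grid import Cell, StateSpace, slice_trajectory
from .trajectory import Trajectory

__all__ = [
    "Node",
    "PlotSpec",
    "build_plot_spec",
    "plot_grid",
    "frame_specs",
    "render_frames",
]

MAX_RADIUS = 0.33  # cell units; longest event gets this radius
MIN_RADIUS = 0.05  # visibility floor
JITTER_MARGIN = 0.02  # keep-out from the cell border beyond the radius


@dataclass(frozen=True)
class Node:
    """One rendered event: its cell, center offset within the cell
    (cell units, relative to the cell center), radius, and event order."""

    cell: Cell
    dx: float
    dy: float
    radius: float
    order: int


@dataclass
class PlotSpec:
    """Complete, render-ready geometry of one grid plot."""

    x_labels: list[str]
    y_labels: list[str]
    x_name: str
    y_name: str
    nodes: list[Node]
    arrows: list[tuple[int, int]]  # node-index pairs, event order
    highlight_first: bool
    jitter_seed: int
    padding: bool = True

    def move_node(self, order: int, dx: float, dy: float) -> None:
        """Manually reposition one node (offsets in cell units)."""
        n = self.nodes[order]
        self.nodes[order] = Node(n.cell, dx, dy, n.radius, n.order)

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "PlotSpec":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        doc["nodes"] = [
            Node(tuple(n["cell"]), n["dx"], n["dy"], n["radius"], n["order"])
            for n in doc["nodes"]
        ]
        doc["arrows"] = [tuple(a) for a in doc["arrows"]]
        return cls(**doc)


def _radii(durations: list[float]) -> list[float]:
    dmax = max(durations)
    radii = []
    for d in durations:
        r = MAX_RADIUS * math.sqrt(d / dmax) if dmax > 0 else MAX_RADIUS
        radii.append(max(r, MIN_RADIUS))
    return radii


def build_plot_spec(
    traj: Trajectory,
    space: StateSpace,
    window: tuple[float, float] | None = None,
    jitter_seed: int = 0,
    padding: bool = True,
) -> PlotSpec:
    """Lay out nodes and arrows for a (windowed) trajectory.

    Deterministic given ``jitter_seed``: each node's jitter is drawn from
    one seeded generator in event order, and the jitter never pushes a node
    across its cell boundary (margin of at least the node radius).
    """
    if window is not None:
        traj = slice_trajectory(traj, *window)
    from .grid import _event_cells  # shared event->cell mapping

    cells = _event_cells(traj, space)
    durations = traj.durations()
    radii = _radii(durations)
    rng = np.random.default_rng(jitter_seed)
    nodes = []
    for order, (cell, r) in enumerate(zip(cells, radii)):
        limit = max(0.5 - r - JITTER_MARGIN, 0.0)
        dx, dy = rng.uniform(-limit, limit, size=2)
        nodes.append(Node(cell, float(dx), float(dy), r, order))
    arrows = [(i, i + 1) for i in range(len(nodes) - 1)]
    return PlotSpec(
        x_labels=list(space.x_dim.categories),
        y_labels=list(space.y_dim.categories),
        x_name=space.x_dim.name,
        y_name=space.y_dim.name,
        nodes=nodes,
        arrows=arrows,
        highlight_first=True,
        jitter_seed=jitter_seed,
        padding=padding,
    )


def render(spec: PlotSpec, path) -> None:
    """Draw a PlotSpec to a PNG/SVG file (pure function of the spec)."""
    nx, ny = len(spec.x_labels), len(spec.y_labels)
    pad = 1 if spec.padding else 0
    fig, ax = plt.subplots(figsize=(1.1 * (nx + pad) + 1.4, 1.1 * (ny + pad) + 1.0))
    if spec.padding:
        # decoration only: a muted extra column (left) and row (bottom)
        ax.add_patch(Rectangle((-1, -1), 1, ny + 1, color="0.92", zorder=0))
        ax.add_patch(Rectangle((-1, -1), nx + 1, 1, color="0.92", zorder=0))
    for gx in range(-pad, nx + 1):
        ax.plot([gx, gx], [-pad, ny], color="0.7", lw=0.8, zorder=1)
    for gy in range(-pad, ny + 1):
        ax.plot([-pad, nx], [gy, gy], color="0.7", lw=0.8, zorder=1)

    centers = []
    for n in spec.nodes:
        cx = n.cell[0] + 0.5 + n.dx
        cy = n.cell[1] + 0.5 + n.dy
        centers.append((cx, cy))
        first = spec.highlight_first and n.order == 0
        ax.add_patch(
            Circle(
                (cx, cy),
                n.radius,
                facecolor="tab:blue",
                alpha=0.55,
                edgecolor="red" if first else "black",
                linewidth=1.8 if first else 0.8,
                zorder=3,
            )
        )
    for i, j in spec.arrows:
        (x0, y0), (x1, y1) = centers[i], centers[j]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(arrowstyle="->", color="0.25", lw=0.9),
            zorder=2,
        )

    ax.set_xticks([i + 0.5 for i in range(nx)])
    ax.set_xticklabels(spec.x_labels, rotation=45, ha="right")
    ax.set_yticks([i + 0.5 for i in range(ny)])
    ax.set_yticklabels(spec.y_labels)
    ax.set_xlabel(spec.x_name)
    ax.set_ylabel(spec.y_name)
    ax.set_xlim(-pad - 0.05, nx + 0.05)
    ax.set_ylim(-pad - 0.05, ny + 0.05)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_grid(
    traj: Trajectory,
    space: StateSpace,
    path=None,
    window: tuple[float, float] | None = None,
    jitter_seed: int = 0,
    padding: bool = True,
) -> PlotSpec:
    """Build (and optionally render) the grid plot for a trajectory."""
    spec = build_plot_spec(traj, space, window, jitter_seed, padding)
    if path is not None:
        render(spec, path)
    return spec


def frame_specs(
    traj: Trajectory,
    space: StateSpace,
    step: float,
    jitter_seed: int = 0,
    padding: bool = True,
) -> list[PlotSpec]:
    """PlotSpecs of the cumulative 'movie' of a trajectory.

    Frame *k* (1-based) covers the window ``[start, start + k*step)``; the
    final frame shows the full trajectory, so the frame count is
    ``ceil(total_duration / step)``. Node placement is computed once for
    the full trajectory and subset per frame, so nodes never move between
    frames.
    """
    if step <= 0:
        raise ValidationError("frame step must be positive")
    full = build_plot_spec(traj, space, None, jitter_seed, padding)
    onsets = [e.onset for e in traj.events]
    n_frames = math.ceil(traj.total_duration / step)
    specs = []
    for k in range(1, n_frames + 1):
        t_end = min(traj.start + k * step, traj.offset)
        keep = [n for n, onset in zip(full.nodes, onsets) if onset < t_end]
        specs.append(
            PlotSpec(
                x_labels=full.x_labels,
                y_labels=full.y_labels,
                x_name=full.x_name,
                y_name=full.y_name,
                nodes=keep,
                arrows=[(i, i + 1) for i in range(len(keep) - 1)],
                highlight_first=full.highlight_first,
                jitter_seed=jitter_seed,
                padding=padding,
            )
        )
    return specs


def render_frames(
    traj: Trajectory,
    space: StateSpace,
    step: float,
    out_dir,
    jitter_seed: int = 0,
    padding: bool = True,
) -> list[Path]:
    """Render the cumulative frame sequence to ``frame_NNNN.png`` files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, spec in enumerate(frame_specs(traj, space, step, jitter_seed, padding), 1):
        path = out_dir / f"frame_{k:04d}.png"
        render(spec, path)
        paths.append(path)
    return paths
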