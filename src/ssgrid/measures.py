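"""Content and structure measures of state space grids.

Content measures describe *where* the system spent its events and time
(per-cell and per-region tallies, proportions, rates). Structure measures
describe *how* it moved: cell range, total cell transitions, dispersion,
and Shannon entropies of the visit, duration, and transition distributions.

Conventions
-----------
* Proportions are fractions of the whole trajectory (events or duration);
  they sum to 1 over the grid.
* Dispersion is the inverted, cell-count-corrected sum of squared
  proportional durations: 0 when all time sits in one cell, 1 when time is
  spread evenly over every cell of the defined state space. The correction
  uses *all* cells of the space, visited or not.
* Entropies use the natural logarithm (nats) and the 0*ln(0) = 0
  convention. Transition entropy is taken over distinct ordered
  (from, to) cell pairs.
* Values are never rounded internally; round only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import Cell, StateSpace, VisitSequence, transitions

__all__ = [
    "CELL_STAT_COLUMNS",
    "GridMeasures",
    "RegionStats",
    "cell_stats",
    "region_stats",
    "axis_profile",
    "share_sd",
    "dispersion",
    "visit_entropy",
    "duration_entropy",
    "transition_entropy",
    "grid_measures",
    "pooled_measures",
    "measures_frame",
]

CELL_STAT_COLUMNS = [
    "events",
    "visits",
    "total_duration",
    "mean_duration_per_visit",
    "event_proportion",
    "duration_proportion",
    "events_per_minute",
]


def _shannon(weights: Iterable[float]) -> float:
    """-sum q ln q over positive normalized weights."""
    w = np.asarray(list(weights), dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValidationError("entropy of an all-zero distribution is undefined")
    q = w[w > 0] / total
    return float(-(q * np.log(q)).sum())


def cell_stats(vs: VisitSequence) -> pd.DataFrame:
    """Per-cell content measures over every cell of the state space.

    Returns a DataFrame indexed by ``(x_index, y_index)`` with columns
    ``events, visits, total_duration, mean_duration_per_visit,
    event_proportion, duration_proportion, events_per_minute``. Unvisited
    cells report zeros.
    """
    space = vs.space
    idx = pd.MultiIndex.from_tuples(space.cells(), names=["x_index", "y_index"])
    df = pd.DataFrame(0.0, index=idx, columns=CELL_STAT_COLUMNS)
    for v in vs.visits:
        df.loc[v.cell, "events"] += v.n_events
        df.loc[v.cell, "visits"] += 1
        df.loc[v.cell, "total_duration"] += v.duration
    visited = df["visits"] > 0
    df.loc[visited, "mean_duration_per_visit"] = (
        df.loc[visited, "total_duration"] / df.loc[visited, "visits"]
    )
    total_events = df["events"].sum()
    total_duration = df["total_duration"].sum()
    df["event_proportion"] = df["events"] / total_events
    df["duration_proportion"] = df["total_duration"] / total_duration
    df["events_per_minute"] = df["events"] / (total_duration / 60.0)
    return df


@dataclass(frozen=True)
class RegionStats:
    """Aggregate content measures for a set of cells (row, column, ...).

    ``visits`` counts *region-level* visits: maximal runs of consecutive
    visits inside the region, so bouncing between two cells of one region
    counts once.
    """

    n_cells: int
    events: int
    visits: int
    total_duration: float
    event_proportion: float
    duration_proportion: float
    events_per_minute: float


def region_stats(vs: VisitSequence, region: Iterable[Cell]) -> RegionStats:
    """Aggregate events, visits, and durations over a cell region."""
    region = frozenset(tuple(c) for c in region)
    if not region:
        raise ValidationError("region is empty")
    unknown = region - set(vs.space.cells())
    if unknown:
        raise ValidationError(f"region contains unknown cells: {sorted(unknown)}")
    events = sum(v.n_events for v in vs.visits if v.cell in region)
    duration = sum(v.duration for v in vs.visits if v.cell in region)
    region_visits = 0
    inside = False
    for v in vs.visits:
        if v.cell in region:
            if not inside:
                region_visits += 1
            inside = True
        else:
            inside = False
    total_duration = vs.total_duration
    return RegionStats(
        n_cells=len(region),
        events=events,
        visits=region_visits,
        total_duration=duration,
        event_proportion=events / vs.n_events,
        duration_proportion=duration / total_duration,
        events_per_minute=events / (total_duration / 60.0),
    )


def axis_profile(vs: VisitSequence, axis: str = "x") -> pd.DataFrame:
    """Per-category aggregates along one axis (e.g., per-speaker columns).

    One row per category of the chosen axis, aggregating that category's
    full column (``axis="x"``) or row (``axis="y"``).
    """
    space = vs.space
    if axis == "x":
        dim, region_of = space.x_dim, space.column
    elif axis == "y":
        dim, region_of = space.y_dim, space.row
    else:
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    rows = []
    for i, label in enumerate(dim.categories):
        rs = region_stats(vs, region_of(i))
        rows.append({"category": label, **asdict(rs)})
    return pd.DataFrame(rows).set_index("category").drop(columns="n_cells")


def share_sd(vs: VisitSequence, axis: str = "x", by: str = "duration_proportion",
             ddof: int = 1) -> float:
    """Standard deviation of per-category percentage shares along an axis.

    Quantifies how unevenly events or time are distributed over the
    categories of one axis — e.g., the SD of per-speaker percentages of
    total talk time. Returned on the percentage scale (shares x 100);
    sample SD by default.
    """
    profile = axis_profile(vs, axis)
    return float((100.0 * profile[by]).std(ddof=ddof))


def dispersion(vs: VisitSequence, space: StateSpace | None = None) -> float:
    """Inverted, cell-count-corrected sum of squared proportional durations.

    ``1 - (n * sum(p_i^2) - 1) / (n - 1)`` with *n* the number of cells of
    the defined state space and ``p_i`` each cell's share of total
    duration. 0 = all time in one cell; 1 = time uniform over all cells.
    """
    space = space or vs.space
    n = space.n_cells
    if n < 2:
        raise ValidationError("dispersion undefined for a state space with < 2 cells")
    total = vs.total_duration
    if total <= 0:
        raise ValidationError("dispersion undefined for zero total duration")
    by_cell: dict[Cell, float] = {}
    for v in vs.visits:
        by_cell[v.cell] = by_cell.get(v.cell, 0.0) + v.duration
    p = np.array(list(by_cell.values())) / total
    return float(1.0 - (n * (p**2).sum() - 1.0) / (n - 1.0))


def visit_entropy(vs: VisitSequence) -> float:
    """Shannon entropy (nats) of per-cell visit proportions."""
    counts: dict[Cell, int] = {}
    for v in vs.visits:
        counts[v.cell] = counts.get(v.cell, 0) + 1
    return _shannon(counts.values())


def duration_entropy(vs: VisitSequence) -> float:
    """Shannon entropy (nats) of per-cell duration proportions."""
    durs: dict[Cell, float] = {}
    for v in vs.visits:
        durs[v.cell] = durs.get(v.cell, 0.0) + v.duration
    return _shannon(durs.values())


def transition_entropy(vs: VisitSequence) -> float:
    """Shannon entropy (nats) over distinct ordered (from, to) transitions."""
    trans = transitions(vs)
    if not trans:
        raise ValidationError("no transitions: sequence has a single visit")
    counts: dict[tuple[Cell, Cell], int] = {}
    for t in trans:
        counts[t] = counts.get(t, 0) + 1
    return _shannon(counts.values())


@dataclass(frozen=True)
class GridMeasures:
    """Whole-grid structure measures for one (or a pool of) trajectories."""

    n_events: int
    n_visits: int
    n_transitions: int
    cell_range: int
    dispersion: float
    visit_entropy: float
    duration_entropy: float
    transition_entropy: float | None

    def as_dict(self) -> dict:
        return asdict(self)

    def allclose(self, other: "GridMeasures", tol: float = 1e-9) -> bool:
        """Equality with floating-point slack on the real-valued measures
        (summation order may differ between equivalent computations)."""
        if (self.n_events, self.n_visits, self.n_transitions, self.cell_range) != (
            other.n_events,
            other.n_visits,
            other.n_transitions,
            other.cell_range,
        ):
            return False
        for a, b in (
            (self.dispersion, other.dispersion),
            (self.visit_entropy, other.visit_entropy),
            (self.duration_entropy, other.duration_entropy),
            (self.transition_entropy, other.transition_entropy),
        ):
            if (a is None) != (b is None):
                return False
            if a is not None and abs(a - b) > tol:
                return False
        return True


def grid_measures(vs: VisitSequence, space: StateSpace | None = None) -> GridMeasures:
    """Bundle all structure measures for one visit sequence.

    ``transition_entropy`` is ``None`` for single-visit sequences, where no
    transition distribution exists.
    """
    space = space or vs.space
    return GridMeasures(
        n_events=vs.n_events,
        n_visits=vs.n_visits,
        n_transitions=vs.n_visits - 1,
        cell_range=len(vs.visited_cells()),
        dispersion=dispersion(vs, space),
        visit_entropy=visit_entropy(vs),
        duration_entropy=duration_entropy(vs),
        transition_entropy=transition_entropy(vs) if vs.n_visits > 1 else None,
    )


def pooled_measures(
    sequences: Iterable[VisitSequence],
) -> tuple[GridMeasures, pd.DataFrame]:
    """Pool several visit sequences over one shared state space.

    Proportions pool over summed durations and visit tallies; transitions
    never cross trajectory boundaries, so ``n_transitions`` is the sum of
    per-trajectory ``visits - 1``. Returns the pooled bundle plus a
    per-trajectory table for between-team comparison.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValidationError("no visit sequences to pool")
    space = seqs[0].space
    if any(s.space != space for s in seqs):
        raise ValidationError("cannot pool sequences over different state spaces")

    visit_counts: dict[Cell, int] = {}
    durs: dict[Cell, float] = {}
    trans_counts: dict[tuple[Cell, Cell], int] = {}
    n_events = n_visits = n_transitions = 0
    for s in seqs:
        n_events += s.n_events
        n_visits += s.n_visits
        n_transitions += s.n_visits - 1
        for v in s.visits:
            visit_counts[v.cell] = visit_counts.get(v.cell, 0) + 1
            durs[v.cell] = durs.get(v.cell, 0.0) + v.duration
        for t in transitions(s):
            trans_counts[t] = trans_counts.get(t, 0) + 1

    n = space.n_cells
    total = sum(durs.values())
    p = np.array(list(durs.values())) / total
    pooled = GridMeasures(
        n_events=n_events,
        n_visits=n_visits,
        n_transitions=n_transitions,
        cell_range=len(visit_counts),
        dispersion=float(1.0 - (n * (p**2).sum() - 1.0) / (n - 1.0)),
        visit_entropy=_shannon(visit_counts.values()),
        duration_entropy=_shannon(durs.values()),
        transition_entropy=_shannon(trans_counts.values()) if trans_counts else None,
    )
    per_traj = measures_frame(seqs)
    return pooled, per_traj


def measures_frame(sequences: Iterable[VisitSequence]) -> pd.DataFrame:
    """One row of grid measures per visit sequence, for tabular export."""
    rows = []
    for s in sequences:
        gm = grid_measures(s)
        rows.append({"trajectory_id": s.trajectory_id, **gm.as_dict()})
    return pd.DataFrame(rows)
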