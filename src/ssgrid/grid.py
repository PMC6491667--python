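"""State spaces, visits, transitions, and time-window slicing.

The state space is the plane spanned by two categorical axes; each cell is
one joint state. A trajectory's events map onto cells; maximal runs of
consecutive events in the same cell collapse into *visits*, the unit for
transition counting: transitions = visits - 1 per trajectory, because the
first visit is not a transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codebook import Codebook, Dimension
from .errors import ValidationError, WindowError
from .trajectory import Event, Trajectory

__all__ = [
    "StateSpace",
    "Visit",
    "VisitSequence",
    "make_state_space",
    "to_visits",
    "transitions",
    "slice_trajectory",
]

Cell = tuple[int, int]  # (x_index, y_index), 0-based


@dataclass(frozen=True)
class StateSpace:
    """A two-dimensional grid of joint states.

    ``x_dim`` and ``y_dim`` keep the codebook's category order; cells are
    addressed ``(x_index, y_index)``, 0-based. Any display padding a plotting
    front end adds around the grid is never part of the state space.
    """

    x_dim: Dimension
    y_dim: Dimension

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValidationError(
                "state space must contain at least 2 cells "
                f"(got {len(self.x_dim)} x {len(self.y_dim)})"
            )

    @property
    def n_cells(self) -> int:
        return len(self.x_dim) * len(self.y_dim)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.x_dim), len(self.y_dim))

    def cells(self) -> list[Cell]:
        """All cells in row-major (x-major) order."""
        return [(x, y) for x in range(len(self.x_dim)) for y in range(len(self.y_dim))]

    def cell_of(self, x_label: str, y_label: str) -> Cell:
        return (self.x_dim.index(x_label), self.y_dim.index(y_label))

    def labels_of(self, cell: Cell) -> tuple[str, str]:
        return (self.x_dim.categories[cell[0]], self.y_dim.categories[cell[1]])

    def column(self, x: int | str) -> frozenset[Cell]:
        """All cells sharing one x category (e.g., one speaker's column)."""
        xi = x if isinstance(x, int) else self.x_dim.index(x)
        if not 0 <= xi < len(self.x_dim):
            raise ValidationError(f"column index {xi} out of range")
        return frozenset((xi, y) for y in range(len(self.y_dim)))

    def row(self, y: int | str) -> frozenset[Cell]:
        """All cells sharing one y category (e.g., one behavior code's row)."""
        yi = y if isinstance(y, int) else self.y_dim.index(y)
        if not 0 <= yi < len(self.y_dim):
            raise ValidationError(f"row index {yi} out of range")
        return frozenset((x, yi) for x in range(len(self.x_dim)))


@dataclass(frozen=True)
class Visit:
    """A maximal run of consecutive events in one cell."""

    cell: Cell
    start: float
    duration: float
    n_events: int


@dataclass(frozen=True)
class VisitSequence:
    """The run-length-collapsed behavioral trajectory.

    Conserves the source trajectory exactly: visit durations sum to the
    total observed duration, and visit event counts sum to the event count.
    """

    visits: tuple[Visit, ...]
    trajectory_id: str
    space: StateSpace

    def __post_init__(self):
        object.__setattr__(self, "visits", tuple(self.visits))
        for a, b in zip(self.visits, self.visits[1:]):
            if a.cell == b.cell:
                raise ValidationError(
                    f"consecutive visits occupy the same cell {a.cell}"
                )

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_events(self) -> int:
        return sum(v.n_events for v in self.visits)

    @property
    def total_duration(self) -> float:
        return sum(v.duration for v in self.visits)

    def visited_cells(self) -> list[Cell]:
        """Distinct visited cells, in first-visit order."""
        seen: dict[Cell, None] = {}
        for v in self.visits:
            seen.setdefault(v.cell, None)
        return list(seen)


def make_state_space(codebook: Codebook, x_dim: str, y_dim: str) -> StateSpace:
    """Build the grid from two named codebook dimensions.

    Axis category order follows the codebook; reordering categories is a
    visualization option, never a property of the space itself.
    """
    if x_dim == y_dim:
        raise ValidationError("x and y dimensions must differ")
    return StateSpace(codebook.dimension(x_dim), codebook.dimension(y_dim))


def _event_cells(traj: Trajectory, space: StateSpace) -> list[Cell]:
    xi = traj.codebook.names.index(space.x_dim.name)
    yi = traj.codebook.names.index(space.y_dim.name)
    return [space.cell_of(ev.values[xi], ev.values[yi]) for ev in traj.events]


def to_visits(traj: Trajectory, space: StateSpace) -> VisitSequence:
    """Collapse a trajectory into its visit sequence over ``space``.

    Events landing in the same cell as their predecessor extend the current
    visit; a cell change opens a new one. Durations and event counts are
    conserved exactly.
    """
    cells = _event_cells(traj, space)
    durations = traj.durations()
    visits: list[Visit] = []
    run_start = traj.events[0].onset
    run_cell = cells[0]
    run_dur = 0.0
    run_n = 0
    for i, cell in enumerate(cells):
        if cell != run_cell:
            visits.append(Visit(run_cell, run_start, run_dur, run_n))
            run_cell = cell
            run_start = traj.events[i].onset
            run_dur = 0.0
            run_n = 0
        run_dur += durations[i]
        run_n += 1
    visits.append(Visit(run_cell, run_start, run_dur, run_n))
    return VisitSequence(tuple(visits), traj.id, space)


def transitions(vs: VisitSequence) -> list[tuple[Cell, Cell]]:
    """Ordered cell-to-cell movements; length is always visits - 1."""
    return [(a.cell, b.cell) for a, b in zip(vs.visits, vs.visits[1:])]


def slice_trajectory(traj: Trajectory, t0: float, t1: float) -> Trajectory:
    """Restrict a trajectory to the half-open window ``[t0, t1)``.

    Events overlapping the window are kept; the first kept event's onset is
    clipped to ``t0`` and the offset to ``t1``, so the sliced trajectory
    covers the overlap with no gaps (the system occupies a state at every
    instant). Adjacent windows ``[0, a)`` and ``[a, b)`` therefore partition
    time with no double counting.
    """
    if t0 >= t1:
        raise WindowError(f"window [{t0}, {t1}) is empty")
    start, end = traj.start, traj.offset
    lo, hi = max(t0, start), min(t1, end)
    if lo >= hi:
        raise WindowError(
            f"window [{t0}, {t1}) outside observation [{start}, {end})"
        )
    kept: list[Event] = []
    onsets = [e.onset for e in traj.events] + [traj.offset]
    for i, ev in enumerate(traj.events):
        ev_end = onsets[i + 1]
        if ev_end <= lo or ev.onset >= hi:
            continue
        onset = max(ev.onset, lo)
        kept.append(Event(onset, ev.values))
    return Trajectory(id=traj.id, codebook=traj.codebook, events=kept, offset=hi)
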