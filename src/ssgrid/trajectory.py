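"""Timed categorical trajectories.

A trajectory is one observation session: a strictly increasing sequence of
event onsets, one category label per coded dimension at each event, and a
terminal offset marking the end of observation. An event lasts until the
next event's onset (the last event until the offset), so durations are
implied, strictly positive, and sum exactly to ``offset - first onset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codebook import Codebook
from .errors import ValidationError

__all__ = [
    "Event",
    "Trajectory",
    "TrajectoryCollection",
    "ValidationReport",
    "validate",
]

#: Coding-practice guidance: units finer than one second are discouraged
#: because most annotation tools resolve to seconds.
MIN_RECOMMENDED_DURATION = 1.0


@dataclass(frozen=True)
class Event:
    """A coded joint occurrence: onset in seconds plus one label per dimension."""

    onset: float
    values: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "onset", float(self.onset))
        object.__setattr__(self, "values", tuple(self.values))


@dataclass
class Trajectory:
    """One observation session over a codebook.

    Parameters
    ----------
    id : str
        Session identifier (file stem, team/meeting label, ...).
    codebook : Codebook
        The coding scheme; ``events[i].values`` aligns with
        ``codebook.dimensions``.
    events : list of Event
        Strictly increasing onsets; at least one event.
    offset : float
        End of observation, strictly after the last onset.
    """

    id: str
    codebook: Codebook
    events: list[Event] = field(default_factory=list)
    offset: float = 0.0

    def __post_init__(self):
        self.events = [e if isinstance(e, Event) else Event(*e) for e in self.events]
        self.offset = float(self.offset)
        problems = _structural_violations(self)
        if problems:
            raise ValidationError(problems)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def start(self) -> float:
        return self.events[0].onset

    @property
    def total_duration(self) -> float:
        return self.offset - self.events[0].onset

    def durations(self) -> list[float]:
        """Per-event durations: next onset minus onset; last uses the offset."""
        onsets = [e.onset for e in self.events] + [self.offset]
        return [onsets[i + 1] - onsets[i] for i in range(len(self.events))]

    def __eq__(self, other):
        if not isinstance(other, Trajectory):
            return NotImplemented
        if self.id != other.id or self.codebook != other.codebook:
            return False
        if len(self.events) != len(other.events):
            return False
        if abs(self.offset - other.offset) > 1e-9:
            return False
        for a, b in zip(self.events, other.events):
            if a.values != b.values or abs(a.onset - b.onset) > 1e-9:
                return False
        return True


@dataclass
class TrajectoryCollection:
    """Several trajectories coded with one shared codebook."""

    trajectories: list[Trajectory]

    def __post_init__(self):
        if not self.trajectories:
            raise ValidationError("collection must contain at least one trajectory")
        cb = self.trajectories[0].codebook
        for t in self.trajectories[1:]:
            if t.codebook != cb:
                raise ValidationError(
                    f"trajectory {t.id!r} uses a different codebook than {self.trajectories[0].id!r}"
                )

    @property
    def codebook(self) -> Codebook:
        return self.trajectories[0].codebook

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: hard violations and soft warnings."""

    violations: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def _structural_violations(traj: Trajectory) -> list[str]:
    problems: list[str] = []
    if not traj.events:
        problems.append(f"trajectory {traj.id!r}: no events")
        return problems
    ndim = len(traj.codebook)
    prev = None
    for i, ev in enumerate(traj.events):
        if len(ev.values) != ndim:
            problems.append(
                f"trajectory {traj.id!r} event {i}: expected {ndim} values, got {len(ev.values)}"
            )
            continue
        for dim, label in zip(traj.codebook.dimensions, ev.values):
            if label not in dim.categories:
                problems.append(
                    f"trajectory {traj.id!r} event {i}: category {label!r} "
                    f"not in dimension {dim.name!r}"
                )
        if prev is not None and ev.onset <= prev:
            problems.append(
                f"trajectory {traj.id!r} event {i}: onset {ev.onset} not greater "
                f"than previous onset {prev}"
            )
        prev = ev.onset
    if traj.events and traj.offset <= traj.events[-1].onset:
        problems.append(
            f"trajectory {traj.id!r}: offset {traj.offset} must exceed last "
            f"onset {traj.events[-1].onset}"
        )
    return problems


def validate(traj: Trajectory) -> ValidationReport:
    """Check a trajectory and report violations and warnings.

    Violations repeat the construction-time invariants (useful after manual
    mutation or for raw data assembled outside the constructors). Sub-second
    event durations produce a warning, not a violation: coding time units
    finer than one second are discouraged but legal.
    """
    violations = _structural_violations(traj)
    warnings = []
    if not violations:
        for i, d in enumerate(traj.durations()):
            if d < MIN_RECOMMENDED_DURATION:
                warnings.append(
                    f"trajectory {traj.id!r} event {i}: duration {d:.3f} s is below "
                    f"the recommended 1 s minimum coding unit"
                )
    return ValidationReport(violations=violations, warnings=warnings)
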