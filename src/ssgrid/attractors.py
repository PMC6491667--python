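"""Attractor description: return statistics, top cells, and winnowing.

An *attractor* is a state (or region) the system settles into often or
long; its strength shows in short return times and few intervening visits
when the system strays. The *winnowing* procedure identifies candidate
attractor cells bottom-up: it iteratively deletes the lowest-duration
cells and tracks a chi-square-style heterogeneity of the remaining
observed durations against a uniform expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .grid import Cell, StateSpace, VisitSequence

__all__ = [
    "Excursion",
    "ReturnStats",
    "WinnowScreen",
    "WinnowResult",
    "return_stats",
    "top_cells",
    "winnow",
]


@dataclass(frozen=True)
class Excursion:
    """One departure from a region: exit time, reentry (or censored), and
    the number of visits made outside before returning."""

    exit_time: float
    reentry_time: float | None
    visits_outside: int

    @property
    def censored(self) -> bool:
        return self.reentry_time is None

    @property
    def return_time(self) -> float | None:
        if self.censored:
            return None
        return self.reentry_time - self.exit_time


@dataclass(frozen=True)
class ReturnStats:
    """Attractor-strength indices for a region.

    Means cover completed excursions only; a trailing excursion that never
    re-enters before the observation ends is censored and excluded (its
    count is reported so users can judge the impact). Means are ``None``
    when no excursion completed.
    """

    region: frozenset[Cell]
    excursions: tuple[Excursion, ...]
    n_excursions: int
    n_censored: int
    mean_return_time: float | None
    mean_return_visits: float | None


def return_stats(vs: VisitSequence, region: Iterable[Cell]) -> ReturnStats:
    """Scan a visit sequence for excursions away from ``region``.

    An excursion starts when the system leaves the region and ends when it
    next enters it; return time is the elapsed seconds, return visits the
    number of outside visits in between.
    """
    region = frozenset(tuple(c) for c in region)
    if not region:
        raise ValidationError("region is empty")
    if not any(v.cell in region for v in vs.visits):
        raise ValidationError("region not visited")

    excursions: list[Excursion] = []
    exit_time: float | None = None
    outside = 0
    for v in vs.visits:
        if v.cell in region:
            if exit_time is not None:
                excursions.append(Excursion(exit_time, v.start, outside))
                exit_time = None
        else:
            if exit_time is None:
                exit_time = v.start  # leaving the region starts the clock
                outside = 0
            outside += 1
    if exit_time is not None:  # observation ended mid-excursion
        excursions.append(Excursion(exit_time, None, outside))

    completed = [e for e in excursions if not e.censored]
    n_censored = len(excursions) - len(completed)
    mean_rt = mean_rv = None
    if completed:
        mean_rt = sum(e.return_time for e in completed) / len(completed)
        mean_rv = sum(e.visits_outside for e in completed) / len(completed)
    return ReturnStats(
        region=region,
        excursions=tuple(excursions),
        n_excursions=len(excursions),
        n_censored=n_censored,
        mean_return_time=mean_rt,
        mean_return_visits=mean_rv,
    )


def top_cells(stats: pd.DataFrame, by: str = "visits", k: int = 3) -> list[Cell]:
    """Rank visited cells by one content measure.

    ``by`` is one of ``visits``, ``total_duration``,
    ``mean_duration_per_visit``. Ties break by total duration, then event
    count, then cell index (ascending), so the ranking is deterministic.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    allowed = {"visits", "total_duration", "mean_duration_per_visit"}
    if by not in allowed:
        raise ValidationError(f"ranking criterion {by!r} not in {sorted(allowed)}")
    visited = stats[stats["visits"] > 0]
    ordered = sorted(
        visited.index,
        key=lambda c: (
            -visited.loc[c, by],
            -visited.loc[c, "total_duration"],
            -visited.loc[c, "events"],
            c,
        ),
    )
    return [tuple(c) for c in ordered[:k]]


@dataclass(frozen=True)
class WinnowScreen:
    """One winnowing step: cells removed, cells remaining, and the
    heterogeneity of observed vs. expected (uniform) durations among the
    remaining cells."""

    removed_cells: frozenset[Cell]
    remaining_cells: frozenset[Cell]
    heterogeneity: float


@dataclass(frozen=True)
class WinnowResult:
    """Full screen log plus the selected attractor candidate cells."""

    screens: tuple[WinnowScreen, ...]
    selected_screen: int
    attractor_cells: frozenset[Cell]

    def screen_frame(self) -> pd.DataFrame:
        """Screen log as a table for CSV export."""
        rows = []
        for i, s in enumerate(self.screens):
            rows.append(
                {
                    "screen": i,
                    "n_removed": len(s.removed_cells),
                    "n_remaining": len(s.remaining_cells),
                    "removed_cells": ";".join(map(str, sorted(s.removed_cells))),
                    "remaining_cells": ";".join(map(str, sorted(s.remaining_cells))),
                    "heterogeneity": s.heterogeneity,
                    "selected": i == self.selected_screen,
                }
            )
        return pd.DataFrame(rows)


def _heterogeneity(durations: dict[Cell, float]) -> float:
    """Chi-square-style sum of (observed - expected)^2 / expected with a
    uniform expected duration over the given cells."""
    expected = sum(durations.values()) / len(durations)
    return sum((d - expected) ** 2 / expected for d in durations.values())


def winnow(
    vs: VisitSequence,
    space: StateSpace | None = None,
    stop_ratio: float = 0.5,
) -> WinnowResult:
    """Iteratively delete lowest-duration cells to isolate attractors.

    Screen 0 scores all visited cells. Each subsequent screen removes the
    cell(s) of minimal total duration (ties removed together, so the log is
    permutation-invariant), then recomputes heterogeneity over the
    remaining cells against a uniform expectation. Screening stops before
    the remaining set would shrink below two cells; if only one cell was
    ever visited, it is returned directly as the sole attractor.

    The selected screen is the last one whose proportional heterogeneity
    change from its predecessor is at least ``stop_ratio`` (screen 0 if
    none qualifies); the surviving cells there are the attractor
    candidates. The full log is always returned, so any alternative
    stopping rule can be applied post hoc.
    """
    durs: dict[Cell, float] = {}
    for v in vs.visits:
        durs[v.cell] = durs.get(v.cell, 0.0) + v.duration
    cells = frozenset(durs)
    if len(cells) == 1:
        only = WinnowScreen(frozenset(), cells, 0.0)
        return WinnowResult((only,), 0, cells)

    screens = [WinnowScreen(frozenset(), cells, _heterogeneity(durs))]
    remaining = dict(durs)
    while len(remaining) > 2:
        low = min(remaining.values())
        drop = frozenset(c for c, d in remaining.items() if d == low)
        if len(remaining) - len(drop) < 2:
            break
        for c in drop:
            del remaining[c]
        screens.append(
            WinnowScreen(drop, frozenset(remaining), _heterogeneity(remaining))
        )

    selected = 0
    for i in range(1, len(screens)):
        prev, cur = screens[i - 1].heterogeneity, screens[i].heterogeneity
        if prev > 0:
            change = abs(cur - prev) / prev
        else:
            change = float("inf") if cur > 0 else 0.0
        if change >= stop_ratio:
            selected = i
    return WinnowResult(tuple(screens), selected, screens[selected].remaining_cells)
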