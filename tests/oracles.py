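"""Independent brute-force reference implementations.

Everything here is deliberately written as plain event-loop Python over
raw trajectory data (dicts, lists, math.log) without reusing any of the
package's measure code, so it can serve as an independent cross-check of
the library's vectorized/structured implementations.
"""

import math
from statistics import stdev


def event_cells(traj, space):
    """Map each event to its (x_index, y_index) cell by direct label lookup."""
    names = [d.name for d in traj.codebook.dimensions]
    xi = names.index(space.x_dim.name)
    yi = names.index(space.y_dim.name)
    xs = list(space.x_dim.categories)
    ys = list(space.y_dim.categories)
    return [(xs.index(ev.values[xi]), ys.index(ev.values[yi])) for ev in traj.events]


def event_durations(traj):
    out = []
    for i, ev in enumerate(traj.events):
        nxt = traj.events[i + 1].onset if i + 1 < len(traj.events) else traj.offset
        out.append(nxt - ev.onset)
    return out


def rle_visits(traj, space):
    """Run-length encode events into (cell, start, duration, n_events)."""
    cells = event_cells(traj, space)
    durs = event_durations(traj)
    runs = []
    for i, c in enumerate(cells):
        if runs and runs[-1][0] == c:
            cell, start, d, n = runs[-1]
            runs[-1] = (cell, start, d + durs[i], n + 1)
        else:
            runs.append((c, traj.events[i].onset, durs[i], 1))
    return runs


def shannon(values):
    total = sum(values)
    h = 0.0
    for v in values:
        if v > 0:
            p = v / total
            h -= p * math.log(p)
    return h


def cell_tallies(traj, space):
    """Per-cell (events, visits, duration) dicts from a raw event scan."""
    ev_count, vis_count, dur = {}, {}, {}
    cells = event_cells(traj, space)
    durs = event_durations(traj)
    prev = None
    for i, c in enumerate(cells):
        ev_count[c] = ev_count.get(c, 0) + 1
        dur[c] = dur.get(c, 0.0) + durs[i]
        if c != prev:
            vis_count[c] = vis_count.get(c, 0) + 1
        prev = c
    return ev_count, vis_count, dur


def grid_measures(traj, space):
    """All structure measures from scratch."""
    runs = rle_visits(traj, space)
    ev_count, vis_count, dur = cell_tallies(traj, space)
    n = len(space.x_dim.categories) * len(space.y_dim.categories)
    total = sum(dur.values())
    sum_p2 = sum((d / total) ** 2 for d in dur.values())
    trans = {}
    for a, b in zip(runs, runs[1:]):
        key = (a[0], b[0])
        trans[key] = trans.get(key, 0) + 1
    return {
        "n_events": sum(ev_count.values()),
        "n_visits": len(runs),
        "n_transitions": len(runs) - 1,
        "cell_range": len(vis_count),
        "dispersion": 1.0 - (n * sum_p2 - 1.0) / (n - 1.0),
        "visit_entropy": shannon(vis_count.values()),
        "duration_entropy": shannon(dur.values()),
        "transition_entropy": shannon(trans.values()) if trans else None,
    }


def dispersion_from_durations(durations, n_cells):
    """Direct formula on a raw duration vector (zeros allowed)."""
    total = sum(durations)
    sum_p2 = sum((d / total) ** 2 for d in durations)
    return 1.0 - (n_cells * sum_p2 - 1.0) / (n_cells - 1.0)


def region_tallies(traj, space, region):
    """Events, region-level visits, and duration inside a cell region."""
    region = set(region)
    runs = rle_visits(traj, space)
    events = sum(n for c, _, _, n in runs if c in region)
    duration = sum(d for c, _, d, _ in runs if c in region)
    visits = 0
    inside = False
    for c, _, _, _ in runs:
        if c in region:
            if not inside:
                visits += 1
            inside = True
        else:
            inside = False
    return {"events": events, "visits": visits, "duration": duration}


def column_share_sd(traj, space, axis="x"):
    """Sample SD of per-category duration percentage shares along an axis."""
    _, _, dur = cell_tallies(traj, space)
    total = sum(dur.values())
    k = len(space.x_dim.categories) if axis == "x" else len(space.y_dim.categories)
    pos = 0 if axis == "x" else 1
    shares = []
    for i in range(k):
        shares.append(100.0 * sum(d for c, d in dur.items() if c[pos] == i) / total)
    return stdev(shares)


def return_stats(traj, space, region):
    """Excursion scan: (completed [(return_time, visits_outside)], n_censored)."""
    region = set(region)
    runs = rle_visits(traj, space)
    completed = []
    censored = 0
    exit_time = None
    outside = 0
    for c, start, _, _ in runs:
        if c in region:
            if exit_time is not None:
                completed.append((start - exit_time, outside))
                exit_time = None
        else:
            if exit_time is None:
                exit_time = start
                outside = 0
            outside += 1
    if exit_time is not None:
        censored = 1
    return completed, censored


def winnow_screens(traj, space):
    """Screen log: list of (removed frozenset, remaining frozenset, heterogeneity)."""
    _, _, dur = cell_tallies(traj, space)
    remaining = dict(dur)

    def het(d):
        exp = sum(d.values()) / len(d)
        return sum((v - exp) ** 2 / exp for v in d.values())

    if len(remaining) == 1:
        return [(frozenset(), frozenset(remaining), 0.0)]
    screens = [(frozenset(), frozenset(remaining), het(remaining))]
    while len(remaining) > 2:
        low = min(remaining.values())
        drop = frozenset(c for c, v in remaining.items() if v == low)
        if len(remaining) - len(drop) < 2:
            break
        for c in drop:
            del remaining[c]
        screens.append((drop, frozenset(remaining), het(remaining)))
    return screens
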