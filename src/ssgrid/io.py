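"""Reading and writing trajectory files.

Two dialects are supported:

* **.trj** — GridWare-style tab-delimited, one trajectory per file.
  Line 1 is a header ``Onset<TAB>dim1<TAB>dim2...``; each following line is
  an onset in decimal seconds plus one category label per dimension.
  The final data row carries the terminal offset: its onset ends the
  observation, and any category cells on it are ignored (exported files
  vary in whether they repeat the last state there). Lines starting with
  ``#`` are comments.

* **long format** — CSV/TSV with columns
  ``trajectory_id, onset, dim1, dim2...`` holding many trajectories.
  The terminal offset per trajectory comes either from a terminal row with
  empty category cells or from a declared uniform ``offset`` argument.

Onsets are written as the shortest decimal that parses back to the exact
float, so reading then writing a file produced by :func:`write_trj`
reproduces it byte for byte and the in-memory round trip is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .codebook import Codebook
from .errors import ValidationError
from .trajectory import Event, Trajectory, TrajectoryCollection

__all__ = ["read_trj", "write_trj", "read_long", "write_long", "ONSET_COLUMN"]

ONSET_COLUMN = "Onset"


def _format_onset(t: float) -> str:
    """Decimal seconds: integers bare, otherwise the shortest decimal that
    parses back to exactly the same float (sub-second precision is never
    truncated)."""
    if t == int(t):
        return str(int(t))
    return repr(t)


def _parse_onset(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{where}: onset {text!r} is not a number") from None


def read_trj(path, codebook: Codebook, id: str | None = None) -> Trajectory:
    """Parse a tab-delimited .trj file into a :class:`Trajectory`.

    The header must name the onset column first, then the codebook's
    dimensions (in any order; the header fixes the column layout). The last
    data row supplies the terminal offset; category cells on it, if present,
    are ignored. Missing category values in any non-terminal row are an
    error — the interaction stream must be exhaustive, with no gaps.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [
        (lineno, line.split("\t"))
        for lineno, line in enumerate(lines, start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if len(rows) < 3:
        raise ValidationError(
            f"{path}: need a header plus at least two data rows (event + terminal)"
        )
    header_no, header = rows[0]
    header = [h.strip() for h in header]
    if not header or header[0].lower() != ONSET_COLUMN.lower():
        raise ValidationError(
            f"{path} line {header_no}: first header column must be {ONSET_COLUMN!r}"
        )
    dim_names = header[1:]
    if sorted(dim_names) != sorted(codebook.names):
        raise ValidationError(
            f"{path} line {header_no}: header dimensions {dim_names} do not match "
            f"codebook dimensions {list(codebook.names)}"
        )
    # column position of each codebook dimension within the data rows
    col_of = {name: 1 + dim_names.index(name) for name in codebook.names}

    events = []
    violations = []
    data = rows[1:]
    for k, (lineno, cells) in enumerate(data):
        terminal = k == len(data) - 1
        onset = _parse_onset(cells[0], f"{path} line {lineno}")
        if terminal:
            offset = onset
            break
        values = []
        for dim in codebook.dimensions:
            j = col_of[dim.name]
            label = cells[j].strip() if j < len(cells) else ""
            if not label:
                violations.append(
                    f"{path} line {lineno}: missing value for dimension "
                    f"{dim.name!r} (no gaps allowed)"
                )
            elif label not in dim.categories:
                violations.append(
                    f"{path} line {lineno}: category {label!r} not in "
                    f"dimension {dim.name!r}"
                )
            values.append(label)
        if events and onset <= events[-1].onset:
            violations.append(
                f"{path} line {lineno}: onset {onset} not greater than previous"
            )
        events.append(Event(onset, tuple(values)))
    if violations:
        raise ValidationError(violations)
    return Trajectory(id=id or path.stem, codebook=codebook, events=events, offset=offset)


def write_trj(traj: Trajectory, path) -> None:
    """Write a trajectory in the .trj dialect (terminal row = bare offset)."""
    lines = ["\t".join([ONSET_COLUMN, *traj.codebook.names])]
    for ev in traj.events:
        lines.append("\t".join([_format_onset(ev.onset), *ev.values]))
    lines.append(_format_onset(traj.offset))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".trj", ".txt"}:
        return "\t"
    return ","


def read_long(
    path,
    codebook: Codebook,
    offset: float | None = None,
) -> TrajectoryCollection:
    """Parse a long-format delimited table into a collection of trajectories.

    Rows are grouped by ``trajectory_id`` and sorted by onset within each
    id, so shuffled input is equivalent to sorted input. A row whose
    category cells are all empty is the terminal row for its trajectory;
    alternatively a uniform ``offset`` (absolute seconds) may be declared
    for every trajectory. Duplicate (id, onset) pairs are an error.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        table = [row for row in reader if row and any(c.strip() for c in row)]
    if not table:
        raise ValidationError(f"{path}: empty file")
    header = [h.strip() for h in table[0]]
    expected = ["trajectory_id", "onset", *codebook.names]
    if sorted(header) != sorted(expected):
        raise ValidationError(
            f"{path}: header {header} does not match expected columns {expected}"
        )
    idx = {name: header.index(name) for name in expected}

    groups: dict[str, list[tuple[float, list[str], int]]] = {}
    for lineno, row in enumerate(table[1:], start=2):
        tid = row[idx["trajectory_id"]].strip()
        onset = _parse_onset(row[idx["onset"]], f"{path} line {lineno}")
        labels = [
            row[idx[name]].strip() if idx[name] < len(row) else ""
            for name in codebook.names
        ]
        groups.setdefault(tid, []).append((onset, labels, lineno))

    trajectories = []
    violations = []
    for tid in sorted(groups):  # id order, independent of row order
        rows = sorted(groups[tid], key=lambda r: r[0])
        onsets = [r[0] for r in rows]
        if len(set(onsets)) != len(onsets):
            violations.append(f"{path}: duplicated (trajectory_id={tid!r}, onset) pair")
            continue
        terminal_offset = offset
        if all(not lab for lab in rows[-1][1]):  # terminal row: empty categories
            terminal_offset = rows[-1][0]
            rows = rows[:-1]
        if terminal_offset is None:
            violations.append(
                f"{path}: trajectory {tid!r} has no terminal row and no "
                f"declared offset"
            )
            continue
        events = []
        for onset, labels, lineno in rows:
            for dim, label in zip(codebook.dimensions, labels):
                if not label:
                    violations.append(
                        f"{path} line {lineno}: missing value for dimension "
                        f"{dim.name!r} in trajectory {tid!r}"
                    )
                elif label not in dim.categories:
                    violations.append(
                        f"{path} line {lineno}: category {label!r} not in "
                        f"dimension {dim.name!r}"
                    )
            events.append(Event(onset, tuple(labels)))
        if not violations:
            trajectories.append(
                Trajectory(id=tid, codebook=codebook, events=events, offset=terminal_offset)
            )
    if violations:
        raise ValidationError(violations)
    return TrajectoryCollection(trajectories)


def write_long(collection: TrajectoryCollection, path) -> None:
    """Write a collection as one long-format table with terminal rows."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    cb = collection.codebook
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["trajectory_id", "onset", *cb.names])
        for traj in collection:
            for ev in traj.events:
                writer.writerow([traj.id, _format_onset(ev.onset), *ev.values])
            writer.writerow([traj.id, _format_onset(traj.offset)] + [""] * len(cb))
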